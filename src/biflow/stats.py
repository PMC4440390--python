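"""Population statistics and distribution comparison for cytometry tables.

Includes the mean/SEM/STD/n summary (with the report-rounding
convention that prints the mean to the decimal place of the SEM), 1-D
percentile gating against a control population, and a two-sample
two-dimensional Kolmogorov–Smirnov test in the Fasano–Franceschini
quadrant formulation with Peacock's asymptotic p-value (a permutation
p-value is available for small samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "PopulationSummary",
    "summarize",
    "Gate1D",
    "percentile_gate",
    "ks2d",
]


@dataclass(frozen=True)
class PopulationSummary:
    """mean / SEM / STD / n of any per-cell quantity."""

    mean: float
    sem: float  # nan for n == 1
    std: float  # nan for n == 1
    n: int

    def rounded(self) -> tuple[str, str]:
        """(mean, SEM) strings with SEM at one significant digit and the
        mean rounded to the same decimal place — the convention of
        population-statistics tables."""
        if self.n < 2 or not math.isfinite(self.sem) or self.sem == 0:
            return (f"{self.mean:g}", "")
        exponent = math.floor(math.log10(abs(self.sem)))
        sem_r = round(self.sem, -exponent)
        if sem_r >= 10 ** (exponent + 1):  # rounding carried to the next digit
            exponent += 1
            sem_r = round(self.sem, -exponent)
        decimals = max(-exponent, 0)
        return (f"{self.mean:.{decimals}f}", f"{sem_r:.{decimals}f}")


def summarize(values) -> PopulationSummary:
    """Sample mean, STD (n-1 denominator) and SEM = STD/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty population")
    if v.size == 1:
        return PopulationSummary(mean=float(v[0]), sem=np.nan, std=np.nan, n=1)
    std = float(v.std(ddof=1))
    return PopulationSummary(
        mean=float(v.mean()), sem=std / math.sqrt(v.size), std=std, n=int(v.size)
    )


@dataclass(frozen=True)
class Gate1D:
    """Threshold gate on one channel, e.g. the 99th centile of a control."""

    key: str
    threshold: float
    side: str = "above"  # events pass when value is strictly on this side
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("above", "below"):
            raise ValueError("side must be 'above' or 'below'")
        if not math.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v > self.threshold if self.side == "above" else v < self.threshold


def percentile_gate(
    control_values, percentile: float, key: str = "", side: str = "above"
) -> Gate1D:
    """Gate at an empirical percentile of a control population.

    The threshold is the linearly interpolated order statistic, so
    applying an ``above`` gate back to the control passes about
    ``100 - percentile`` percent of it.
    """
    v = np.asarray(control_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty control population")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    thr = float(np.percentile(v, percentile))  # linear interpolation
    return Gate1D(
        key=key,
        threshold=thr,
        side=side,
        provenance=f"{percentile:g}th centile of control (n={v.size})",
    )


# --------------------------------------------------------------------------
# two-sample 2D Kolmogorov–Smirnov (Fasano–Franceschini)


def _max_quadrant_diff(origins: np.ndarray, a: np.ndarray, b: np.ndarray,
                       chunk: int = 512) -> float:
    """Max over origins and the four quadrants of |F_a - F_b|.

    Quadrants are open (points on the dividing lines are excluded),
    fractions are taken within each sample.
    """
    d = 0.0
    na, nb = a.shape[0], b.shape[0]
    for lo in range(0, origins.shape[0], chunk):
        o = origins[lo : lo + chunk]
        sides = []
        for pts in (a, b):
            gx = pts[None, :, 0] > o[:, None, 0]
            lx = pts[None, :, 0] < o[:, None, 0]
            gy = pts[None, :, 1] > o[:, None, 1]
            ly = pts[None, :, 1] < o[:, None, 1]
            sides.append(((gx, lx), (gy, ly)))
        (agx, alx), (agy, aly) = sides[0]
        (bgx, blx), (bgy, bly) = sides[1]
        for ix, iy in ((0, 0), (0, 1), (1, 0), (1, 1)):
            fa = ((agx, alx)[ix] & (agy, aly)[iy]).sum(axis=1) / na
            fb = ((bgx, blx)[ix] & (bgy, bly)[iy]).sum(axis=1) / nb
            d = max(d, float(np.abs(fa - fb).max()))
    return d


def _ks2d_statistic(a: np.ndarray, b: np.ndarray) -> float:
    d1 = _max_quadrant_diff(a, a, b)
    d2 = _max_quadrant_diff(b, a, b)
    return 0.5 * (d1 + d2)


def ks2d(
    sample_a,
    sample_b,
    method: str = "asymptotic",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sample 2D Kolmogorov–Smirnov test.

    The statistic is the Fasano–Franceschini quadrant form: for every
    data point of either sample as origin, the plane is split into four
    open quadrants and the maximal difference between the two samples'
    quadrant fractions is recorded; D averages the maxima obtained with
    origins from sample a and from sample b.

    ``method="asymptotic"`` (default) uses Peacock's asymptotic formula
    with the Fasano–Franceschini correlation correction; for small
    samples ``method="permutation"`` draws ``n_perm`` label permutations
    instead.  Both samples need at least 10 points.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("samples must be (n, 2) point arrays")
    if a.shape[0] < 10 or b.shape[0] < 10:
        raise ValueError("2D KS needs at least 10 points per sample")
    d = _ks2d_statistic(a, b)
    if method == "asymptotic":
        return d, _peacock_pvalue(d, a, b)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.vstack([a, b])
        na = a.shape[0]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            dp = _ks2d_statistic(pooled[perm[:na]], pooled[perm[na:]])
            if dp >= d:
                hits += 1
        return d, (hits + 1) / (n_perm + 1)
    raise ValueError("method must be 'asymptotic' or 'permutation'")


def _pearson_r(x: np.ndarray) -> float:
    if np.ptp(x[:, 0]) == 0 or np.ptp(x[:, 1]) == 0:
        return 0.0
    return float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])


def _peacock_pvalue(d: float, a: np.ndarray, b: np.ndarray) -> float:
    n_eff = a.shape[0] * b.shape[0] / (a.shape[0] + b.shape[0])
    r2 = 0.5 * (_pearson_r(a) ** 2 + _pearson_r(b) ** 2)
    sqrt_n = math.sqrt(n_eff)
    denom = 1.0 + math.sqrt(max(1.0 - r2, 0.0)) * (0.25 - 0.75 / sqrt_n)
    z = sqrt_n * d / denom
    return float(special.kolmogorov(z))
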