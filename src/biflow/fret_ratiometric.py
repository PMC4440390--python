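"""Three-cube ratiometric FRET analysis for conventional flow cytometry.

Channels per cell (all background-corrected):

* ``I_DD`` — donor excitation, donor emission;
* ``I_DA`` — donor excitation, acceptor emission (sensitized channel);
* ``I_AA`` — acceptor excitation, acceptor emission.

Bleed-through factors come from single-fluorophore controls as medians:
S1 = med(I_DA/I_DD) and S3 = med(I_AA/I_DD) on donor-only cells,
S2 = med(I_DA/I_AA) on acceptor-only cells.  The sensitized emission is

    F_c = I_DA - S1*I_DD - S2*(I_AA - S3*I_DD),

which vanishes identically on both single-fluorophore controls.  For a
series of linked 1:1 donor–acceptor standards, F_c/I_AA' is linear in
I_DD/I_AA' (I_AA' = I_AA - S3*I_DD, the acceptor channel stripped of
donor bleed): the slope is k = -s/d and the intercept y0 = s/a, where
d, s, a are the effective detection efficiencies of donor, sensitized
and direct-acceptor signal.  Regression across at least two standards
therefore calibrates the setup, after which

    E = F_c / (F_c - k * I_DD)

is exact per cell under the mixing model.  The factor alpha = k/y0
(= -a/d) is stored alongside k and y0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .stats import PopulationSummary, summarize

__all__ = [
    "BleedThrough",
    "AlphaCalibration",
    "background_correct",
    "gate_positive",
    "bleedthrough_factors",
    "sensitized_emission",
    "calibrate_alpha",
    "efficiency_ratiometric",
]

_CHANNELS = ["I_DD", "I_DA", "I_AA"]


@dataclass(frozen=True)
class BleedThrough:
    """Unitless median bleed-through ratios from single-colour controls."""

    s1: float  # donor signal leaking into the sensitized channel
    s2: float  # directly excited acceptor leaking into the sensitized channel
    s3: float  # donor signal leaking into the direct-acceptor channel

    def __post_init__(self) -> None:
        if min(self.s1, self.s2, self.s3) < 0:
            raise ValueError("bleed-through factors must be non-negative")


@dataclass(frozen=True)
class AlphaCalibration:
    r_f: dict[str, float]  # per-construct median F_c / I_AA'
    abscissa: dict[str, float]  # per-construct median I_DD / I_AA'
    k: float  # regression slope (negative when standards differ in E)
    y0: float  # regression intercept
    alpha: float  # k / y0


def background_correct(
    raw: pd.DataFrame, empty_controls: pd.DataFrame, stat: str = "mean"
) -> pd.DataFrame:
    """Subtract the empty-vector control's per-channel background.

    ``stat`` is ``"mean"`` (default) or ``"median"``.  Cellular
    autofluorescence measured on cells carrying an empty non-fluorescent
    vector is the background of all three channels.
    """
    if len(empty_controls) == 0:
        raise ValueError("empty-vector control population is empty")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    agg = getattr(empty_controls[_CHANNELS], stat)()
    out = raw.copy()
    out[_CHANNELS] = raw[_CHANNELS] - agg
    return out


def gate_positive(cells: pd.DataFrame) -> pd.DataFrame:
    """Keep cells positive in all three background-corrected channels."""
    mask = (cells[_CHANNELS] > 0).all(axis=1)
    return cells[mask].reset_index(drop=True)


def _safe_median_ratio(num: pd.Series, den: pd.Series, label: str) -> float:
    ok = den != 0
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(
            f"{label}: excluded {dropped} cells with zero denominator",
            stacklevel=3,
        )
    if not ok.any():
        raise ValueError(f"{label}: no cells with non-zero denominator")
    return float(np.median(num[ok] / den[ok]))


def bleedthrough_factors(
    gfp_only: pd.DataFrame, rfp_only: pd.DataFrame
) -> BleedThrough:
    """Median bleed-through ratios from gated single-colour controls."""
    if len(gfp_only) == 0 or len(rfp_only) == 0:
        raise ValueError("bleed-through controls must be non-empty")
    s1 = _safe_median_ratio(gfp_only["I_DA"], gfp_only["I_DD"], "S1")
    s3 = _safe_median_ratio(gfp_only["I_AA"], gfp_only["I_DD"], "S3")
    s2 = _safe_median_ratio(rfp_only["I_DA"], rfp_only["I_AA"], "S2")
    return BleedThrough(s1=s1, s2=s2, s3=s3)


def sensitized_emission(cells: pd.DataFrame, s: BleedThrough) -> pd.Series:
    """F_c = I_DA - S1*I_DD - S2*(I_AA - S3*I_DD); may be negative."""
    return (
        cells["I_DA"]
        - s.s1 * cells["I_DD"]
        - s.s2 * (cells["I_AA"] - s.s3 * cells["I_DD"])
    )


def calibrate_alpha(
    standards: dict[str, pd.DataFrame], s: BleedThrough
) -> AlphaCalibration:
    """Least-squares line of R_F against I_DD/I_AA' across constructs.

    Per construct, R_F = median(F_c / I_AA') and the abscissa
    median(I_DD / I_AA') are computed on gated cells, with
    I_AA' = I_AA - S3*I_DD.  Requires >= 2 constructs with distinct
    abscissa values.
    """
    if len(standards) < 2:
        raise ValueError("alpha calibration needs at least two FRET standards")
    r_f: dict[str, float] = {}
    x: dict[str, float] = {}
    for name, cells in standards.items():
        f_c = sensitized_emission(cells, s)
        i_aa_d = cells["I_AA"] - s.s3 * cells["I_DD"]
        r_f[name] = _safe_median_ratio(f_c, i_aa_d, f"R_F[{name}]")
        x[name] = _safe_median_ratio(cells["I_DD"], i_aa_d, f"x[{name}]")
    xv = np.array(list(x.values()))
    yv = np.array(list(r_f.values()))
    if np.ptp(xv) == 0:
        raise ValueError("degenerate regression: identical abscissa values")
    res = sp_stats.linregress(xv, yv)
    k, y0 = float(res.slope), float(res.intercept)
    if y0 == 0:
        raise ValueError("zero regression intercept: alpha undefined")
    return AlphaCalibration(r_f=r_f, abscissa=x, k=k, y0=y0, alpha=k / y0)


def efficiency_ratiometric(
    cells: pd.DataFrame,
    s: BleedThrough,
    calib: AlphaCalibration,
    trim: float = 0.10,
    trim_mode: str = "symmetric",
) -> tuple[pd.Series, PopulationSummary]:
    """Per-cell E = F_c/(F_c - k*I_DD) plus an outlier-trimmed summary.

    The population summary excludes ``trim`` (default 10%) of the cells
    as outliers: symmetrically (half from each tail of the E
    distribution, default) or, with ``trim_mode="deviation"``, the cells
    with the largest absolute deviation from the median.
    """
    f_c = sensitized_emission(cells, s)
    e = f_c / (f_c - calib.k * cells["I_DD"])
    ev = e.to_numpy(dtype=float)
    n_drop = int(round(trim * ev.size))
    if trim_mode == "symmetric":
        kept = np.sort(ev)[n_drop // 2 : ev.size - (n_drop - n_drop // 2)]
    elif trim_mode == "deviation":
        dev = np.abs(ev - np.median(ev))
        kept = ev[np.argsort(dev, kind="stable")[: ev.size - n_drop]]
    else:
        raise ValueError("trim_mode must be 'symmetric' or 'deviation'")
    if kept.size == 0:
        raise ValueError("population empty after outlier trimming")
    return e, summarize(kept)
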