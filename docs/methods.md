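# Methods

This note documents the models, estimators and numerical choices behind
`biflow`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## Units and containers

Macro times are stored in seconds (float64; sub-ns resolution over
minutes of acquisition), micro times in nanoseconds, burst durations in
ms and count rates in photons/ms.  A `PhotonStream` holds the sorted
per-photon arrays (macro time, micro time, detector channel), the
`AcquisitionConfig` (sync period 12.5 ns for an 80 MHz laser, micro-time
window, ADC bin count, macro bin width, channel ids) and, for simulated
data, per-particle ground truth.  The on-disk container is a plain-text
header + CSV format written with 17 significant digits, so
`read_stream(write_stream(s)) == s` holds bit-for-bit.

The laser period forces the 12.5 ns sync window; hardware that records
only a 10 ns ADC window is supported by setting `micro_window = 10.0`
(micro times are always sampled and fitted within `micro_window`).

## The photon-stream simulator

The simulator emulates particles transiting a circular illumination
patch in a microfluidic channel:

* **Arrivals** — a Poisson process with configurable rate.  Mean gaps
  much larger than the transit give isolated bursts; higher rates
  produce two-particle coincidences at the rate predicted by the
  exponential gap law, which is how the merged-burst artifact is
  studied.
* **Transit envelope** — Gaussian photon-rate profile with
  configurable FWHM (default 2 ms).  The true illumination profile of
  any given instrument is generally unpublished; a Gaussian is the
  natural model for a circular patch, and downstream assertions are
  envelope-agnostic except where the Gaussian form is used explicitly
  (see the merge oracle below).
* **Per-cell brightness** — expected burst photon counts are
  log-normal (`intensity_sigma_dex`, default 0.5 dex ≈ the two orders
  of magnitude spanned by transient expression); realised counts are
  Poisson.
* **Per-cell lifetime** — normal with configurable mean/STD, truncated
  at 0.05 ns; an optional `coupling` (ns per decade of intensity)
  reproduces the empirical negative lifetime–expression trend of
  brightly expressing cells.
* **Micro times** — inverse-CDF draws from the exponential decay
  truncated to the sync window (closed-form mean
  τ − T/(e^{T/τ} − 1), used throughout as the calibration identity);
  mixtures implement bi-exponential decays with the second component's
  *intensity* fraction specified directly.  Background photons are
  uniform in macro and micro time (the standard TCSPC assumption for
  uncorrelated counts).
* **Optional non-idealities** — a Gaussian instrument response of
  width σ_IRF folded into the window (default 0 = ideal), and
  single-photon-per-sync-period censoring to emulate pulse pile-up
  (default off).

What the simulator does **not** model: detector afterpulsing and dark
counts with non-uniform micro-time structure, scattering/autofluorescence
spectra, flow-profile variation across the channel, and cell doublets
other than temporal coincidence.  Tests passing on these streams
demonstrate correctness of the analysis algorithms under the stated
model, not robustness to every instrument artifact.

## Burst segmentation

Macro times are histogrammed into 20 µs bins, median-filtered (default
window 3 bins; the window is exposed because no standard value exists),
and thresholded.  Burst boundaries come from the *filtered* trace;
BD/PC/MCR are computed from the *raw* bins inside the run, so the
filter suppresses spurious boundaries without distorting statistics.
The threshold is user-set in counts/bin; `suggest_threshold` proposes
background mean + 5·√background with the median bin count as the
background estimate.  Bursts are then gated to PC ∈ [500, 10,000]
(configurable), the particle-burst size range this analysis targets;
the gate also removes the few-photon edge fragments that Poisson noise
detaches from burst tails.

**Coincidence oracle.** Two Gaussian transits of peak binned amplitude
A merge into one burst when the trace between them stays above the
threshold, i.e. when their centres are closer than
d* = √(8σ² ln(2A/TH)).  The truth-side oracle counts particle pairs
closer than d*; the segmentation's merged-burst count agrees with it
within binomial error.  A Gaussian envelope has no unique "transit
duration", so this analytically derived merge separation is the
principled interval length for overlap counting.

## Lifetime estimation

The default estimator is maximum likelihood under the truncated
exponential: for binned data the multinomial likelihood over ADC bins
is maximised by bounded 1-D search on log τ; for raw micro times the
MLE solves the score equation mean(t) = τ − T/(e^{T/τ} − 1) by
bracketed root finding (no solution exists when the sample mean
reaches T/2; the fit is then flagged, not raised).  MLE needs no
weighting scheme and stays calibrated at the few-hundred-photon scale
of a dim transit; bias is below 1 % at 2,000 photons and the estimator
STD scales as n^{−1/2}.  The alternative is Levenberg–Marquardt least
squares with Poisson weights (√max(counts, 1)).  Both accept an
optional constant offset for uniform background; the default model is
offset-free tail fitting over the full window with no IRF
deconvolution — hybrid-detector responses are an order of magnitude
shorter than the 0.2–5 ns lifetimes of interest, and the IRF of any
particular setup is unknown here.  Decays with fewer than 100 photons
(configurable) or fewer than two occupied bins are rejected.
ADC resolution defaults to 256 bins, balancing Poisson occupancy at
500–10,000 photons per burst.  Periodic re-excitation wrap-around needs
no separate code path for these models: folding an exponential decay of
any lifetime back into the window leaves a density proportional to
e^{−t/τ} on [0, T), which is exactly the truncated-exponential model
already fitted (the geometric wrap factor is absorbed by the window
normalisation).  Folding would only change the fit in combination with
a non-trivial IRF, which is out of scope.

**Global bi-exponential analysis.** With lifetimes (τ₁, τ₂) fixed,
each cell's amplitude fit is non-negative least squares on the
bin-integrated basis τ_k(e^{−l/τ_k} − e^{−r/τ_k}) — a convex problem
with a unique solution.  Unweighted NNLS keeps the amplitude estimates
unbiased in the interior of the parameter space; at the boundaries
(one component absent) the non-negativity constraint clamps roughly
half the fits to exactly zero and leaves a noise-floor fraction on the
rest, which is why population-level recovery statistics pool the
histograms before fitting.  With lifetimes free, the shared pair is
estimated by alternating per-cell NNLS with a Nelder–Mead update of
(log τ₁, log τ₂); each step minimises the joint squared-residual
objective, so it is non-increasing, and the iteration stops on
relative improvement < 1e−8 or 50 passes.  Intensity fractions are
f_k = A_k τ_k/ΣA_jτ_j, invariant under joint amplitude rescaling.

## Lifetime-based FRET estimators

E = 1 − τᵢ/τ̄_D with three choices of the donor reference τ̄_D:

1. **basic** — mean lifetime of all donor-only controls;
2. **matched** — mean lifetime of the `subset_fraction` (default 5 %)
   of controls with intensities most similar to cell *i*.  Similarity
   is |Δ log₁₀ I| by default (expression spans decades; a linear-scale
   option exists); the subset size is max(1, round(f·N)); distance ties
   break by control index order;
3. **iterative** — as matched, but on the unquenched intensity
   Iᵢ/(1 − Eᵢ) using the previous pass's E (pass 1 starts at E = 0 and
   therefore equals the matched estimator exactly).  The recursion
   stops when the mean over cells of |E_j − E_{j−1}|/|E_j| falls below
   `tolerance` (default 1 %); cells with |E| < 10⁻⁶ are excluded from
   that average to avoid division blow-ups, and cells whose previous E
   reaches 1 have the correction capped at 1/(1 − 0.999) and are
   flagged.  On populations with a mild lifetime–intensity trend the
   recursion terminates in 2–3 passes.

Negative efficiencies are reported, never clipped, so population means
stay unbiased under noise.  E ≤ 1 holds by construction for positive
lifetimes.

## Ratiometric three-cube FRET

Channels per cell: I_DD (donor-excited donor emission), I_DA
(donor-excited acceptor emission), I_AA (acceptor-excited acceptor
emission), background-corrected against empty-vector cells (mean by
default, median optional) and gated positive in all three channels.
Bleed-through factors are medians over single-colour controls:
S₁ = med(I_DA/I_DD), S₃ = med(I_AA/I_DD) on donor-only cells,
S₂ = med(I_DA/I_AA) on acceptor-only cells (zero denominators are
excluded with a warning — single-colour controls are dark in the other
fluorophore's channels and are therefore not positivity-gated).  The
sensitized emission F_c = I_DA − S₁I_DD − S₂(I_AA − S₃I_DD) vanishes
identically on both controls.

For 1:1 linked donor–acceptor standards with channel detection
efficiencies (d, s, a), writing I_AA′ = I_AA − S₃I_DD (the acceptor
channel stripped of donor bleed) gives exactly

    F_c/I_AA′ = s/a − (s/d) · I_DD/I_AA′,

so regressing the per-construct medians R_F = med(F_c/I_AA′) against
med(I_DD/I_AA′) over ≥ 2 standards yields k = −s/d and y₀ = s/a, and
E = F_c/(F_c − k·I_DD) is exact per cell; α = k/y₀ = −a/d is stored
with the calibration.  Using I_AA′ rather than raw I_AA in both ratios
is what makes the inversion exact for S₃ > 0; with S₃ = 0 the two
are identical.  Population summaries exclude 10 % of cells as outliers
(5 % from each tail of the E distribution by default; largest absolute
deviation from the median as an option).

Known property: per-cell E is a nonlinear ratio of the channels, so
multiplicative channel noise of coefficient cv biases the population
mean at order cv² (≈ 0.5–1 percentage point at cv = 0.10) even though
the noise-free inversion is exact — a generic feature of ratiometric
FRET estimators, and one reason lifetime-based readouts are preferred
for quantitative work.

## Statistics and outputs

Summaries report mean, sample STD (n−1) and SEM = STD/√n; the
`rounded()` helper reproduces the reporting convention of rounding the
SEM to one significant digit and the mean to the same decimal place.
Percentile gates use linearly interpolated order statistics (stated
because conventions differ).  The two-sample 2-D Kolmogorov–Smirnov
test uses the Fasano–Franceschini quadrant statistic — for each data
point of either sample as origin, the maximal difference of the two
samples' open-quadrant fractions, averaged over the two origin choices
— with the Peacock asymptotic p-value including the correlation
correction (1 + √(1−r²)(0.25 − 0.75/√n)); a permutation p-value is
available for small samples.  The asymptotic null is slightly
conservative at moderate n (type-I rate ~2–5 % at nominal 5 %), which
is harmless at the p < 10⁻⁶ decision thresholds typical for comparing
cytometry distributions.  FCS output is version 3.1, single DATA
segment, 32-bit little-endian floats in list mode — the most widely
readable layout; parameter names are sanitized to ASCII
deterministically.

## Problem sizes and determinism

All randomness flows through `numpy` `SeedSequence`-derived generators;
identical seeds reproduce streams byte-for-byte.  The test-suite and
acceptance-script simulation sizes (e.g. 1.2×10⁵ cells for dispersion
checks, 500 bursts × 2,000 photons for estimator calibration, 200
cells × 2,000 photons × 10 replicates for the bi-exponential
titration, 200 null datasets of 2×500 points for KS calibration) were
chosen so each property is measured with at least 3σ headroom over its
Monte-Carlo error while the whole suite completes in a couple of
minutes on one CPU.

## Known limitations

* No IRF deconvolution; sub-200 ps lifetimes would need it.
* The per-cell NNLS amplitude boundary bias (clamping) is inherent to
  non-negative estimation; pool histograms or use the global fit for
  unbiased population fractions near f = 0 or 1.
* The ratiometric inversion assumes strict 1:1 donor–acceptor linkage
  and linear detection; free-fluorophore mixtures violate it.
* The vendor 32-bit FIFO format is not parsed; streams enter via the
  documented text container or the simulator.
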