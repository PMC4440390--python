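# biflow

Burst-integrated fluorescence lifetime (BIFL) analysis for time-domain
fluorescence lifetime flow cytometry — from raw TCSPC photon records to
per-cell lifetimes, FRET efficiencies and cytometry-grade outputs.

## The problem

A fluorescence-lifetime flow cytometer detects cells flowing through a
pulsed-laser illumination volume with a time-correlated single photon
counting (TCSPC) card in FIFO mode: every detected photon is stamped
with a **macro time** (lab-frame arrival, spanning the acquisition) and
a **micro time** (delay after the laser sync pulse, within one 12.5 ns
period at 80 MHz).  Each passing cell produces a burst of 500–10,000
photons over a ~ms transit; the micro-time histogram of a burst is that
cell's fluorescence decay.  This package implements the complete
analysis chain for such data, plus a photon-stream simulator with known
ground truth that stands in for the instrument:

1. **Burst segmentation** (`biflow.bursts`) — macro times are binned
   into 20 µs bins, median-filtered, and thresholded; each
   above-threshold run is one burst, characterised by burst duration
   (BD), photon count (PC) and mean count rate (MCR).
2. **Lifetime fitting** (`biflow.decay`) — per-burst micro-time
   histograms are fitted with a truncated mono-exponential by maximum
   likelihood (default) or Levenberg–Marquardt least squares.  For
   two-component decays, a **global bi-exponential analysis** shares one
   lifetime pair (τ₁, τ₂) across all cells and channels while fitting
   non-negative amplitudes A₁, A₂ per cell; intensity fractions are
   f_k = A_k τ_k / (A₁τ₁ + A₂τ₂).
3. **Lifetime FRET** (`biflow.fret_lifetime`) — per-cell efficiency
   E = 1 − τᵢ/τ̄_D against a donor-only control population, with two
   refinements for expression-dependent donor lifetimes: matching each
   cell against the 5 % of controls with the most similar intensity,
   and a recursion that matches on the FRET-unquenched intensity
   Iᵢ/(1 − Eᵢ) until the mean relative change of E drops below 1 %.
4. **Ratiometric FRET** (`biflow.fret_ratiometric`) — the conventional
   three-cube cytometer arm: background correction, bleed-through
   factors S₁–S₃ from single-colour controls, sensitized emission
   F_c = I_DA − S₁I_DD − S₂(I_AA − S₃I_DD), α calibration by regressing
   R_F against I_DD/I_AA across FRET-standard constructs, and per-cell
   E = F_c/(F_c − k·I_DD) with outlier-trimmed population summaries.
5. **Statistics and IO** (`biflow.stats`, `biflow.fcs`) — mean/SEM/STD
   summaries with the table-rounding convention, percentile gates, a
   two-sample 2-D Kolmogorov–Smirnov test (Fasano–Franceschini), and an
   FCS 3.1 writer/reader so results open in standard cytometry software.

The simulator (`biflow.simulate`) generates FIFO streams from particle
populations with configurable lifetime/intensity distributions, a
lifetime–expression coupling, Poisson arrivals (including two-particle
coincidences), Gaussian transit envelopes and uniform background, and
three-channel intensity tables for the ratiometric arm that are exactly
invertible in the noise-free limit.

## Worked example

Simulate a FRET-construct population (τ = 2.038 ± 0.18 ns) and a
donor-only control (τ = 2.593 ± 0.13 ns), segment and fit each stream,
and compute all three lifetime-FRET estimators:

```sh
biflow simulate -c examples/fret_cells.toml  --seed 1 -o fret_cells.stream
biflow simulate -c examples/donor_only.toml --seed 2 -o donor_only.stream
biflow fit fret_cells.stream -o fret_cells.csv
biflow fit donor_only.stream -o donor_only.csv
biflow fret fret_cells.csv donor_only.csv -o fret_table.csv
biflow report fret_table.csv -o cells.fcs
```

prints

```text
fret_cells.stream: 483511 photons, 200 particles
donor_only.stream: 478483 photons, 200 particles
fret_cells.csv: 198 cells fitted (mle)
donor_only.csv: 194 cells fitted (mle)
E_basic: mean 21.9% (SEM 0.4, STD 6.3, n=198)
E_matched: mean 21.6% (SEM 0.5, STD 6.3, n=198)
E_iterative: mean 21.4% (SEM 0.5, STD 6.6, n=198)
iterations_used: 3
cells.fcs: 198 events, 11 parameters
```

198 of the 200 simulated transits survive the photon-count gate
[500, 10,000] and fitting; the mean efficiency matches the analytic
value 1 − 2.038/2.593 ≈ 21.4 % (the basic estimator sits slightly
higher because per-burst background photons are not modelled by the
default zero-offset fit), and the per-cell dispersion of ~7 % E
reflects the 0.18 ns lifetime spread.  The recursion converged on the
third pass.  `cells.fcs` is an FCS 3.1 list-mode file readable by any
cytometry tool.

The library surface mirrors the CLI: `simulate_stream`,
`detect_bursts`, `fit_mono`, `fit_biexp_global`, `efficiency_basic` /
`efficiency_matched` / `efficiency_iterative`, `bleedthrough_factors`,
`calibrate_alpha`, `efficiency_ratiometric`, `ks2d`, `write_fcs`.

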