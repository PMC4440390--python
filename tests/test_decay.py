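"""Lifetime estimation: histograms, MLE vs least squares, global analysis."""

import numpy as np
import pytest
from scipy import optimize

import biflow as bf
from biflow.decay import (
    DecayHistogram,
    fit_biexp_global,
    fit_mono,
    fit_mono_times,
    fractional_intensity,
    histogram_micro_times,
)
from biflow.simulate import PopulationSpec, simulate_stream
from conftest import WINDOW, decay_histogram


def score_equation_tau(micro_times, window):
    """Independent oracle: 1-D root finding on the truncated-exponential
    score equation  mean(t) = tau - T/(exp(T/tau) - 1)."""
    m = float(np.mean(micro_times))

    def g(tau):
        with np.errstate(over="ignore"):  # expm1 overflow -> exact 0 term
            return tau - window / np.expm1(window / tau) - m

    return optimize.brentq(g, 1e-6, 1e6, xtol=1e-12)


class TestHistogram:
    @pytest.fixture
    def burst_stream(self):
        spec = PopulationSpec(
            n_cells=1, lifetime_mean=2.5, intensity_mean=1000,
            channel_split=(0.7, 0.3),
        )
        config = bf.AcquisitionConfig(channels=(0, 1))
        stream = simulate_stream(spec, config, seed=2)
        bursts = bf.detect_bursts(stream, threshold=2.0, min_pc=100)
        return stream, bursts[0]

    def test_photon_conserving(self, burst_stream):
        stream, burst = burst_stream
        hist = histogram_micro_times(stream, burst)
        assert hist.counts.sum() == burst.pc

    def test_per_channel_conservation(self, burst_stream):
        stream, burst = burst_stream
        for ch, expected in burst.per_channel_counts.items():
            hist = histogram_micro_times(stream, burst, channel=ch)
            assert hist.counts.sum() == expected

    def test_exponential_shape(self, rng):
        hist = decay_histogram(rng, 100_000, 2.5, adc_bins=16)
        # expectation decreases monotonically; at n=1e5 and 16 wide bins
        # the realized counts do too
        assert (np.diff(hist.counts) < 0).all()

    def test_empty_burst_rejected(self, burst_stream):
        stream, burst = burst_stream
        from dataclasses import replace

        empty = replace(burst, photon_span=(5, 5))
        with pytest.raises(ValueError, match="insufficient"):
            histogram_micro_times(stream, empty)


class TestMonoFit:
    def test_degenerate_histogram_rejected(self):
        edges = np.linspace(0, WINDOW, 257)
        counts = np.zeros(256)
        counts[3] = 500
        with pytest.raises(ValueError, match="degenerate"):
            fit_mono(DecayHistogram(edges=edges, counts=counts))

    def test_all_equal_micro_times_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mono_times(np.full(500, 3.0), WINDOW)

    def test_too_few_photons_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_mono_times(np.array([1.0, 2.0]), WINDOW)

    def test_mle_recovers_lifetime_at_high_counts(self, rng):
        hist = decay_histogram(rng, 100_000, 2.5)
        fit = fit_mono(hist, method="mle")
        assert fit.converged
        assert 2.45 < fit.tau < 2.55

    def test_binned_mle_matches_score_equation_oracle(self, rng):
        times = bf.sample_truncated_exponential(rng, 2.5, WINDOW, 20_000)
        oracle = score_equation_tau(times, WINDOW)
        cont = fit_mono_times(times, WINDOW)
        assert cont.tau == pytest.approx(oracle, rel=1e-9)
        edges = np.linspace(0, WINDOW, 2049)  # fine bins: binning loss tiny
        counts, _ = np.histogram(times, bins=edges)
        binned = fit_mono(DecayHistogram(edges=edges, counts=counts))
        assert binned.tau == pytest.approx(oracle, rel=2e-3)

    def test_lsq_and_mle_agree(self, rng):
        hist = decay_histogram(rng, 100_000, 2.5)
        mle = fit_mono(hist, method="mle")
        lsq = fit_mono(hist, method="lsq")
        # combined standard error ~ tau/sqrt(n) per method
        se = 2 * np.sqrt(2) * 2.5 / np.sqrt(100_000)
        assert abs(mle.tau - lsq.tau) < 2 * se
        assert lsq.converged

    def test_estimator_bias_below_one_percent(self, rng):
        taus = []
        for _ in range(500):
            hist = decay_histogram(rng, 2000, 2.5)
            taus.append(fit_mono(hist).tau)
        assert abs(np.mean(taus) - 2.5) < 0.01 * 2.5

    def test_precision_scales_as_inverse_sqrt_photons(self, rng):
        ns = [500, 2000, 8000]
        stds = []
        for n in ns:
            taus = [fit_mono(decay_histogram(rng, n, 2.5)).tau
                    for _ in range(150)]
            stds.append(np.std(taus))
        slope = np.polyfit(np.log(ns), np.log(stds), 1)[0]
        assert abs(slope + 0.5) < 0.1

    def test_offset_fit_handles_uniform_background(self, rng):
        n_decay, n_bg = 18_000, 2_000
        t = np.concatenate([
            bf.sample_truncated_exponential(rng, 2.5, WINDOW, n_decay),
            rng.uniform(0, WINDOW, n_bg),
        ])
        edges = np.linspace(0, WINDOW, 257)
        counts, _ = np.histogram(t, bins=edges)
        hist = DecayHistogram(edges=edges, counts=counts)
        plain = fit_mono(hist, method="mle")
        with_bg = fit_mono(hist, method="mle", fit_offset=True)
        assert abs(with_bg.tau - 2.5) < abs(plain.tau - 2.5)
        assert abs(with_bg.tau - 2.5) < 0.1


class TestGlobalBiExp:
    def test_single_cell_equals_direct_amplitude_fit(self, rng):
        hist = decay_histogram(rng, 5000, [0.2, 2.95], [0.5, 0.5])
        fit = fit_biexp_global([hist], taus=(0.2, 2.95))
        # direct NNLS on the same design is the per-cell problem
        e1 = np.exp(-hist.edges / 0.2)
        e2 = np.exp(-hist.edges / 2.95)
        m = np.column_stack([0.2 * (e1[:-1] - e1[1:]),
                             2.95 * (e2[:-1] - e2[1:])])
        direct, _ = optimize.nnls(m, hist.counts.astype(float))
        assert fit.a1[0] == pytest.approx(direct[0], rel=1e-9, abs=1e-9)
        assert fit.a2[0] == pytest.approx(direct[1], rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("f2_true", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_fraction_recovery_with_fixed_lifetimes(self, rng, f2_true):
        hists = [
            decay_histogram(rng, 2000, [0.2, 2.95], [1 - f2_true, f2_true])
            for _ in range(200)
        ]
        fit = fit_biexp_global(hists, taus=(0.2, 2.95))
        f2 = fit.f2[fit.fitted]
        # population mean within 3 per-cell standard deviations (clamping
        # at the amplitude boundary makes SEM-level bias expected at 0/1)
        spread = max(np.std(f2), 5e-3)
        assert abs(np.mean(f2) - f2_true) < 3 * spread

    def test_pure_long_component_pins_short_amplitude_to_boundary(self, rng):
        hists = [decay_histogram(rng, 4000, [0.2, 2.95], [0.0, 1.0])
                 for _ in range(20)]
        fit = fit_biexp_global(hists, taus=(0.2, 2.95))
        # the non-negativity constraint is active: Poisson noise leaves
        # roughly half the cells exactly at A1 = 0 and the rest with a
        # spurious short-component fraction at the noise floor
        assert np.mean(fit.a1 == 0.0) > 0.25
        assert np.all(fit.f1 < 0.02)

    def test_equal_lifetimes_rejected(self, rng):
        hist = decay_histogram(rng, 1000, 2.0)
        with pytest.raises(ValueError):
            fit_biexp_global([hist], taus=(2.0, 2.0))

    def test_dim_cells_skipped_with_flag(self, rng):
        bright = decay_histogram(rng, 2000, [0.2, 2.95], [0.5, 0.5])
        dim = decay_histogram(rng, 30, [0.2, 2.95], [0.5, 0.5])
        fit = fit_biexp_global([bright, dim], taus=(0.2, 2.95))
        assert fit.fitted.tolist() == [True, False]
        assert np.isnan(fit.f2[1])

    def test_free_lifetimes_recovered_and_objective_monotone(self, rng):
        hists = [decay_histogram(rng, 20_000, [0.2, 2.95], [0.4, 0.6])
                 for _ in range(10)]
        fit = fit_biexp_global(hists, taus=None, taus_init=(0.5, 4.0))
        assert fit.tau1 == pytest.approx(0.2, abs=0.05)
        assert fit.tau2 == pytest.approx(2.95, abs=0.15)
        fixed = fit_biexp_global(hists, taus=(fit.tau1, fit.tau2))
        assert fixed.objective <= fit.objective * (1 + 1e-9)


class TestFractionalIntensity:
    def test_zero_second_amplitude(self):
        assert fractional_intensity(3.0, 0.0, 0.2, 2.95) == (1.0, 0.0)

    def test_hand_arithmetic(self):
        f1, f2 = fractional_intensity(1.0, 1.0, 0.2, 2.95)
        assert f2 == pytest.approx(2.95 / 3.15)
        assert f1 + f2 == pytest.approx(1.0)

    def test_component_swap_symmetry(self):
        f1, f2 = fractional_intensity(2.0, 5.0, 0.2, 2.95)
        g1, g2 = fractional_intensity(5.0, 2.0, 2.95, 0.2)
        assert (f1, f2) == pytest.approx((g2, g1))

    def test_invariant_under_joint_rescaling(self):
        base = fractional_intensity(2.0, 5.0, 0.2, 2.95)
        scaled = fractional_intensity(2.0e3, 5.0e3, 0.2, 2.95)
        assert base == pytest.approx(scaled)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            fractional_intensity(0.0, 0.0, 0.2, 2.95)
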