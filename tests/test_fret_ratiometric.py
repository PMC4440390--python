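"""Three-cube ratiometric FRET: calibration algebra and round-trips."""

import numpy as np
import pandas as pd
import pytest

from biflow.fret_ratiometric import (
    AlphaCalibration,
    BleedThrough,
    background_correct,
    bleedthrough_factors,
    calibrate_alpha,
    efficiency_ratiometric,
    gate_positive,
    sensitized_emission,
)
from biflow.simulate import simulate_ratiometric_cells

S_TRIPLE = (0.05, 0.10, 0.02)
ALPHA = -1.5
E_TRUE = {"7aa": 0.30, "19aa": 0.20, "32aa": 0.10}


@pytest.fixture
def clean_tables():
    return simulate_ratiometric_cells(
        E_TRUE, bleedthrough=S_TRIPLE, alpha=ALPHA, n_cells=300, seed=42
    )


class TestBackgroundAndGating:
    def test_constant_offset_removed_exactly(self):
        raw = pd.DataFrame({"I_DD": [110.0], "I_DA": [60.0], "I_AA": [30.0]})
        empty = pd.DataFrame(
            {"I_DD": [10.0, 10.0], "I_DA": [5.0, 5.0], "I_AA": [20.0, 20.0]}
        )
        out = background_correct(raw, empty)
        assert out.iloc[0].tolist() == [100.0, 55.0, 10.0]

    def test_raw_equal_to_control_mean_gives_zero(self):
        empty = pd.DataFrame(
            {"I_DD": [8.0, 12.0], "I_DA": [1.0, 3.0], "I_AA": [4.0, 6.0]}
        )
        out = background_correct(empty.mean().to_frame().T, empty)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_simulated_offsets_removed(self):
        bg = (50.0, 30.0, 20.0)
        tabs = simulate_ratiometric_cells(
            {"a": 0.2}, alpha=-1.0, n_cells=100, background=bg, seed=3
        )
        corrected = background_correct(tabs["a"], tabs["empty"])
        reference = simulate_ratiometric_cells(
            {"a": 0.2}, alpha=-1.0, n_cells=100, seed=3
        )["a"]
        assert np.allclose(corrected.to_numpy(), reference.to_numpy())

    def test_empty_control_rejected(self):
        cells = pd.DataFrame({"I_DD": [1.0], "I_DA": [1.0], "I_AA": [1.0]})
        with pytest.raises(ValueError, match="empty"):
            background_correct(cells, cells.iloc[:0])

    def test_gate_drops_any_nonpositive_channel(self):
        cells = pd.DataFrame(
            {
                "I_DD": [1.0, -0.1, 2.0, 3.0],
                "I_DA": [1.0, 1.0, 0.0, 3.0],
                "I_AA": [1.0, 1.0, 1.0, 3.0],
            }
        )
        kept = gate_positive(cells)
        assert len(kept) == 2

    def test_noise_free_expressers_fully_retained(self, clean_tables):
        for name in E_TRUE:
            assert len(gate_positive(clean_tables[name])) == 300


class TestBleedThrough:
    def test_exact_recovery_from_controls(self, clean_tables):
        s = bleedthrough_factors(
            clean_tables["gfp_only"], clean_tables["rfp_only"]
        )
        assert (s.s1, s.s2, s.s3) == pytest.approx(S_TRIPLE)

    def test_zero_crosstalk(self):
        tabs = simulate_ratiometric_cells(
            {"a": 0.2}, bleedthrough=(0.0, 0.0, 0.0), alpha=-1.0,
            n_cells=50, seed=1,
        )
        s = bleedthrough_factors(tabs["gfp_only"], tabs["rfp_only"])
        assert (s.s1, s.s2, s.s3) == (0.0, 0.0, 0.0)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            BleedThrough(-0.1, 0.0, 0.0)


class TestSensitizedEmission:
    def test_reduces_to_ida_without_bleedthrough(self):
        cells = pd.DataFrame(
            {"I_DD": [10.0], "I_DA": [7.0], "I_AA": [3.0]}
        )
        s = BleedThrough(0.0, 0.0, 0.0)
        assert sensitized_emission(cells, s)[0] == 7.0

    def test_vanishes_on_both_single_colour_controls(self, clean_tables):
        s = bleedthrough_factors(
            clean_tables["gfp_only"], clean_tables["rfp_only"]
        )
        for ctrl in ("gfp_only", "rfp_only"):
            f_c = sensitized_emission(clean_tables[ctrl], s)
            assert np.allclose(f_c, 0.0, atol=1e-9)


class TestCalibration:
    def test_noise_free_round_trip_to_machine_precision(self, clean_tables):
        s = bleedthrough_factors(
            clean_tables["gfp_only"], clean_tables["rfp_only"]
        )
        standards = {k: gate_positive(clean_tables[k]) for k in E_TRUE}
        calib = calibrate_alpha(standards, s)
        assert calib.alpha == pytest.approx(ALPHA, rel=1e-12)
        for name, e_true in E_TRUE.items():
            e, summary = efficiency_ratiometric(standards[name], s, calib)
            assert np.allclose(e, e_true, atol=1e-12)
            assert summary.mean == pytest.approx(e_true, abs=1e-12)

    def test_two_identical_constructs_degenerate(self, clean_tables):
        s = BleedThrough(*S_TRIPLE)
        cells = gate_positive(clean_tables["7aa"])
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_alpha({"a": cells, "b": cells.copy()}, s)

    def test_exact_line_returns_slope_and_intercept(self):
        # constructs built so that (x, R_F) lie exactly on y = y0 + k x
        s = BleedThrough(0.0, 0.0, 0.0)
        standards = {}
        for e in (0.1, 0.3):
            x = np.full(20, 100.0)
            standards[f"E{e}"] = pd.DataFrame(
                {"I_DD": (1 - e) * x, "I_DA": e * x, "I_AA": 2.0 * x}
            )
        calib = calibrate_alpha(standards, s)
        assert calib.y0 == pytest.approx(0.5)  # s_eff / a_eff = 1/2
        assert calib.k == pytest.approx(-1.0)  # -s_eff / d_eff
        assert calib.alpha == pytest.approx(-2.0)

    def test_fewer_than_two_constructs_rejected(self, clean_tables):
        s = BleedThrough(*S_TRIPLE)
        with pytest.raises(ValueError, match="two"):
            calibrate_alpha({"only": clean_tables["7aa"]}, s)


class TestEfficiency:
    def test_scale_invariance_per_cell(self, clean_tables):
        s = bleedthrough_factors(
            clean_tables["gfp_only"], clean_tables["rfp_only"]
        )
        standards = {k: gate_positive(clean_tables[k]) for k in E_TRUE}
        calib = calibrate_alpha(standards, s)
        cells = standards["19aa"]
        e_base, _ = efficiency_ratiometric(cells, s, calib)
        e_scaled, _ = efficiency_ratiometric(cells * 37.5, s, calib)
        assert np.allclose(e_base, e_scaled)

    def test_null_population_mean_zero(self):
        tabs = simulate_ratiometric_cells(
            {"null": 0.0, "pos": 0.2}, bleedthrough=S_TRIPLE, alpha=ALPHA,
            n_cells=200, seed=7,
        )
        s = bleedthrough_factors(tabs["gfp_only"], tabs["rfp_only"])
        calib = calibrate_alpha(
            {k: gate_positive(tabs[k]) for k in ("null", "pos")}, s
        )
        e, summary = efficiency_ratiometric(
            gate_positive(tabs["null"]), s, calib
        )
        assert summary.mean == pytest.approx(0.0, abs=1e-12)

    def test_noisy_channels_recover_within_three_sem(self):
        tabs = simulate_ratiometric_cells(
            E_TRUE, bleedthrough=S_TRIPLE, alpha=ALPHA, n_cells=2000,
            noise_cv=0.10, seed=11,
        )
        clean = simulate_ratiometric_cells(
            E_TRUE, bleedthrough=S_TRIPLE, alpha=ALPHA, n_cells=2000, seed=11
        )
        s = bleedthrough_factors(clean["gfp_only"], clean["rfp_only"])
        standards = {k: gate_positive(tabs[k]) for k in E_TRUE}
        calib = calibrate_alpha(standards, s)
        for name, e_true in E_TRUE.items():
            _, summary = efficiency_ratiometric(standards[name], s, calib)
            # E is a nonlinear ratio of noisy channels, so multiplicative
            # noise of coefficient cv induces a second-order distortion of
            # order cv^2 in the population mean on top of sampling error
            assert abs(summary.mean - e_true) < 2 * 0.10**2 + 3 * summary.sem

    def test_trimmed_summary_ignores_gross_outliers(self, clean_tables):
        s = bleedthrough_factors(
            clean_tables["gfp_only"], clean_tables["rfp_only"]
        )
        standards = {k: gate_positive(clean_tables[k]) for k in E_TRUE}
        calib = calibrate_alpha(standards, s)
        cells = standards["19aa"].copy()
        cells.loc[:5, "I_DA"] *= 50.0  # 2% gross outliers
        _, summary = efficiency_ratiometric(cells, s, calib)
        assert summary.mean == pytest.approx(0.20, abs=1e-6)

    def test_deviation_trim_mode(self, clean_tables):
        s = bleedthrough_factors(
            clean_tables["gfp_only"], clean_tables["rfp_only"]
        )
        standards = {k: gate_positive(clean_tables[k]) for k in E_TRUE}
        calib = calibrate_alpha(standards, s)
        _, summary = efficiency_ratiometric(
            standards["7aa"], s, calib, trim_mode="deviation"
        )
        assert summary.mean == pytest.approx(0.30, abs=1e-12)
        with pytest.raises(ValueError, match="trim_mode"):
            efficiency_ratiometric(standards["7aa"], s, calib,
                                   trim_mode="bogus")
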