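"""Plate normalization, 4PL fitting, ΔIC50, Bliss scoring, smoothing and
curve extraction — with grid-search and direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest

from organoidquant.doseresponse import (
    PRESET_GRIDS,
    BlissMatrix,
    DoseMatrix,
    bliss_excess,
    delta_ic50,
    extract_curve,
    fit_dose_response,
    four_pl,
    normalize_viability,
    smooth_matrix,
)
from organoidquant.synthgen import make_plate_reads


def _reads(signals, concs):
    rows = [
        dict(well=f"W{i}", conc_a_nM=c, conc_b_nM=0.0, signal=s, role="treated")
        for i, (c, s) in enumerate(zip(concs, signals))
    ]
    rows += [dict(well="V0", conc_a_nM=0.0, conc_b_nM=0.0, signal=1000.0, role="vehicle"),
             dict(well="V1", conc_a_nM=0.0, conc_b_nM=0.0, signal=1000.0, role="vehicle")]
    return pd.DataFrame(rows)


class TestNormalization:
    def test_vehicle_plateau_midpoint_identities(self):
        reads = _reads([1000.0, 550.0, 100.0], [1.0, 10.0, 100.0])
        matrix = normalize_viability(reads, baseline_rule=100.0)
        col = matrix.values[:, 0]
        by_conc = dict(zip(matrix.conc_a_nM, col))
        assert by_conc[1.0] == pytest.approx(100.0, abs=1e-12)
        assert by_conc[10.0] == pytest.approx(50.0, abs=1e-12)
        assert by_conc[100.0] == pytest.approx(0.0, abs=1e-12)

    def test_replicates_averaged_after_normalization(self):
        reads = _reads([800.0, 600.0], [10.0, 10.0])
        matrix = normalize_viability(reads, baseline_rule=0.0)
        assert matrix.values[matrix.conc_a_nM == 10.0, 0] == pytest.approx(70.0)

    def test_top_k_baseline_uses_most_inhibited_wells(self):
        grid = PRESET_GRIDS["matrix14"]
        reads = make_plate_reads((-7.5, 1.5), (-7.5, 1.5), grid, grid, noise_cv=0.0)
        matrix = normalize_viability(reads)
        # the plateau estimate is the mean of the 3 highest-total-conc wells
        treated = reads[reads["role"] == "treated"].copy()
        treated["total"] = treated["conc_a_nM"] + treated["conc_b_nM"]
        top3 = treated.nlargest(3, "total")
        assert matrix.provenance["baseline"] == pytest.approx(top3["signal"].mean())

    def test_no_vehicle_wells_rejected(self):
        reads = _reads([500.0], [10.0])
        with pytest.raises(ValueError):
            normalize_viability(reads[reads["role"] == "treated"])

    def test_failed_assay_rejected(self):
        reads = _reads([2000.0], [10.0])  # "plateau" above vehicle
        with pytest.raises(ValueError):
            normalize_viability(reads, baseline_rule=1500.0)


class TestFit:
    def test_noiseless_selfconsistency(self):
        conc = PRESET_GRIDS["matrix14"] * 1e-9
        y = four_pl(np.log10(conc), -7.0, 1.0)
        fit = fit_dose_response(conc, y)
        assert fit.converged
        assert fit.log10_ic50 == pytest.approx(-7.0, abs=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_of_fitted_curve_is_50(self):
        conc = PRESET_GRIDS["matrix14"] * 1e-9
        rng = np.random.default_rng(0)
        y = four_pl(np.log10(conc), -6.5, 1.4) + rng.normal(0, 2, conc.size)
        fit = fit_dose_response(conc, y)
        assert fit.predict([fit.ic50_molar])[0] == pytest.approx(50.0, abs=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self):
        grid = PRESET_GRIDS["matrix14"]
        reads = make_plate_reads((-7.0, 1.0), None, grid, noise_cv=0.05, seed=1)
        matrix = normalize_viability(reads, baseline_rule=20_000.0)
        curve = extract_curve(matrix, "row_a_mono")
        conc = curve["conc_nM"].to_numpy() * 1e-9
        y = curve["viability_pct"].to_numpy()
        fit = fit_dose_response(conc, y)
        assert abs(fit.log10_ic50 + 7.0) < 0.1
        # brute-force grid search over (log10_ic50, slope) minimizing SSE
        lg, sg = np.meshgrid(np.linspace(-8.5, -5.5, 301), np.linspace(0.3, 3.0, 136))
        sse = np.array(
            [
                np.sum((four_pl(np.log10(conc), a, b) - y) ** 2)
                for a, b in zip(lg.ravel(), sg.ravel())
            ]
        )
        best = np.argmin(sse)
        assert fit.log10_ic50 == pytest.approx(lg.ravel()[best], abs=0.01)
        assert fit.hill_slope == pytest.approx(sg.ravel()[best], abs=0.02)
        assert fit.rss <= sse[best] + 1e-9

    def test_flat_response_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response(np.array([1e-9, 1e-8, 1e-7, 1e-6]), np.full(4, 50.0))

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response(np.array([1e-9, 1e-8, 1e-7]), np.array([90.0, 50.0, 10.0]))


class TestDeltaIC50:
    def _fit(self, log_ic50):
        conc = PRESET_GRIDS["matrix14"] * 1e-9
        return fit_dose_response(conc, four_pl(np.log10(conc), log_ic50, 1.0))

    def test_identical_fits_give_zero(self):
        f = self._fit(-7.0)
        assert delta_ic50(f, f) == 0.0

    def test_two_decade_shift(self):
        assert delta_ic50(self._fit(-6.0), self._fit(-8.0)) == pytest.approx(2.0, abs=1e-6)

    def test_antisymmetry(self):
        a, b = self._fit(-6.3), self._fit(-7.9)
        assert delta_ic50(a, b) == pytest.approx(-delta_ic50(b, a))


class TestBliss:
    def _matrix(self, values, conc=None):
        conc = conc if conc is not None else np.array([0.0, 10.0, 100.0, 1000.0])
        return DoseMatrix(values, conc, conc)

    def test_independent_surface_scores_zero(self):
        fa = np.array([0.0, 0.2, 0.5, 0.9])
        v = 100 * np.outer(1 - fa, 1 - fa)
        scores = bliss_excess(self._matrix(v)).scores
        assert np.max(np.abs(scores)) < 1e-12

    def test_excess_over_zero_monotherapies(self):
        v = np.full((2, 2), 100.0)
        v[1, 1] = 70.0  # combo kills 30% though monotherapies kill nothing
        matrix = DoseMatrix(v, np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        assert bliss_excess(matrix).scores[1, 1] == pytest.approx(0.3)

    def test_scores_match_direct_formula_oracle(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 110, (4, 4))
        v[0, 0] = 100.0
        matrix = self._matrix(v)
        scores = bliss_excess(matrix).scores
        for i in range(1, 4):
            for j in range(1, 4):
                fa = min(max(1 - v[i, 0] / 100, 0), 1)
                fb = min(max(1 - v[0, j] / 100, 0), 1)
                obs = min(max(1 - v[i, j] / 100, 0), 1)
                assert scores[i, j] == pytest.approx(obs - (fa + fb - fa * fb))

    def test_injected_excess_recovered(self):
        grid = PRESET_GRIDS["matrix14"]
        for delta in (0.1, 0.2, 0.3):
            reads = make_plate_reads((-7.0, 1.0), (-7.0, 1.0), grid, grid,
                                     bliss_excess=delta, noise_cv=0.0)
            matrix = normalize_viability(reads, baseline_rule=20_000.0)
            scores = bliss_excess(matrix).scores
            # at cells where the independent viability exceeds delta the
            # generator did not clip and the score equals delta exactly
            va = 1 / (1 + (matrix.conc_a_nM[1:] * 1e-9 / 1e-7))
            unclipped = np.outer(va, va) >= delta
            assert np.allclose(scores[1:, 1:][unclipped], delta, atol=1e-9)

    def test_missing_monotherapy_axes_rejected(self):
        matrix = DoseMatrix(np.ones((2, 2)), np.array([1.0, 10.0]), np.array([1.0, 10.0]))
        with pytest.raises(ValueError):
            bliss_excess(matrix)


class TestSmoothing:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(5)
        m = DoseMatrix(rng.uniform(0, 100, (4, 4)),
                       np.array([0, 1, 10, 100.0]), np.array([0, 1, 10, 100.0]))
        assert np.array_equal(smooth_matrix(m, 1).values, m.values)

    def test_constant_matrix_unchanged(self):
        m = DoseMatrix(np.full((5, 5), 42.0), np.arange(5.0), np.arange(5.0))
        assert np.allclose(smooth_matrix(m, 3).values, 42.0)

    def test_center_cell_is_mean_of_neighborhood(self):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        m = DoseMatrix(vals, np.arange(3.0), np.arange(3.0))
        assert smooth_matrix(m, 3).values[1, 1] == pytest.approx(vals.mean())

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(-0.5, 0.5, (6, 6))
        b = BlissMatrix(scores, np.arange(6.0), np.arange(6.0))
        out = smooth_matrix(b, 5).scores
        assert out.min() >= scores.min() - 1e-12
        assert out.max() <= scores.max() + 1e-12

    def test_even_window_rejected(self):
        m = DoseMatrix(np.ones((2, 2)), np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            smooth_matrix(m, 2)


class TestCurveExtraction:
    def _full_matrix(self):
        grid = PRESET_GRIDS["matrix14"]
        reads = make_plate_reads((-7.0, 1.0), (-6.5, 1.2), grid, grid, noise_cv=0.0)
        return normalize_viability(reads, baseline_rule=20_000.0), grid

    def test_equimolar_diagonal_has_full_length(self):
        matrix, grid = self._full_matrix()
        diag = extract_curve(matrix, "fixed_ratio_diagonal", 0.0)
        assert len(diag) == 14
        assert np.allclose(diag["conc_nM"], grid)
        assert np.allclose(diag["conc_b_nM"], grid)

    def test_offset_returns_representable_subset(self):
        conc = np.concatenate([[0.0], np.logspace(0, 2, 5)])  # 2 decades, step 0.5
        vals = np.random.default_rng(7).uniform(0, 100, (6, 6))
        matrix = DoseMatrix(vals, conc, conc)
        diag = extract_curve(matrix, "fixed_ratio_diagonal", -2.0)
        assert len(diag) == 1  # only the (100, 1) pairing exists
        assert diag["conc_nM"].iloc[0] == pytest.approx(100.0)

    def test_unrepresentable_offset_rejected(self):
        matrix, _ = self._full_matrix()
        with pytest.raises(ValueError):
            extract_curve(matrix, "fixed_ratio_diagonal", -1.7)

    def test_monotherapy_row_equals_generating_4pl(self):
        matrix, grid = self._full_matrix()
        row = extract_curve(matrix, "row_a_mono")
        expected = four_pl(np.log10(grid * 1e-9), -7.0, 1.0)
        assert np.allclose(row["viability_pct"], expected, atol=1e-9)
        col = extract_curve(matrix, "col_b_mono")
        expected_b = four_pl(np.log10(grid * 1e-9), -6.5, 1.2)
        assert np.allclose(col["viability_pct"], expected_b, atol=1e-9)
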