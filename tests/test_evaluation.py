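"""Screening statistics: ANOVA p, oriented AUC, grid scans, summaries."""

import numpy as np
import pytest

from eegmarkers import CohortSpec, anova_p, auc, generate_cohort
from eegmarkers.evaluation import (default_grid, electrode_summary,
                                   evaluate_measure, scan_parameters,
                                   validate_group_pair)


class TestAnova:
    def test_identical_groups_give_p_one(self):
        assert anova_p([0, 1], [0, 1]) == pytest.approx(1.0)

    def test_two_point_groups_closed_form(self):
        # SSB = 4, SSW = 1, df = (1, 2) -> F = 8, upper tail 0.1056
        assert anova_p([1, 2], [3, 4]) == pytest.approx(0.10557, abs=1e-4)

    def test_scale_invariance(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10) + 0.5
        assert anova_p(10 * a, 10 * b) == pytest.approx(anova_p(a, b), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_p([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            anova_p([2.0, 2.0], [2.0, 2.0])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3], [4, 5, 6]) == pytest.approx(1.0)

    def test_interleaved_pairs(self):
        assert auc([1, 3], [2, 4]) == pytest.approx(0.75)

    def test_orientation_symmetry(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(12) + 1
        assert auc(a, b) == pytest.approx(auc(b, a))
        assert auc(a, b) >= 0.5

    def test_null_distribution_near_half(self, rng):
        a = rng.standard_normal(10_000)
        b = rng.standard_normal(10_000)
        assert auc(a, b) == pytest.approx(0.5, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestGroupPairValidation:
    def test_mixed_eye_condition_rejected(self):
        with pytest.raises(ValueError, match="eye"):
            validate_group_pair(("A", "D"))

    @pytest.mark.parametrize("pair", [("A", "C"), ("B", "D")])
    def test_study_pairs_accepted(self, pair):
        assert validate_group_pair(pair) == pair


class TestGrids:
    def test_entropy_grid_matches_study_protocol(self):
        grid = default_grid("qe")
        assert len(grid) == 40
        rs = sorted({g["r"] for g in grid})
        assert rs[0] == pytest.approx(0.05) and rs[-1] == pytest.approx(1.0)
        assert {g["m"] for g in grid} == {1, 2}

    def test_quantile_grid_fixed_q_lag_scan(self):
        grid = default_grid("qg")
        assert [g["k"] for g in grid] == list(range(1, 26))
        assert all(g["Q"] == 20 for g in grid)

    def test_parameter_free_measures_get_single_point(self):
        assert default_grid("fd") == [{}]


class TestScan:
    def test_single_point_grid_returned(self, tiny_cohort):
        comp = scan_parameters(tiny_cohort, "fd", "original", ("A", "C"), "Fp1")
        assert comp.params == "" and len(comp.grid) == 1
        assert 0 < comp.p_value <= 1 and 0.5 <= comp.auc <= 1

    def test_empty_grid_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="grid"):
            scan_parameters(tiny_cohort, "qg", "original", ("A", "C"),
                            "Fp1", grid=[])

    def test_best_point_minimises_p(self, tiny_cohort):
        comp = scan_parameters(tiny_cohort, "qg", "original", ("A", "C"), "Fp1")
        assert comp.p_value == comp.grid["p_value"].min()

    def test_strong_effect_reaches_high_auc(self):
        """Quantile-graph jump length on the delta band separates a
        delta-shifted cohort with AUC >= 0.9 at the best grid point."""
        from eegmarkers import effect_spec
        spec = effect_spec(0.5, n_healthy=16, n_ad=16, n_channels=1, seed=42)
        records = generate_cohort(spec)
        comp = scan_parameters(records, "qg", "delta", ("A", "C"), "Fp1")
        assert comp.auc >= 0.9


class TestElectrodeSummary:
    def test_mean_p_over_electrodes(self, tiny_cohort):
        comps = evaluate_measure(tiny_cohort, "fd", "original", ("A", "C"))
        table, mean_p = electrode_summary(comps)
        assert len(table) == 1  # single-channel cohort
        assert mean_p == pytest.approx(table["p_value"].mean())

    def test_missing_electrode_named(self, tiny_cohort):
        comps = evaluate_measure(tiny_cohort, "fd", "original", ("A", "C"))
        with pytest.raises(ValueError, match="O2"):
            electrode_summary(comps, electrodes=("Fp1", "O2"))


class TestNullCalibration:
    def test_false_positive_rate_under_exact_null(self):
        """Zero-effect cohorts: the fraction of p < 0.05 over 200 replicate
        comparisons stays within 0.05 +/- 0.02."""
        hits = 0
        for rep in range(200):
            spec = CohortSpec(n_healthy=10, n_ad=10, n_channels=1,
                              delta_shift=0.0, autocorr_boost=0.0,
                              seed=5000 + rep)
            records = generate_cohort(spec)
            comp = scan_parameters(records, "fd", "original", ("A", "C"), "Fp1")
            hits += comp.p_value < 0.05
        assert abs(hits / 200 - 0.05) <= 0.02


class TestCoherenceScreening:
    def test_pairwise_screening_and_classification_path(self):
        """Coherence is screened per electrode pair; the best pair's
        per-subject summaries feed the classifier without error."""
        from eegmarkers import RunConfig, run_pipeline
        spec = CohortSpec(n_healthy=5, n_ad=5, n_channels=3, seed=31)
        records = generate_cohort(spec)
        comps = evaluate_measure(records, "wc", "original", ("A", "C"),
                                 coherence_pairs=[("Fp1", "Fp2"), ("Fp1", "F3")])
        assert {c.electrode for c in comps} == {"Fp1-Fp2", "Fp1-F3"}
        assert all(0.5 <= c.auc <= 1.0 and 0.0 < c.p_value <= 1.0
                   for c in comps)
        config = RunConfig(spec=spec, measures=("wc",), bands=("original",),
                           group_pairs=(("A", "C"),), k_folds=3, seed=31,
                           coherence_pairs=(("Fp1", "Fp2"), ("Fp1", "F3")))
        result = run_pipeline(config)
        assert list(result.classification_table["measure"]) == ["wc"]
        assert result.best_table.iloc[0]["electrode"] in ("Fp1-Fp2", "Fp1-F3")
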