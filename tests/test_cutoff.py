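"""Median CIs, Monte-Carlo decoy FDR and the optimal-cutoff rule."""

import numpy as np
import pandas as pd
import pytest

import apmscreen as aps
from apmscreen.cutoff import DEFAULT_CUTOFF_GRID, _choose_c
from conftest import evidence_frame, toy_ontology_for_truth


class TestMedianCI:
    def test_closed_form_one_to_nine(self):
        lb, ub = aps.median_ci(range(1, 10), 0.05, 1.386)
        assert (ub - lb) / 2 == pytest.approx(1.7111, abs=1e-4)
        assert lb == pytest.approx(3.2889, abs=1e-4)
        assert ub == pytest.approx(6.7111, abs=1e-4)

    def test_conservative_coefficient(self):
        lb, ub = aps.median_ci(range(1, 10), 0.05, 1.960)
        assert (ub - lb) / 2 == pytest.approx(2.4198, abs=1e-4)

    def test_single_value_degenerates_to_point(self):
        assert aps.median_ci([3.5]) == (3.5, 3.5)

    def test_width_halves_when_n_quadruples(self):
        base = list(range(1, 10))
        lb1, ub1 = aps.median_ci(base)
        lb4, ub4 = aps.median_ci(base * 4)  # same median and IQR, 4x the n
        assert (ub1 - lb1) / (ub4 - lb4) == pytest.approx(2.0)

    def test_validation(self):
        with pytest.raises(aps.ValidationError):
            aps.median_ci([])
        with pytest.raises(aps.ValidationError):
            aps.median_ci([1, 2], c_coef=2.5)

    def test_choose_c_escalates_on_dissimilar_groups(self):
        assert _choose_c(10, 10, 1.0, 1.0) == 1.386
        assert _choose_c(10, 30, 1.0, 1.0) == 1.960
        assert _choose_c(10, 10, 1.0, 2.5) == 1.960


def _cs_table(scores):
    frame = pd.DataFrame({"p_bait": np.abs(scores), "p_control": 0.0,
                          "cs": np.asarray(scores, float)},
                         index=pd.Index([f"P{i}" for i in range(len(scores))],
                                        name="protein_id"))
    return aps.scoring.ConfidenceScoreTable(frame=frame)


class TestEstimateFdrCurve:
    def _null_world(self, seed=5):
        cfg = aps.SynthConfig(k_bait=8, k_control=40, n_specific=0,
                              outlier_fraction=0.0,
                              contaminant_inclusion_range=(0.1, 0.6),
                              reliable_inclusion_threshold=0.5, seed=seed)
        bait, control, _ = aps.generate_apms(cfg)
        res = aps.InteractionScreen(bait, control, adjust_pmin=True).fit(
            cs_cutoff=0.15, seed=seed)
        return bait, control, res

    def test_no_decoy_discovery_means_zero_fdr(self):
        # control too weak to ever produce a decoy prey above the threshold:
        # all control scores fall below the prefilter threshold
        control_ev = evidence_frame([(f"C{k}", f"X{j}", "PEPK", 5.0)
                                     for k in range(4) for j in range(6)])
        bait_cs = _cs_table([0.9, 0.8, 0.5])
        ctrl_marg = aps.InclusionTable("R", pd.Series(dtype=float), 1)
        curve = aps.estimate_fdr_curve(
            bait_cs, control_ev, [f"C{k}" for k in range(4)], ctrl_marg,
            n_bait_universe=3, k_bait=2, mst_control=25.0, p_min=0.75,
            n_mc=5, seed=0)
        assert (curve.fp_hat == 0).all()
        assert (curve.fdr_hat == 0).all()

    def test_pure_contaminant_bait_pushes_fdr_to_one(self):
        bait, control, res = self._null_world()
        curve = aps.estimate_fdr_curve(
            res.cs_table, control.evidence, control.replicate_ids,
            res.side_control.r_marginals, n_bait_universe=res.side_bait.n_naive,
            k_bait=bait.k, mst_control=res.mst_control, p_min=0.75,
            n_mc=50, seed=5)
        small = curve.cutoff_grid <= 0.05
        assert np.all(curve.fdr_hat[small] >= 0.7)

    def test_fp_hat_non_increasing_in_cutoff(self):
        bait, control, res = self._null_world(seed=6)
        curve = aps.estimate_fdr_curve(
            res.cs_table, control.evidence, control.replicate_ids,
            res.side_control.r_marginals, n_bait_universe=res.side_bait.n_naive,
            k_bait=bait.k, mst_control=res.mst_control, p_min=0.75,
            n_mc=20, seed=6)
        assert (np.diff(curve.fp_hat) <= 1e-12).all()

    def test_deterministic_decoy_matches_single_screen(self):
        """With the decoy sample forced to the whole control (universe size =
        sample size, replicate count = k_bait), every Monte-Carlo replicate is
        the same deterministic screen; the estimate must equal its count."""
        cfg = aps.SynthConfig(k_bait=6, k_control=6, n_specific=0,
                              outlier_fraction=0.0,
                              contaminant_inclusion_range=(0.3, 0.9),
                              reliable_inclusion_threshold=0.5, seed=9)
        bait, control, _ = aps.generate_apms(cfg)
        res = aps.InteractionScreen(bait, control, adjust_pmin=True).fit(
            cs_cutoff=0.15, seed=9)
        decoy = aps.engine.screen_side(control.evidence, control.replicate_ids,
                                       "bait", mst=res.mst_control, p_min=0.75,
                                       adjust_pmin=True)
        cs = aps.confidence_scores(decoy.r_marginals, res.side_control.r_marginals,
                                   decoy.r_set)
        expected = np.array([cs.discoveries(c) for c in DEFAULT_CUTOFF_GRID],
                            dtype=float)
        curve = aps.estimate_fdr_curve(
            res.cs_table, control.evidence, control.replicate_ids,
            res.side_control.r_marginals,
            n_bait_universe=control.evidence["protein_id"].nunique(),
            k_bait=6, mst_control=res.mst_control, p_min=0.75, n_mc=2, seed=1)
        assert np.allclose(curve.fp_hat, expected)

    def test_nmc_validated(self):
        with pytest.raises(aps.ValidationError):
            aps.estimate_fdr_curve(_cs_table([0.5]), evidence_frame([]), [],
                                   aps.InclusionTable("R", pd.Series(dtype=float), 1),
                                   1, 1, 25.0, 0.75, n_mc=0)


class TestSimilarityDistanceCurve:
    def _setup(self, tmp_path, seed=4):
        bait, control, truth = aps.generate_apms(aps.SynthConfig(seed=seed))
        ont = toy_ontology_for_truth(truth, tmp_path)
        res = aps.InteractionScreen(bait, control, ont, adjust_pmin=True).fit(
            cs_cutoff=0.15, seed=seed)
        return res, ont

    def test_enriched_selection_separates(self, tmp_path):
        """Planted preys share the bait's deep annotation, the naive pool is
        dominated by unrelated contaminants: the CI distance is positive."""
        res, ont = self._setup(tmp_path)
        curve = aps.similarity_distance_curve(
            ont, "BAIT", res.side_bait.matrix.proteins, res.cs_table,
            grid=(0.05, 0.15), b_reps=64, seed=0)
        assert np.all(curve.d[~np.isnan(curve.d)] > 0)

    def test_null_selection_does_not_separate(self, tmp_path):
        """A selection identical to the naive pool carries no coherence gain:
        both CIs share the same center, so the gap is -2h <= 0."""
        res, ont = self._setup(tmp_path)
        proteins = res.side_bait.matrix.proteins
        fake = _cs_table([0.5] * len(proteins))
        fake.frame.index = pd.Index(proteins, name="protein_id")
        curve = aps.similarity_distance_curve(
            ont, "BAIT", proteins, fake, grid=(0.1,), b_reps=64, seed=2)
        assert curve.d[0] <= 0

    def test_d_is_ci_gap(self, tmp_path):
        res, ont = self._setup(tmp_path)
        curve = aps.similarity_distance_curve(
            ont, "BAIT", res.side_bait.matrix.proteins, res.cs_table,
            grid=(0.05, 0.1, 0.15), b_reps=32, seed=3)
        for i in range(len(curve.cutoff_grid)):
            if not np.isnan(curve.d[i]):
                assert curve.d[i] == pytest.approx(
                    curve.ci_s[i, 0] - curve.ci_n[i, 1])

    def test_empty_selection_yields_missing_d(self, tmp_path):
        res, ont = self._setup(tmp_path)
        empty = _cs_table([])
        curve = aps.similarity_distance_curve(
            ont, "BAIT", res.side_bait.matrix.proteins, empty,
            grid=(0.1,), b_reps=8, seed=0)
        assert np.isnan(curve.d[0])


class TestEstimateOptimalCutoff:
    def _fdr(self, grid, fdr_vals, disc=None):
        grid = np.asarray(grid, float)
        fdr_vals = np.asarray(fdr_vals, float)
        disc = np.where(np.isnan(fdr_vals), 0, 10) if disc is None else disc
        return aps.FdrCurve(grid, fdr_vals * 10, disc, fdr_vals,
                            np.zeros(len(grid)), 10, 0)

    def _d(self, grid, d_vals):
        grid = np.asarray(grid, float)
        n = len(grid)
        return aps.SimilarityDistanceCurve(grid, np.asarray(d_vals, float),
                                           np.zeros((n, 2)), np.zeros((n, 2)),
                                           8, 0.05, np.full(n, 1.386))

    def test_unique_minimum_with_positive_d(self):
        grid = (0.05, 0.10, 0.15, 0.20)
        est = aps.estimate_optimal_cutoff(
            self._fdr(grid, [0.4, 0.2, 0.0, 0.1]),
            self._d(grid, [-0.1, 0.0, 0.005, 0.002]))
        assert est.cs_cutoff_hat == 0.15
        assert not est.no_positive_d

    def test_fdr_ties_broken_by_largest_d(self):
        grid = (0.05, 0.10)
        est = aps.estimate_optimal_cutoff(self._fdr(grid, [0.0, 0.0]),
                                          self._d(grid, [0.01, 0.05]))
        assert est.cs_cutoff_hat == 0.10

    def test_no_positive_d_falls_back_with_warning_flag(self):
        grid = (0.05, 0.10, 0.15)
        est = aps.estimate_optimal_cutoff(self._fdr(grid, [0.3, 0.1, 0.2]),
                                          self._d(grid, [-0.2, -0.1, -0.3]))
        assert est.cs_cutoff_hat == 0.10
        assert est.no_positive_d

    def test_tie_without_similarity_curve_prefers_specificity(self):
        grid = (0.05, 0.10, 0.15)
        est = aps.estimate_optimal_cutoff(self._fdr(grid, [0.0, 0.0, 0.0]), None)
        assert est.cs_cutoff_hat == 0.15
        assert est.no_positive_d

    def test_all_missing_fdr_is_an_error(self):
        grid = (0.05, 0.10)
        with pytest.raises(aps.EstimationError):
            aps.estimate_optimal_cutoff(self._fdr(grid, [np.nan, np.nan]), None)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(aps.ValidationError):
            aps.estimate_optimal_cutoff(self._fdr((0.1, 0.2), [0.1, 0.2]),
                                        self._d((0.1,), [0.0]))
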