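import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from exomarker.biomarker import (
    FocusCriteria,
    MarkerEvaluator,
    OrRulePanel,
    auc,
    combine_markers_or_rule,
    combined_rank_score_auc,
    exclusion_filter,
    focus_list_filter,
    full_specificity_threshold,
    roc_points,
    round_percent,
    sensitivity_at_full_specificity,
    symmetric_effect,
    youden_threshold,
)
from exomarker.synthetic import generate_worked_example_fixture

from oracles import exhaustive_youden, pairwise_auc


class TestFullSpecificityThreshold:
    def test_threshold_is_control_maximum(self):
        th = full_specificity_threshold([1.0, 2.0, 3.0])
        assert th == 3.0
        assert not (3.0 > th)       # value at the threshold is negative
        assert 3.1 > th             # strictly above is positive

    def test_all_undetected_controls_give_zero(self):
        # positivity then reduces to detection itself
        assert full_specificity_threshold([0.0] * 15) == 0.0

    def test_specificity_is_exactly_one(self, rng):
        controls = rng.lognormal(0, 2, 15)
        th = full_specificity_threshold(controls)
        assert (controls > th).sum() == 0

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            full_specificity_threshold([])


class TestSensitivity:
    @pytest.mark.parametrize("count,percent", [
        (15, 94), (13, 81), (12, 75), (11, 69), (10, 63), (9, 56), (8, 50),
        (0, 0),
    ])
    def test_percent_of_sixteen_patients(self, count, percent):
        patients = [2.0] * count + [0.5] * (16 - count)
        frac, n_pos, pct = sensitivity_at_full_specificity(patients, 1.0, 16)
        assert n_pos == count
        assert frac == pytest.approx(count / 16)
        assert pct == percent

    def test_rounding_is_half_away_from_zero(self):
        assert round_percent(0.625) == 63      # 62.5
        assert round_percent(0.6875) == 69     # 68.75
        assert round_percent(0.5625) == 56     # banker's rounding would err


class TestYouden:
    def test_perfect_separation(self):
        th, j = youden_threshold([1.0, 2.0], [3.0, 4.0])
        assert j == 1.0
        assert 2.0 < th < 3.0

    def test_identical_distributions(self):
        _, j = youden_threshold([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert j == 0.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            c = np.round(rng.normal(0, 1, rng.integers(2, 9)), 1)
            p = np.round(rng.normal(0.8, 1, rng.integers(2, 9)), 1)
            th, j = youden_threshold(c, p)
            assert j == pytest.approx(exhaustive_youden(c, p), abs=1e-12)
            # the returned threshold actually attains J
            attained = (p > th).mean() + (c <= th).mean() - 1.0
            assert attained == pytest.approx(j, abs=1e-12)

    def test_at_least_full_specificity_J(self, rng):
        c = rng.normal(0, 1, 10)
        p = rng.normal(1, 1, 12)
        _, j = youden_threshold(c, p)
        th_full = full_specificity_threshold(c)
        j_full = (p > th_full).mean() + (c <= th_full).mean() - 1.0
        assert j >= j_full - 1e-12


class TestRocAuc:
    def test_perfect_separation_contains_corner(self):
        pts = roc_points([1.0, 2.0], [3.0, 4.0])
        assert (0.0, 1.0) in pts
        assert auc([1.0, 2.0], [3.0, 4.0]) == 1.0

    def test_single_values(self):
        assert roc_points([1.0], [2.0]) == [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]

    def test_monotone_staircase_from_origin_to_corner(self, rng):
        c = rng.normal(0, 1, 9)
        p = rng.normal(1, 1, 11)
        pts = roc_points(c, p)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        arr = np.array(pts)
        assert (np.diff(arr[:, 0]) >= 0).all()
        assert (np.diff(arr[:, 1]) >= -1e-12).all()

    def test_all_ties_give_half(self):
        assert auc([5.0] * 4, [5.0] * 6) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(1, 13), rng.integers(1, 13)
            c = np.round(rng.normal(0, 1, n1), 1)   # rounding forces ties
            p = np.round(rng.normal(0.5, 1, n2), 1)
            assert auc(c, p) == pytest.approx(pairwise_auc(c, p), abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self, rng):
        c = rng.normal(0, 1, 8)
        p = rng.normal(1, 1, 10)
        assert auc(c, p) + auc(p, c) == pytest.approx(1.0, abs=1e-12)


class TestPanelCombination:
    def test_or_rule_reaches_full_sensitivity(self):
        # marker A positive on patients 1..15, marker B on patient 16 only
        pat_a = [2.0] * 15 + [0.0]
        pat_b = [0.0] * 15 + [2.0]
        ctr = [0.5] * 15
        sens, spec = combine_markers_or_rule(
            {"A": 1.0, "B": 1.0},
            {"A": pat_a, "B": pat_b},
            {"A": ctr, "B": ctr},
        )
        assert sens == 1.0 and spec == 1.0

    def test_self_combination_idempotent(self):
        pat = [2.0] * 10 + [0.0] * 6
        ctr = [0.5] * 15
        sens, _ = combine_markers_or_rule(
            {"A": 1.0, "A2": 1.0}, {"A": pat, "A2": pat},
            {"A": ctr, "A2": ctr})
        assert sens == pytest.approx(10 / 16)

    def test_never_below_best_single_marker(self, rng):
        for _ in range(50):
            ctr = {m: rng.lognormal(0, 1, 15) for m in "AB"}
            pat = {m: rng.lognormal(0.5, 1, 16) for m in "AB"}
            th = {m: full_specificity_threshold(ctr[m]) for m in "AB"}
            sens, spec = combine_markers_or_rule(th, pat, ctr)
            singles = [
                sensitivity_at_full_specificity(pat[m], th[m])[0] for m in "AB"
            ]
            assert sens >= max(singles) - 1e-12
            assert spec == 1.0

    def test_rank_score_auc_identical_markers(self, rng):
        vals = rng.normal(0, 1, 20)
        labels = np.array([0] * 10 + [1] * 10)
        combined = combined_rank_score_auc({"A": vals, "B": vals}, labels)
        assert combined == pytest.approx(auc(vals[:10], vals[10:]))

    def test_rank_score_auc_perfect_pair(self):
        labels = np.array([0] * 5 + [1] * 5)
        a = np.concatenate([np.arange(5), 10 + np.arange(5.0)])
        combined = combined_rank_score_auc({"A": a, "B": a * 2}, labels)
        assert combined == 1.0

    def test_complementary_markers_usually_improve_auc(self, rng):
        """Markers elevated in disjoint patient subsets: the pooled rank
        score recovers both subsets, beating either marker alone."""
        wins = 0
        n_trials = 200
        for _ in range(n_trials):
            labels = np.array([0] * 10 + [1] * 10)
            a = rng.normal(0, 0.5, 20)
            b = rng.normal(0, 0.5, 20)
            a[10:15] += 3.0    # marker A flags patients 1-5
            b[15:20] += 3.0    # marker B flags patients 6-10
            combined = combined_rank_score_auc({"A": a, "B": b}, labels)
            best = max(auc(a[:10], a[10:]), auc(b[:10], b[10:]))
            wins += combined >= best
        assert wins / n_trials >= 0.95


class TestFocusList:
    def _table(self):
        return pd.DataFrame({
            "lfq_and_ibaq_significant": [True, True, True, False],
            "sensitivity_full_spec": [0.56, 0.40, 0.50, 0.90],
            "ibaq_ratio": [2.1, 3.0, 0.48, 5.0],
        }, index=["keep_up", "low_sens", "keep_down", "not_sig"])

    def test_three_criteria_and_ordering(self):
        out = focus_list_filter(self._table())
        assert list(out.index) == ["keep_up", "keep_down"]
        # down-regulation counted symmetrically: 1/0.48 = 2.08 >= 1.75
        assert out.loc["keep_down", "effect"] == pytest.approx(1 / 0.48)

    def test_boundary_fold_change_inclusive(self):
        tbl = pd.DataFrame({
            "lfq_and_ibaq_significant": [True, True],
            "sensitivity_full_spec": [0.56, 0.50],
            "ibaq_ratio": [1.75, 0.5714285714285714],  # exactly the bound
        }, index=["up_edge", "down_edge"])
        out = focus_list_filter(tbl)
        assert set(out.index) == {"up_edge", "down_edge"}

    def test_missing_columns_reported(self):
        with pytest.raises(KeyError, match="ibaq_ratio"):
            focus_list_filter(pd.DataFrame({
                "lfq_and_ibaq_significant": [True],
                "sensitivity_full_spec": [0.9]}))

    def test_infinite_ratio_is_kept(self):
        tbl = pd.DataFrame({
            "lfq_and_ibaq_significant": [True],
            "sensitivity_full_spec": [0.75],
            "ibaq_ratio": [np.inf],
        }, index=["unique"])
        assert list(focus_list_filter(tbl).index) == ["unique"]

    def test_symmetric_effect(self):
        assert symmetric_effect(4.0) == 4.0
        assert symmetric_effect(0.25) == 4.0
        assert symmetric_effect(np.inf) == np.inf


class TestExclusionFilter:
    def test_confounder_removed_and_reported(self):
        tbl = pd.DataFrame({"x": [1, 2]}, index=["lactotransferrin", "tm256"])
        out, removed = exclusion_filter(tbl, {"lactotransferrin"})
        assert removed == ["lactotransferrin"]
        assert list(out.index) == ["tm256"]

    def test_empty_and_disjoint_sets_are_identity(self):
        tbl = pd.DataFrame({"x": [1]}, index=["a"])
        for conf in (set(), {"zzz"}):
            out, removed = exclusion_filter(tbl, conf)
            assert removed == [] and list(out.index) == ["a"]


class TestMarkerEvaluator:
    @pytest.fixture(scope="class")
    def fitted(self):
        matrix, design = generate_worked_example_fixture()
        X = matrix.values.T
        y = (matrix.groups == "patient").astype(int).to_numpy()
        return MarkerEvaluator().fit(X, y), X, y

    def test_worked_example_percent_column(self, fitted):
        ev, _, _ = fitted
        expected = {"tm256-like": 94, "lamtor1-like": 81, "vatl-like": 75,
                    "steap4-like": 69, "arl8b-like": 63, "cldn10-like": 56,
                    "bdh2-like": 50}
        for marker, pct in expected.items():
            assert ev.results_.loc[marker, "percent_sensitivity"] == pct

    def test_detection_only_marker_threshold_zero(self, fitted):
        ev, _, _ = fitted
        assert ev.results_.loc["vatl-like", "threshold_full_spec"] == 0.0

    def test_heatmap_sums_reproduce_sensitivity_counts(self, fitted):
        ev, X, y = fitted
        heat = ev.transform(X)
        pat_sums = heat.loc[y == 1].sum(axis=0)
        assert (pat_sums == ev.results_["n_patients_positive"]).all()
        # controls are all-negative at full-specificity thresholds
        assert not heat.loc[y == 0].any().any()

    def test_sklearn_protocol(self, fitted):
        ev, X, y = fitted
        cloned = clone(ev)
        assert cloned.get_params() == {"threshold": "full_specificity"}
        cloned.set_params(threshold="youden").fit(X, y)
        heat = cloned.transform(X)
        assert heat.shape == X.shape


class TestOrRulePanel:
    def test_fit_predict_and_attributes(self):
        matrix, _ = generate_worked_example_fixture()
        X = matrix.values.T
        y = (matrix.groups == "patient").astype(int).to_numpy()
        clf = OrRulePanel(markers=["tm256-like", "lamtor1-like"]).fit(X, y)
        pred = clf.predict(X)
        assert clf.specificity_ == 1.0
        assert (pred[y == 0] == 0).all()
        assert clf.sensitivity_ >= 15 / 16
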