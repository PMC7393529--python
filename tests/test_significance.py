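"""Balanced-bootstrap OVA random forests and permutation significance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import facekin as fk
from facekin.config import RFConfig
from facekin.errors import InvalidArgumentError
from facekin.significance import (
    LabeledFeatureTable,
    _pearson_p,
    _stratified_split,
)

FAST = RFConfig(n_trees=40, min_leaf=5, r=60, n_bootstrap=3,
                importance_iterations=8, permutation_repeats=8, seed=5)


class TestOvaLabels:
    def test_binary_identity(self):
        y = np.array(["a", "b", "a"])
        assert np.array_equal(fk.make_ova_labels(y, "a"), [1, 0, 1])

    def test_four_class_counts(self):
        y = np.repeat([1, 2, 3, 4], 10)
        ova = fk.make_ova_labels(y, 2)
        assert ova.sum() == 10 and len(ova) - ova.sum() == 30

    def test_absent_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fk.make_ova_labels(np.array([1, 2]), 3)


class TestBalancedBootstrap:
    def test_exact_counts_per_class(self):
        y = np.array([0] * 7 + [1] * 90)
        idx = fk.balanced_bootstrap(y, 25, np.random.default_rng(0))
        assert len(idx) == 50
        assert (y[idx] == 0).sum() == 25 and (y[idx] == 1).sum() == 25

    def test_small_class_resampled_with_replacement(self):
        y = np.array([0, 0, 0] + [1] * 20)
        idx = fk.balanced_bootstrap(y, 10, np.random.default_rng(1))
        drawn = idx[y[idx] == 0]
        assert len(drawn) == 10 and set(drawn) <= {0, 1, 2}

    def test_deterministic_given_seed(self):
        y = np.repeat([0, 1], 30)
        a = fk.balanced_bootstrap(y, 15, np.random.default_rng(42))
        b = fk.balanced_bootstrap(y, 15, np.random.default_rng(42))
        assert np.array_equal(a, b)


def _gaussian_problem(n=500, informative_delta=3.0, n_features=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n, n_features))
    y = np.repeat([0, 1], n)
    X[y == 1, 0] += informative_delta
    return X, y


class TestTrainForest:
    def test_perfect_predictor_tops_ranking(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        X = rng.normal(0, 1, (300, 5))
        X[:, 3] = y  # feature identical to the label
        oob = fk.train_rf_oob(X, y, FAST)
        assert oob.oob_accuracy > 0.97
        assert oob.importances_.argmax() == 3

    def test_informative_gaussian_feature_recovered(self):
        X, y = _gaussian_problem()
        oob = fk.train_rf_oob(X, y, FAST)
        assert oob.oob_accuracy > 0.9
        assert oob.importances_.argmax() == 0

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fk.train_rf_oob(np.zeros((10, 3)), np.zeros(10, int), FAST)

    def test_oob_votes_match_naive_recount(self):
        # the incremental vote bookkeeping agrees with a from-scratch
        # majority vote over each row's out-of-bag trees
        X, y = _gaussian_problem(n=80, seed=3)
        oob = fk.train_rf_oob(X, y, FAST, compute_importance=False)
        for row in range(0, len(X), 17):
            trees = [t for t in range(len(oob.forest.estimators_))
                     if oob.oob_mask[t, row]]
            votes = [int(oob.forest.estimators_[t].predict(X[row:row + 1])[0])
                     for t in trees]
            expected = int(sum(votes) * 2 > len(votes))
            assert oob.oob_pred[row] == expected


class TestPermutationSignificance:
    def test_informative_feature_highly_significant(self):
        X, y = _gaussian_problem()
        oob = fk.train_rf_oob(X, y, FAST, compute_importance=False)
        p = fk.permutation_feature_significance(oob, 0, FAST,
                                                np.random.default_rng(0))
        assert p < 1e-3

    def test_never_split_feature_has_p_one(self):
        X, y = _gaussian_problem(n=200)
        X = np.column_stack([X, np.zeros(len(X))])  # constant: never split on
        oob = fk.train_rf_oob(X, y, FAST, compute_importance=False)
        j = X.shape[1] - 1
        assert j not in np.concatenate(oob.tree_features)
        p = fk.permutation_feature_significance(oob, j, FAST,
                                                np.random.default_rng(0))
        assert p == 1.0

    def test_out_of_range_feature_rejected(self):
        X, y = _gaussian_problem(n=50)
        oob = fk.train_rf_oob(X, y, FAST, compute_importance=False)
        with pytest.raises(InvalidArgumentError):
            fk.permutation_feature_significance(oob, 99, FAST)

    def test_closed_form_chi_square_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = rng.integers(1, 60, (2, 2)).astype(float)
            assert _pearson_p(t) == pytest.approx(
                chi2_contingency(t, correction=False)[1], abs=1e-12)


class TestBenjaminiHochberg:
    def test_flat_pvalues_unchanged(self):
        adj, flags = fk.benjamini_hochberg(np.full(10, 0.01))
        assert np.allclose(adj, 0.01)
        assert flags.all()

    def test_hand_computed_staircase(self):
        adj, flags = fk.benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)
        assert flags.all()

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        adj, _ = fk.benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)

    def test_flags_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.2, 30)
        _, lo = fk.benjamini_hochberg(p, alpha=0.03)
        _, hi = fk.benjamini_hochberg(p, alpha=0.10)
        assert np.all(hi[lo])  # raising alpha never removes a flag

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fk.benjamini_hochberg(np.array([0.1, 1.2]))


class TestLabeledTable:
    def test_missing_values_rejected(self):
        with pytest.raises(InvalidArgumentError):
            LabeledFeatureTable(X=np.array([[1.0, np.nan]]), y=np.array([1]))

    def test_single_row_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            LabeledFeatureTable(X=np.zeros((3, 2)), y=np.array([1, 1, 2]))

    def test_from_frame_selects_numeric_columns(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [0.1, 0.2, 0.3, 0.4],
                              "label": ["x", "x", "y", "y"]})
        table = LabeledFeatureTable.from_frame(frame, "label")
        assert table.feature_names == ["a", "b"]
        assert table.X.shape == (4, 2)

    def test_stratified_split_keeps_both_classes(self):
        y = np.repeat([0, 1], [20, 180])
        train, test = _stratified_split(y, 0.9, np.random.default_rng(0))
        assert set(y[train]) == {0, 1} and set(y[test]) == {0, 1}
        assert len(train) + len(test) == 200


class TestFullAnalysis:
    def test_planted_features_recovered_noise_ignored(self):
        table = fk.synth_feature_table(fk.FeatureTableSpec(
            n_classes=4, n_per_class=300, informative={1: [1, 5, 9]},
            effect_size=2.0, seed=21))
        cfg = RFConfig(n_trees=60, min_leaf=20, r=150, n_bootstrap=3,
                       importance_iterations=15, permutation_repeats=15, seed=2)
        res = fk.run_significance_analysis(table, cfg, classes=[1])
        flagged = set(res.significant_features(1))
        assert {"f01_head_max_raise", "f05_eyebrow_max_raise",
                "f09_lips_max_raise"} <= flagged
        assert len(flagged) <= 5  # at most sporadic noise flags

    def test_constant_feature_never_significant(self):
        table = fk.synth_feature_table(fk.FeatureTableSpec(
            n_classes=2, n_per_class=100, seed=3))
        table.X[:, 7] = 1.25  # identical across classes
        res = fk.run_significance_analysis(table, FAST, classes=[1])
        row = res.per_class[1].iloc[7]
        assert not row.significant and row.p_raw == 1.0

    def test_posthoc_reports_target_vs_rest_difference(self):
        table = fk.synth_feature_table(fk.FeatureTableSpec(
            n_classes=3, n_per_class=200, informative={2: [4]},
            effect_size=3.0, seed=5))
        cfg = RFConfig(n_trees=50, min_leaf=10, r=120, n_bootstrap=3,
                       importance_iterations=10, permutation_repeats=10, seed=4)
        res = fk.run_significance_analysis(table, cfg, classes=[2])
        post = res.posthoc
        assert (post["class"] == 2).all()
        row = post[post.feature == "f04_head_path_length"].iloc[0]
        assert row.difference == pytest.approx(3.0, abs=0.4)
        assert row.mean_target - row.mean_rest == pytest.approx(row.difference)

    def test_bit_reproducible_given_seed(self):
        table = fk.synth_feature_table(fk.FeatureTableSpec(
            n_classes=2, n_per_class=60, seed=6))
        a = fk.run_significance_analysis(table, FAST, classes=[1])
        b = fk.run_significance_analysis(table, FAST, classes=[1])
        pd.testing.assert_frame_equal(a.per_class[1], b.per_class[1])
        assert a.test_accuracy == b.test_accuracy

    def test_unknown_class_subset_rejected(self):
        table = fk.synth_feature_table(fk.FeatureTableSpec(
            n_classes=2, n_per_class=30, seed=7))
        with pytest.raises(InvalidArgumentError):
            fk.run_significance_analysis(table, FAST, classes=[9])
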