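"""Split, SMOTE, CV tuning, threshold selection, evaluation, importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pimddi.risk_model import (
    LeakageError,
    Threshold,
    evaluate,
    roc_auc_trapezoidal,
    select_threshold,
    smote,
    stratified_split,
    tune_and_train,
    variable_importance,
)


def _rows(n_pos, n_neg, seed=0, n_features=3):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    df = pd.DataFrame(
        rng.normal(size=(n, n_features)), columns=[f"x{i}" for i in range(n_features)]
    )
    df["flag"] = rng.integers(0, 2, n)
    df["outcome"] = [1] * n_pos + [0] * n_neg
    df["patient_id"] = [f"P{i}" for i in range(n)]
    return df


class TestStratifiedSplit:
    def test_proportions_preserved_within_one_patient(self):
        rows = _rows(171, 829)
        train, test = stratified_split(rows, 0.2, seed=3)
        assert len(train) == 800 and len(test) == 200
        assert abs(train["outcome"].mean() - 0.171) < 1 / len(test)
        assert abs(test["outcome"].mean() - 0.171) < 1 / len(test)

    def test_reproducible_under_fixed_seed(self):
        rows = _rows(50, 200)
        a1, b1 = stratified_split(rows, seed=9)
        a2, b2 = stratified_split(rows, seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_single_class_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            stratified_split(_rows(0, 100))


class TestSmote:
    def test_100_vs_20_becomes_100_vs_100(self):
        out = smote(_rows(20, 100), k_neighbors=5, seed=1)
        assert out["outcome"].value_counts().to_dict() == {0: 100, 1: 100}

    def test_already_balanced_input_returned_unchanged(self):
        rows = _rows(50, 50)
        pd.testing.assert_frame_equal(smote(rows, seed=1), rows)

    def test_minority_smaller_than_k_plus_one_is_an_error(self):
        with pytest.raises(ValueError, match="smaller k"):
            smote(_rows(4, 100), k_neighbors=5)

    def test_synthetic_points_lie_on_segments_between_near_minority_pairs(self):
        """Two well-separated minority clusters: every synthetic point must be
        a convex combination of two minority points of the same cluster."""
        rng = np.random.default_rng(2)
        a = rng.normal(loc=0.0, scale=0.1, size=(10, 2))
        b = rng.normal(loc=50.0, scale=0.1, size=(10, 2))
        minority = np.vstack([a, b])
        majority = rng.normal(loc=25.0, scale=0.1, size=(80, 2))
        df = pd.DataFrame(np.vstack([minority, majority]), columns=["x0", "x1"])
        df["outcome"] = [1] * 20 + [0] * 80
        out = smote(df, k_neighbors=5, seed=7)
        synth = out.iloc[100:][["x0", "x1"]].to_numpy()
        assert len(synth) == 60
        for p in synth:
            cluster = a if p[0] < 25 else b
            # oracle: p = u + t (v - u) for some same-cluster pair (u, v)
            on_segment = False
            for i in range(len(cluster)):
                for j in range(len(cluster)):
                    if i == j:
                        continue
                    u, v = cluster[i], cluster[j]
                    d = v - u
                    denom = float(d @ d)
                    t = float((p - u) @ d) / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(u + t * d - p) < 1e-8:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_binary_features_copied_not_interpolated(self):
        out = smote(_rows(20, 100, seed=3), seed=3)
        assert set(np.unique(out["flag"])) <= {0, 1}


class TestSelectThreshold:
    def test_perfectly_separating_scores_reach_distance_zero(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr = select_threshold(scores, labels)
        assert thr.distance == 0.0
        assert 0.2 < thr.value <= 0.8

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.integers(0, 1)),
            min_size=2,
            max_size=20,
        ).filter(lambda d: len({lab for _, lab in d}) == 2)
    )
    def test_equals_exhaustive_enumeration_on_small_inputs(self, data):
        """The selected cut-point matches brute-force search over all cuts."""
        scores = np.array([s for s, _ in data])
        labels = np.array([l for _, l in data])
        thr = select_threshold(scores, labels)
        # independent brute force
        pos, neg = labels == 1, labels == 0
        best = None
        for cut in sorted(set(scores)):
            pred = scores >= cut
            sens = (pred & pos).sum() / pos.sum()
            spec = (~pred & neg).sum() / neg.sum()
            d = np.hypot(1 - sens, 1 - spec)
            key = (d, -sens, cut)
            if best is None or key < best[0]:
                best = (key, cut, d)
        assert thr.value == best[1]
        assert thr.distance == pytest.approx(best[2])

    def test_constant_scores_warn_and_return_single_cut(self):
        with pytest.warns(UserWarning, match="constant"):
            thr = select_threshold(np.full(6, 0.5), np.array([0, 1, 0, 1, 0, 1]))
        assert thr.value == 0.5

    def test_one_class_labels_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class _ConstModel:
    """Minimal stand-in exposing predict_scores for evaluation tests."""

    family = "gradient_boosted_trees"

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def predict_scores(self, rows):
        return self._scores[: len(rows)]


class TestEvaluate:
    def test_perfect_scores_give_all_ones(self):
        test = pd.DataFrame({"outcome": [0, 0, 1, 1]})
        model = _ConstModel([0.1, 0.2, 0.8, 0.9])
        rep = evaluate(model, test, Threshold(0.5, "train"))
        assert rep.accuracy == rep.sensitivity == rep.specificity == rep.roc_auc == 1.0

    def test_reversed_scores_have_complementary_auc(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 200)
        scores = rng.random(200)
        auc = roc_auc_trapezoidal(labels, scores)
        assert roc_auc_trapezoidal(labels, -scores) == pytest.approx(1 - auc, abs=1e-9)

    def test_threshold_selected_on_test_is_refused(self):
        test = pd.DataFrame({"outcome": [0, 1]})
        with pytest.raises(LeakageError):
            evaluate(_ConstModel([0.1, 0.9]), test, Threshold(0.5, "test"))


class TestTuneAndTrain:
    def test_single_point_grid_returns_that_configuration(self):
        rows = _rows(30, 120, seed=8)
        fitted = tune_and_train(
            rows, "random_forest", grid=[{"n_estimators": 20, "max_depth": 3}],
            folds=3, seed=1,
        )
        assert fitted.best_params == {"n_estimators": 20, "max_depth": 3}
        assert len(fitted.cv_results) == 1

    def test_planted_deterministic_signal_reaches_cv_auc_near_one(self):
        rows = _rows(40, 160, seed=8)
        rows["x0"] = rows["outcome"] * 10.0  # feature fully determines outcome
        fitted = tune_and_train(
            rows, "gradient_boosted_trees",
            grid=[{"n_estimators": 30, "max_depth": 3, "learning_rate": 0.3}],
            folds=3, seed=1,
        )
        assert fitted.cv_results["mean_cv_auc"].iloc[0] > 0.99

    def test_label_permuted_outcome_has_chance_level_cv_auc(self):
        rng = np.random.default_rng(12)
        rows = _rows(60, 140, seed=12)
        rows["outcome"] = rng.permutation(rows["outcome"].to_numpy())
        fitted = tune_and_train(
            rows, "random_forest", grid=[{"n_estimators": 50, "max_depth": 3}],
            folds=5, seed=2,
        )
        assert 0.3 < fitted.cv_results["mean_cv_auc"].iloc[0] < 0.7

    def test_unknown_family_and_empty_grid_rejected(self):
        rows = _rows(30, 100)
        with pytest.raises(ValueError, match="family"):
            tune_and_train(rows, "deep_net")
        with pytest.raises(ValueError, match="non-empty"):
            tune_and_train(rows, "random_forest", grid=[])


class TestVariableImportance:
    def test_signal_feature_ranks_first_and_sums_to_one(self):
        rows = _rows(40, 160, seed=9)
        rows["x0"] = rows["outcome"] * 5.0 + np.random.default_rng(0).normal(0, 0.1, 200)
        fitted = tune_and_train(
            rows, "gradient_boosted_trees",
            grid=[{"n_estimators": 30, "max_depth": 3, "learning_rate": 0.3}],
            folds=3, seed=1,
        )
        imp = variable_importance(fitted)
        assert imp["feature"].iloc[0] == "x0"
        assert imp["importance"].sum() == pytest.approx(1.0)
        assert (imp["importance"].diff().dropna() <= 1e-12).all()

    def test_svm_has_no_gain_importance(self):
        rows = _rows(30, 100, seed=10)
        fitted = tune_and_train(rows, "support_vector_machine", grid=[{"C": 1.0}],
                                folds=3, seed=1)
        with pytest.raises(ValueError, match="tree-ensemble"):
            variable_importance(fitted)


def test_full_pipeline_reproducible_under_master_seed(small_result):
    from pimddi.risk_model import run_ml_workflow

    rows = small_result.cohort
    grid = [{"n_estimators": 30, "max_depth": 3, "learning_rate": 0.1}]
    out1 = run_ml_workflow(rows, "gradient_boosted_trees", grid=grid, folds=3, seed=5)
    out2 = run_ml_workflow(rows, "gradient_boosted_trees", grid=grid, folds=3, seed=5)
    assert out1[1] == out2[1]
    assert out1[2].as_dict() == out2[2].as_dict()
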