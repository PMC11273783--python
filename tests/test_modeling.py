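import numpy as np
import pytest

from pathomics.errors import ConfigurationError, PathomicsError
from pathomics.modeling import (ModelReport, SelectionConfig, SvmConfig,
                                evaluate_confusion, mi_scores, nested_cv,
                                select_features)

from oracles import binned_mi


def two_gaussians(n=80, separation=6.0, d=10, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 1, (n, d))
    X[:, 0] += y * separation
    return X, y


class TestMiScores:
    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 500)
        X = rng.normal(0, 1, (500, 1))
        assert mi_scores(X, y, seed=0)[0] < 0.05

    def test_informative_feature_near_label_entropy(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 250)
        X = (y + rng.normal(0, 0.01, 500)).reshape(-1, 1)
        score = mi_scores(X, y, seed=1)[0]
        assert score == pytest.approx(np.log(2), abs=0.1)
        # discrete plug-in estimate agrees
        assert binned_mi(X[:, 0], y) == pytest.approx(np.log(2), abs=0.1)

    def test_matches_sklearn_knn_estimator(self):
        """Independent implementation of the same kNN estimator agrees to
        machine precision on tie-free continuous data."""
        from sklearn.feature_selection import mutual_info_classif

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 120)
        X = rng.normal(0, 1, (120, 6))
        X[:, 0] += 1.5 * y
        X[:, 1] -= 0.8 * y
        ours = mi_scores(X, y, seed=0)
        ref = mutual_info_classif(X, y, n_neighbors=3, random_state=0)
        assert np.abs(ours - ref).max() < 1e-9

    def test_duplicated_columns_get_equal_scores(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        f = rng.normal(0, 1, 100) + y
        X = np.column_stack([f, f])
        s = mi_scores(X, y, seed=5)
        assert s[0] == s[1]

    def test_mi_shrinks_with_sample_size_for_independent_pair(self):
        rng = np.random.default_rng(3)
        est = {}
        for n in (100, 1000):
            y = np.array([0, 1] * (n // 2))
            X = rng.normal(0, 1, (n, 1))
            est[n] = mi_scores(X, y, seed=0)[0]
        assert est[1000] <= est[100] + 0.02
        assert est[1000] < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(PathomicsError):
            mi_scores(np.zeros((5, 2)), np.zeros(5), seed=0)


class TestSelection:
    def test_threshold_boundary_inclusive(self):
        scores = np.array([0.5, 0.29, 0.1])
        sel = select_features(scores, SelectionConfig(mode="threshold",
                                                      mi_threshold=0.29))
        assert sel.tolist() == [0, 1]

    def test_top_k_identity(self):
        scores = np.array([0.3, 0.1, 0.2])
        sel = select_features(scores, SelectionConfig(mode="top_k", top_k=3))
        assert sorted(sel.tolist()) == [0, 1, 2]
        assert sel.tolist() == [0, 2, 1]  # descending score order

    def test_top_k_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 50)
        sel = select_features(scores, SelectionConfig(mode="top_k", top_k=10))
        oracle = set(np.argsort(-scores)[:10].tolist())
        assert set(sel.tolist()) == oracle

    def test_tie_break_by_column_order(self):
        scores = np.array([0.5, 0.9, 0.5, 0.2])
        sel = select_features(scores, SelectionConfig(mode="top_k", top_k=2))
        assert sel.tolist() == [1, 0]

    def test_empty_selection_raises(self):
        with pytest.raises(PathomicsError, match="threshold"):
            select_features(np.array([0.1]), SelectionConfig(
                mode="threshold", mi_threshold=0.5))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(mode="magic")
        with pytest.raises(ConfigurationError):
            SvmConfig(kernel="poly")
        with pytest.raises(ConfigurationError):
            SvmConfig(outer_folds=1)


class TestNestedCv:
    def test_separable_data_high_accuracy(self):
        X, y = two_gaussians()
        rep = nested_cv(X, y, SvmConfig(kernel="linear", seed=0))
        assert rep.metrics["accuracy"] >= 0.95
        assert rep.auc_mean >= 0.99

    def test_each_case_in_exactly_one_outer_fold(self):
        X, y = two_gaussians(n=40)
        rep = nested_cv(X, y, SvmConfig(kernel="linear", seed=1))
        c = rep.confusion
        assert c["tp"] + c["fp"] + c["tn"] + c["fn"] == len(y)
        assert len(rep.pooled_scores) == len(y)

    def test_seeded_determinism_is_exact(self):
        X, y = two_gaussians(n=40, separation=1.0, seed=5)
        sel = SelectionConfig(mode="top_k", top_k=5, seed=3)
        a = nested_cv(X, y, SvmConfig(kernel="rbf", seed=3), sel)
        b = nested_cv(X, y, SvmConfig(kernel="rbf", seed=3), sel)
        assert a.to_dict() == b.to_dict()

    def test_permuted_labels_stay_near_chance(self):
        rng = np.random.default_rng(6)
        X, y = two_gaussians(n=40, separation=2.0, seed=6)
        aucs = []
        for i in range(20):
            yp = rng.permutation(y)
            rep = nested_cv(X, yp, SvmConfig(kernel="linear", seed=i))
            aucs.append(rep.auc_mean)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_selection_scope_whole_dataset_runs(self):
        X, y = two_gaussians(n=40, separation=2.0, seed=7)
        sel = SelectionConfig(mode="top_k", top_k=4, seed=0)
        rep = nested_cv(X, y, SvmConfig(seed=0, selection_scope="whole_dataset"),
                        sel)
        # every fold used the same (globally selected) feature list
        assert all(f == rep.selected_features[0]
                   for f in rep.selected_features)

    def test_too_few_cases_per_class_rejected(self):
        X = np.zeros((6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(PathomicsError):
            nested_cv(X, y, SvmConfig(seed=0))


class TestEvaluateConfusion:
    def test_symmetric_matrix(self):
        m = evaluate_confusion(25, 25, 25, 25)
        assert m["accuracy"] == 0.5
        assert m["precision"] == 0.5
        assert m["recall"] == 0.5

    def test_division_by_zero_flagged(self):
        m = evaluate_confusion(0, 0, 10, 5)
        assert m["precision"] == 0.0
        assert "precision" in m["undefined"]

    def test_metric_identities(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = evaluate_confusion(int(tp), int(fp), int(tn), int(fn))
            assert m["precision"] * (tp + fp) == pytest.approx(tp)
            assert m["recall"] * (tp + fn) == pytest.approx(tp)
            assert m["npv"] * (tn + fn) == pytest.approx(tn)
            assert m["f_score"] == pytest.approx(
                2 * m["precision"] * m["recall"]
                / (m["precision"] + m["recall"]))

    def test_empty_matrix_rejected(self):
        with pytest.raises(PathomicsError):
            evaluate_confusion(0, 0, 0, 0)


def test_report_serializes_to_json():
    X, y = two_gaussians(n=40)
    rep = nested_cv(X, y, SvmConfig(kernel="linear", seed=0))
    import json

    back = ModelReport(**json.loads(rep.to_json()))
    assert back.auc_mean == rep.auc_mean
    assert back.confusion == rep.confusion
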