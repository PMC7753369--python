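"""Classifiers, cross-validation and metric computation."""

import numpy as np
import pytest

from msvdfuse.classify import (ClassifierSpec, FeatureTable, compute_metrics,
                               cross_validate, knn_classify, tree_classify)


def specificity_oracle(y_true, y_pred, classes):
    """Explicit one-vs-rest true-negative-rate counting."""
    vals = []
    for c in classes:
        tn = fp = 0
        for t, p in zip(y_true, y_pred):
            if t != c and p != c:
                tn += 1
            elif t != c and p == c:
                fp += 1
        if tn + fp:
            vals.append(tn / (tn + fp))
    return 100.0 * np.mean(vals)


def auc_oracle(y_true, scores, classes):
    """Pairwise rank-sum AUC (ties count 1/2), macro over classes."""
    vals = []
    for ci, c in enumerate(classes):
        pos = scores[y_true == c, ci]
        neg = scores[y_true != c, ci]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        vals.append(wins / (len(pos) * len(neg)))
    return 100.0 * np.mean(vals)


class TestKnn:
    def test_nearest_point(self):
        train = FeatureTable(np.array([[0.0], [0.1], [1.0], [1.1]]),
                             np.array(["A", "A", "B", "B"]))
        labels, scores = knn_classify(train, [[0.05]], k=1)
        assert labels[0] == "A"
        np.testing.assert_allclose(scores[0], [1.0, 0.0])

    def test_k_equals_all_votes_majority(self):
        train = FeatureTable(np.array([[0.0], [0.2], [0.4], [10.0]]),
                             np.array(["A", "A", "A", "B"]))
        labels, _ = knn_classify(train, [[100.0]], k=4)
        assert labels[0] == "A"

    def test_vote_tie_prefers_smaller_class_index(self):
        train = FeatureTable(np.array([[0.0], [1.0]]), np.array(["A", "B"]))
        labels, scores = knn_classify(train, [[0.5]], k=2)
        assert labels[0] == "A"
        np.testing.assert_allclose(scores[0], [0.5, 0.5])

    def test_invalid_k(self):
        train = FeatureTable(np.array([[0.0], [1.0]]), np.array(["A", "B"]))
        with pytest.raises(ValueError):
            knn_classify(train, [[0.0]], k=0)
        with pytest.raises(ValueError):
            knn_classify(train, [[0.0]], k=3)


class TestTree:
    def test_linearly_separable_single_split(self):
        X = np.array([[0.0], [0.2], [0.9], [1.1]])
        y = np.array([0, 0, 1, 1])
        labels, _ = tree_classify(FeatureTable(X, y), X)
        np.testing.assert_array_equal(labels, y)

    def test_xor_needs_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        labels, _ = tree_classify(FeatureTable(X, y), X, max_depth=2)
        np.testing.assert_array_equal(labels, y)


class TestComputeMetrics:
    def test_binary_positive_class_specificity(self):
        y_true = np.array(["P", "P", "N", "N", "N", "N"])
        y_pred = np.array(["P", "P", "P", "N", "N", "N"])
        classes = np.array(["N", "P"])
        # one-vs-rest term for P: TN=3, FP=1 -> 75%
        assert specificity_oracle(y_true, y_pred, ["P"]) == pytest.approx(75.0)
        scores = np.where((y_pred == "P")[:, None], [0.0, 1.0], [1.0, 0.0])
        acc, spec, _ = compute_metrics(y_true, y_pred, scores, classes)
        assert spec == pytest.approx(specificity_oracle(y_true, y_pred, classes))
        assert acc == pytest.approx(100 * 5 / 6)

    def test_perfect_ranking_gives_full_auc(self):
        y_true = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        _, _, auc = compute_metrics(y_true, np.array([0, 0, 1, 1]), scores,
                                    np.array([0, 1]))
        assert auc == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_multiclass_against_oracles(self, seed):
        r = np.random.default_rng(seed)
        classes = np.array([0, 1, 2])
        y_true = r.integers(0, 3, 30)
        y_pred = r.integers(0, 3, 30)
        scores = r.dirichlet(np.ones(3), size=30)
        acc, spec, auc = compute_metrics(y_true, y_pred, scores, classes)
        assert acc == pytest.approx(100 * np.mean(y_true == y_pred))
        assert spec == pytest.approx(specificity_oracle(y_true, y_pred, classes),
                                     abs=1e-9)
        assert auc == pytest.approx(auc_oracle(y_true, scores, classes), abs=1e-9)

    def test_relabeling_invariance(self):
        r = np.random.default_rng(3)
        y_true = r.integers(0, 3, 40)
        y_pred = r.integers(0, 3, 40)
        scores = r.dirichlet(np.ones(3), size=40)
        base = compute_metrics(y_true, y_pred, scores, np.array([0, 1, 2]))
        perm = np.array([2, 0, 1])
        base_p = compute_metrics(perm[y_true], perm[y_pred],
                                 scores[:, np.argsort(perm)], np.array([0, 1, 2]))
        assert base[1] == pytest.approx(base_p[1], abs=1e-9)
        assert base[2] == pytest.approx(base_p[2], abs=1e-9)


class TestCrossValidate:
    def _clusters(self, n_per=20, spread=0.05, seed=0):
        r = np.random.default_rng(seed)
        centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5], [2.5, 2.5]])
        X = np.vstack([c + spread * r.standard_normal((n_per, 2)) for c in centers])
        y = np.repeat(np.arange(5), n_per)
        return FeatureTable(X, y)

    def test_separable_clusters_are_perfect(self):
        rep = cross_validate(self._clusters(), ClassifierSpec("knn", k=5),
                             folds=10, seed=0)
        assert rep.accuracy == pytest.approx(100.0)
        assert rep.confusion.sum() == 100
        assert np.trace(rep.confusion) == 100

    def test_accuracy_equals_confusion_trace(self):
        table = self._clusters(spread=3.0, seed=1)
        rep = cross_validate(table, folds=5, seed=2)
        # fold means of unequal-size folds equal the global rate here because
        # folds are equal-sized (100 rows / 5 folds)
        assert rep.accuracy == pytest.approx(
            100 * np.trace(rep.confusion) / rep.confusion.sum())

    def test_chance_level_on_shuffled_labels(self):
        r = np.random.default_rng(0)
        accs = []
        for rep_i in range(10):
            X = r.standard_normal((100, 4))
            y = np.repeat(np.arange(5), 20)
            r.shuffle(y)
            rep = cross_validate(FeatureTable(X, y), folds=5, seed=rep_i)
            accs.append(rep.accuracy)
        assert np.mean(accs) == pytest.approx(20.0, abs=10.0)

    def test_determinism(self):
        table = self._clusters(spread=2.0, seed=4)
        r1 = cross_validate(table, folds=10, seed=9)
        r2 = cross_validate(table, folds=10, seed=9)
        np.testing.assert_array_equal(r1.fold_accuracy, r2.fold_accuracy)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.fingerprint == r2.fingerprint

    def test_small_class_rejected(self):
        X = np.zeros((12, 2))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(FeatureTable(X, y), folds=5, seed=0)
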