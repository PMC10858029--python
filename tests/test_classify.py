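"""Classification and evaluation contracts: grouped stratified folds, the four
classifier families, confusion-matrix bookkeeping and the per-class metrics."""

import numpy as np
import pytest

from ppgarr.classify import (
    ClassifierSpec,
    compare_classifiers,
    confusion,
    cross_validate,
    metrics_from_confusion,
    predict,
    stratified_group_folds,
    train,
)
from ppgarr.features import FEATURE_NAMES


def _blobs(n_per=30, sep=10.0, seed=0, d=4):
    r = np.random.default_rng(seed)
    Xa = r.normal(0, 1, (n_per, d))
    Xb = r.normal(sep, 1, (n_per, d))
    X = np.vstack([Xa, Xb])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestFolds:
    def test_twenty_groups_ten_folds(self):
        labels = np.repeat("x", 100)
        groups = np.repeat([f"g{i}" for i in range(20)], 5)
        fa = stratified_group_folds(labels, groups, 10, seed=0)
        counts = [len(set(groups[fa.fold_of_row == f])) for f in range(10)]
        assert counts == [2] * 10

    def test_groups_not_split(self):
        labels = np.repeat(["a", "b"], 50)
        groups = np.repeat([f"g{i}" for i in range(20)], 5)
        fa = stratified_group_folds(labels, groups, 5, seed=1)
        for g in set(groups):
            assert len(set(fa.fold_of_row[groups == g])) == 1

    def test_class_balance_across_folds(self):
        labels = np.repeat(["a", "b"], 50)
        groups = np.repeat([f"g{i}" for i in range(20)], 5)
        fa = stratified_group_folds(labels, groups, 5, seed=2)
        for cls in ("a", "b"):
            per_fold = [np.sum((labels == cls) & (fa.fold_of_row == f)) for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 5  # one 5-row group

    def test_deterministic(self):
        labels = np.repeat(["a", "b"], 50)
        groups = np.repeat([f"g{i}" for i in range(20)], 5)
        a = stratified_group_folds(labels, groups, 5, seed=3)
        b = stratified_group_folds(labels, groups, 5, seed=3)
        assert np.array_equal(a.fold_of_row, b.fold_of_row)

    def test_more_folds_than_groups(self):
        with pytest.raises(ValueError):
            stratified_group_folds(["a"] * 4, ["g1", "g1", "g2", "g2"], 10, 0)


class TestTrainPredict:
    def test_knn_one_neighbor_memorizes(self):
        X, y = _blobs(sep=3.0)
        model = train(ClassifierSpec("knn", n_neighbors=1), X, y)
        assert np.array_equal(predict(model, X), y)

    def test_tree_shatters_consistent_data(self):
        X, y = _blobs(sep=2.0)
        model = train(ClassifierSpec("dt", seed=0), X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_svm_separates_distant_blobs(self):
        X, y = _blobs(n_per=60, sep=10.0)
        rs = np.random.default_rng(1).permutation(len(y))
        tr, te = rs[:60], rs[60:]
        model = train(ClassifierSpec("svm", seed=0), X[tr], y[tr])
        assert np.mean(predict(model, X[te]) == y[te]) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train(ClassifierSpec("dt"), X, ["a"] * 10)

    def test_prediction_is_rowwise(self):
        X, y = _blobs(sep=5.0)
        model = train(ClassifierSpec("knn"), X, y)
        perm = np.random.default_rng(0).permutation(len(y))
        assert np.array_equal(predict(model, X[perm]), predict(model, X)[perm])

    def test_empty_rows_and_dim_mismatch(self):
        X, y = _blobs()
        model = train(ClassifierSpec("dt", seed=0), X, y)
        assert predict(model, np.zeros((0, X.shape[1]))).size == 0
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, X.shape[1] + 1)))

    def test_ensemble_needs_two_learners(self):
        with pytest.raises(ValueError):
            ClassifierSpec("ensemble", n_estimators=1)


class TestConfusion:
    def test_perfect_diagonal(self):
        y = ["a"] * 3 + ["b"] * 5
        cm = confusion(y, y, ["a", "b"])
        assert np.array_equal(cm, [[3, 0], [0, 5]])

    def test_hand_tally(self):
        cm = confusion(list("aabbb"), list("abbba"), ["a", "b"])
        assert np.array_equal(cm, [[1, 1], [1, 2]])
        assert cm.sum() == 5

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["z"], ["a", "b"])


class TestMetrics:
    def test_hand_computed_binary_case(self):
        cm = np.array([[8, 2], [5, 85]])
        frag = metrics_from_confusion(cm, ["pos", "neg"])
        m = frag["per_class"]["pos"]
        assert m["sensitivity"] == pytest.approx(0.8, abs=1e-9)
        assert m["specificity"] == pytest.approx(85 / 90, abs=1e-9)
        assert m["precision"] == pytest.approx(8 / 13, abs=1e-9)
        assert frag["accuracy"] == pytest.approx(0.93, abs=1e-9)

    def test_perfect_predictions(self):
        frag = metrics_from_confusion(np.diag([4, 6, 2]), ["a", "b", "c"])
        assert frag["accuracy"] == 1.0
        for m in frag["per_class"].values():
            assert m["sensitivity"] == 1.0 and m["precision"] == 1.0

    def test_absent_class_undefined_coded(self):
        cm = np.array([[5, 0], [0, 0]])
        frag = metrics_from_confusion(cm, ["a", "b"])
        assert np.isnan(frag["per_class"]["b"]["sensitivity"])
        assert frag["per_class"]["a"]["sensitivity"] == 1.0


class TestCrossValidate:
    @pytest.fixture()
    def data(self, small_feature_table):
        t = small_feature_table
        return (
            t[list(FEATURE_NAMES)].to_numpy(),
            t["label"].to_numpy(),
            t["record_id"].to_numpy(),
        )

    def test_pooled_confusion_partitions_dataset(self, data):
        X, y, g = data
        folds = stratified_group_folds(y, g, 5, 0)
        rep = cross_validate(X, y, folds, ClassifierSpec("dt", seed=0))
        assert rep.pooled_confusion.sum() == len(y)
        assert sum(m.sum() for m in rep.per_fold_confusions) == len(y)

    def test_high_accuracy_on_separable_synthetics(self, data):
        X, y, g = data
        folds = stratified_group_folds(y, g, 5, 0)
        rep = cross_validate(X, y, folds, ClassifierSpec("knn", seed=0))
        assert rep.accuracy >= 0.90

    def test_deterministic(self, data):
        X, y, g = data
        folds = stratified_group_folds(y, g, 5, 0)
        r1 = cross_validate(X, y, folds, ClassifierSpec("ensemble", seed=1, n_estimators=20))
        r2 = cross_validate(X, y, folds, ClassifierSpec("ensemble", seed=1, n_estimators=20))
        assert r1.to_json() == r2.to_json()

    def test_compare_classifiers_table(self, data):
        X, y, g = data
        folds = stratified_group_folds(y, g, 5, 0)
        specs = [ClassifierSpec("dt", seed=0), ClassifierSpec("knn", seed=0)]
        reports, table = compare_classifiers(X, y, folds, specs)
        assert len(reports) == 2
        assert len(table) == 2 * 5  # 2 classifiers x 5 classes
        assert set(table["classifier"]) == {"dt", "knn"}

    def test_bagging_not_worse_than_single_tree(self):
        # bagging reduces variance: over seeds, mean ensemble accuracy is not
        # materially below the single tree's
        accs_dt, accs_en = [], []
        for seed in range(6):
            r = np.random.default_rng(seed)
            X = r.normal(size=(120, 6))
            y = np.where(X[:, 0] + X[:, 1] + 0.8 * r.normal(size=120) > 0, "p", "q")
            g = np.array([f"g{i % 24}" for i in range(120)])
            folds = stratified_group_folds(y, g, 4, seed)
            accs_dt.append(cross_validate(X, y, folds, ClassifierSpec("dt", seed=seed)).accuracy)
            accs_en.append(
                cross_validate(
                    X, y, folds, ClassifierSpec("ensemble", seed=seed, n_estimators=50)
                ).accuracy
            )
        assert np.mean(accs_dt) <= np.mean(accs_en) + 0.02
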