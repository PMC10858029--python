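"""Classifier training and cross-validated evaluation.

Four classifier families are supported — decision tree, RBF-kernel SVM,
k-nearest neighbours and a bagged-tree ensemble — evaluated with grouped
stratified k-fold cross-validation: all segments cut from one source record
share a fold, so a classifier is never tested on segments of a record it
trained on.  Per-class one-vs-rest sensitivity, specificity and precision
plus overall (pooled micro) accuracy are reported from the cross-validated
confusion matrices.  Standardization (and PCA or feature sub-setting, when
configured) is refit inside each training fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "FoldAssignment",
    "MetricsReport",
    "stratified_group_folds",
    "train",
    "predict",
    "confusion",
    "metrics_from_confusion",
    "cross_validate",
    "compare_classifiers",
]

CLASSIFIER_KINDS = ("dt", "svm", "knn", "ensemble")


@dataclass(frozen=True)
class ClassifierSpec:
    """Kind + hyperparameters + seed for one classifier configuration."""

    kind: str
    seed: int = 0
    n_neighbors: int = 5  # knn
    svm_c: float = 1.0  # svm box constraint
    n_estimators: int = 100  # ensemble

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.n_estimators < 2:
            raise ValueError("an ensemble needs >= 2 learners")


@dataclass
class FoldAssignment:
    """Fold id per row; whole groups (source records) share a fold."""

    fold_of_row: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.fold_of_row = np.asarray(self.fold_of_row, dtype=int)
        present = np.unique(self.fold_of_row)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("every fold must be non-empty")


def stratified_group_folds(
    labels: Sequence[str],
    groups: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign whole groups to k folds, balancing class counts greedily.

    Groups are shuffled (seeded) within each class and dealt to the fold
    currently holding the fewest groups of that class, ties broken by total
    row load then fold id — deterministic for a given seed.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq_groups = pd.unique(groups)
    if len(uniq_groups) < k:
        raise ValueError(f"k={k} exceeds the number of groups ({len(uniq_groups)})")
    group_label: dict[str, str] = {}
    group_size: dict[str, int] = {}
    for g in uniq_groups:
        mask = groups == g
        vals, counts = np.unique(labels[mask], return_counts=True)
        group_label[g] = vals[np.argmax(counts)]
        group_size[g] = int(mask.sum())
    rng = np.random.default_rng(seed)
    fold_rows = np.zeros(k, dtype=int)
    fold_class_groups: dict[str, np.ndarray] = {}
    assignment: dict[str, int] = {}
    for cls in sorted(set(group_label.values())):
        cls_groups = [g for g in uniq_groups if group_label[g] == cls]
        order = rng.permutation(len(cls_groups))
        fold_class_groups[cls] = np.zeros(k, dtype=int)
        for i in order:
            g = cls_groups[i]
            key = [
                (fold_class_groups[cls][f], fold_rows[f], f) for f in range(k)
            ]
            f_best = min(range(k), key=lambda f: key[f])
            assignment[g] = f_best
            fold_class_groups[cls][f_best] += 1
            fold_rows[f_best] += group_size[g]
    fold_of_row = np.array([assignment[g] for g in groups], dtype=int)
    return FoldAssignment(fold_of_row, k)


def _median_heuristic_gamma(X: np.ndarray, seed: int, max_rows: int = 512) -> float:
    """RBF kernel scale 1/(2*median^2) of pairwise Euclidean distances."""
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_rows:
        X = X[rng.choice(X.shape[0], max_rows, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(X)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


def train(spec: ClassifierSpec, X: np.ndarray, y: Sequence[str]):
    """Fit one classifier; deterministic under ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if spec.kind == "dt":
        model = DecisionTreeClassifier(criterion="gini", random_state=spec.seed)
    elif spec.kind == "knn":
        model = KNeighborsClassifier(n_neighbors=spec.n_neighbors)
    elif spec.kind == "svm":
        gamma = _median_heuristic_gamma(X, spec.seed)
        model = SVC(C=spec.svm_c, kernel="rbf", gamma=gamma, random_state=spec.seed)
    else:  # ensemble: bagged decision trees
        model = BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion="gini"),
            n_estimators=spec.n_estimators,
            random_state=spec.seed,
        )
    model.fit(X, y)
    return model


def predict(model, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    if X.shape[1] != model.n_features_in_:
        raise ValueError("feature dimension mismatch with the trained model")
    return model.predict(X)


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> np.ndarray:
    """Row = true class, column = predicted class, in ``class_order``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    unknown = set(y_true) | set(y_pred)
    if not unknown <= set(class_order):
        raise ValueError(f"labels outside class order: {sorted(unknown - set(class_order))}")
    return _sk_confusion(y_true, y_pred, labels=list(class_order)).astype(int)


def metrics_from_confusion(cm: np.ndarray, class_order: Sequence[str]) -> dict:
    """One-vs-rest sensitivity/specificity/precision per class + accuracy.

    A 0/0 ratio (e.g. sensitivity of a class absent from the test rows) is
    reported as NaN — a distinguished 'undefined' value, never silently 0.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    per_class = {}
    for i, cls in enumerate(class_order):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[cls] = {
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "precision": ratio(tp, tp + fp),
        }
    return {"accuracy": float(np.trace(cm) / total), "per_class": per_class}


@dataclass
class MetricsReport:
    """Cross-validated evaluation result for one classifier configuration."""

    class_order: tuple[str, ...]
    pooled_confusion: np.ndarray
    per_fold_confusions: list[np.ndarray]
    accuracy: float
    per_class: dict
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "pooled_confusion": self.pooled_confusion.astype(int).tolist(),
            "per_fold_confusions": [m.astype(int).tolist() for m in self.per_fold_confusions],
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _fit_fold_transform(
    X_train: np.ndarray,
    X_test: np.ndarray,
    pca_k: int | None,
    feature_idx: np.ndarray | None,
):
    """Per-fold preprocessing: optional column subset, standardize, optional PCA."""
    from .selection import pca_fit, pca_transform, standardize_apply, standardize_fit

    if feature_idx is not None:
        X_train = X_train[:, feature_idx]
        X_test = X_test[:, feature_idx]
    params = standardize_fit(X_train)
    X_train = standardize_apply(params, X_train)
    X_test = standardize_apply(params, X_test)
    if pca_k is not None:
        model = pca_fit(X_train, pca_k)
        X_train = pca_transform(model, X_train)
        X_test = pca_transform(model, X_test)
    return X_train, X_test


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    folds: FoldAssignment,
    spec: ClassifierSpec,
    pca_k: int | None = None,
    feature_idx: np.ndarray | None = None,
    class_order: Sequence[str] | None = None,
) -> MetricsReport:
    """Grouped k-fold evaluation with per-fold transform refits.

    Standardization and (when requested) PCA or feature sub-setting are
    functions of the training rows of each fold only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if class_order is None:
        class_order = tuple(sorted(np.unique(y)))
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    fold_cms = []
    for f in range(folds.k):
        test_mask = folds.fold_of_row == f
        X_tr, X_te = _fit_fold_transform(X[~test_mask], X[test_mask], pca_k, feature_idx)
        model = train(spec, X_tr, y[~test_mask])
        pred = predict(model, X_te)
        pooled_true.append(y[test_mask])
        pooled_pred.append(pred)
        fold_cms.append(confusion(y[test_mask], pred, class_order))
    cm = confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred), class_order)
    frag = metrics_from_confusion(cm, class_order)
    config = {
        "classifier": spec.kind,
        "seed": spec.seed,
        "k_folds": folds.k,
        "pca_components": pca_k,
        "n_selected_features": None if feature_idx is None else int(len(feature_idx)),
    }
    return MetricsReport(
        tuple(class_order), cm, fold_cms, frag["accuracy"], frag["per_class"], config
    )


def compare_classifiers(
    X: np.ndarray,
    y: Sequence[str],
    folds: FoldAssignment,
    specs: Sequence[ClassifierSpec],
    **kwargs,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Evaluate several classifiers on identical folds.

    Returns the reports plus a tidy table with one row per
    (classifier, class): sensitivity, specificity, precision and the
    classifier's overall accuracy.
    """
    if not specs:
        raise ValueError("at least one classifier spec required")
    reports = [cross_validate(X, y, folds, s, **kwargs) for s in specs]
    rows = []
    for s, r in zip(specs, reports):
        for cls in r.class_order:
            m = r.per_class[cls]
            rows.append(
                {
                    "classifier": s.kind,
                    "class": cls,
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "precision": m["precision"],
                    "accuracy": r.accuracy,
                }
            )
    return reports, pd.DataFrame(rows)
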