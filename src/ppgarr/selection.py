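"""PCA dimensionality reduction and loading-based feature ranking.

The 41 features mix units (seconds, normalized amplitude, nats, Hz), so PCA
is always run on standardized columns.  Feature relevance is scored by the
explained-variance-weighted maximum absolute loading over the leading
components; accuracy-vs-components and accuracy-vs-selected-features curves
re-run the full grouped cross-validation per point, refitting
standardization and PCA inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .classify import ClassifierSpec, FoldAssignment, cross_validate

__all__ = [
    "StandardizationParams",
    "PCAModel",
    "FeatureRanking",
    "standardize_fit",
    "standardize_apply",
    "pca_fit",
    "pca_transform",
    "rank_features_by_loading",
    "accuracy_vs_components",
    "accuracy_vs_selected_features",
]


@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    n_rows: int
    zero_sd: np.ndarray  # flagged constant columns (passed through as zeros)


def standardize_fit(X: np.ndarray) -> StandardizationParams:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    return StandardizationParams(mean, np.where(zero, 1.0, sd), X.shape[0], zero)


def standardize_apply(params: StandardizationParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.mean) / params.sd


@dataclass
class PCAModel:
    """Orthonormal loadings (d x K) with explained-variance ratios."""

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    n_features: int

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.loadings.shape[1]), atol=1e-8):
            raise ValueError("loadings must be orthonormal")


def pca_fit(X_std: np.ndarray, k: int) -> PCAModel:
    """Top-k principal components of the standardized table.

    The sign of each component is fixed so its largest-magnitude loading
    entry is positive, making the decomposition reproducible across runs.
    """
    X_std = np.asarray(X_std, dtype=float)
    d = X_std.shape[1]
    if not (1 <= k <= d):
        raise ValueError(f"k must lie in [1, {d}]")
    if X_std.shape[0] < 2:
        raise ValueError("PCA needs more than one row")
    pca = _SkPCA(n_components=k, svd_solver="full")
    pca.fit(X_std)
    loadings = pca.components_.T.copy()  # d x k
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
    return PCAModel(loadings, pca.explained_variance_ratio_.copy(), pca.explained_variance_.copy(), d)


def pca_transform(model: PCAModel, X_std: np.ndarray) -> np.ndarray:
    X_std = np.asarray(X_std, dtype=float)
    if X_std.shape[1] != model.n_features:
        raise ValueError("column count does not match the fitted model")
    return X_std @ model.loadings


@dataclass
class FeatureRanking:
    """Feature names ordered by decreasing relevance score."""

    names: list[str]
    scores: np.ndarray
    order: np.ndarray  # original column index per rank position

    def top(self, m: int) -> np.ndarray:
        return self.order[:m]


def rank_features_by_loading(
    model: PCAModel,
    feature_names: Sequence[str],
    n_components_used: int | None = None,
    min_explained: float = 0.90,
) -> FeatureRanking:
    """Score features by their correlation with the leading components.

    score(f) = max over the first n components of
    |loading(f, c)| * explained_variance_ratio(c).  When
    ``n_components_used`` is None, the smallest number of components
    explaining at least ``min_explained`` of the variance is used.  Ties are
    broken by original feature index.
    """
    k_avail = model.loadings.shape[1]
    if n_components_used is None:
        cum = np.cumsum(model.explained_variance_ratio)
        n_components_used = int(np.searchsorted(cum, min_explained) + 1)
        n_components_used = min(n_components_used, k_avail)
    if not (1 <= n_components_used <= k_avail):
        raise ValueError("n_components_used out of range")
    weighted = np.abs(model.loadings[:, :n_components_used]) * model.explained_variance_ratio[
        :n_components_used
    ]
    scores = weighted.max(axis=1)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(
        [feature_names[i] for i in order], scores[order], order
    )


def accuracy_vs_components(
    X: np.ndarray,
    y: Sequence[str],
    folds: FoldAssignment,
    specs: Sequence[ClassifierSpec],
    k_values: Sequence[int],
) -> pd.DataFrame:
    """Cross-validated accuracy per (classifier, number of PCA components).

    PCA and standardization are refit inside each training fold.
    """
    rows = []
    for spec in specs:
        for k in k_values:
            report = cross_validate(X, y, folds, spec, pca_k=int(k))
            rows.append({"classifier": spec.kind, "n_components": int(k), "accuracy": report.accuracy})
    return pd.DataFrame(rows)


def accuracy_vs_selected_features(
    X: np.ndarray,
    y: Sequence[str],
    folds: FoldAssignment,
    ranking: FeatureRanking,
    specs: Sequence[ClassifierSpec],
    m_values: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy using the top-m ranked features, per m."""
    d = X.shape[1]
    if len(ranking.order) != d:
        raise ValueError("ranking must cover all features")
    if m_values is None:
        m_values = range(1, d + 1)
    rows = []
    for spec in specs:
        for m in m_values:
            report = cross_validate(X, y, folds, spec, feature_idx=ranking.top(int(m)))
            rows.append({"classifier": spec.kind, "n_features": int(m), "accuracy": report.accuracy})
    return pd.DataFrame(rows)
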