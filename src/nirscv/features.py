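"""Across-subject PCA of beta maps, t-score component ranking, group
contrast maps, and reconstruction of an SVM classifier as a channel-space
weight map.

The beta matrix (subjects x channels) is decomposed into orthonormal spatial
components; each subject is a point in PC-score space and can be
reconstructed as ``mean_map + sum_j score_ij * PC_j``.  Components are ranked
for feature selection by the absolute two-sample t statistic of their scores
between the diagnostic groups — the statistic whose fold-wise recomputation
(or leaky pooled computation) the cross-validation machinery in
:mod:`nirscv.classify` revolves around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from . import _smo
from .preprocess import BetaMatrix

__all__ = [
    "BetaPCA",
    "PCRanking",
    "TScoreSelector",
    "fit_pca",
    "rank_pcs",
    "group_contrast",
    "svm_weight_map",
]


def _as_matrix(beta_matrix) -> np.ndarray:
    if isinstance(beta_matrix, BetaMatrix):
        return beta_matrix.values
    return np.asarray(beta_matrix, float)


class BetaPCA(TransformerMixin, BaseEstimator):
    """Centered, unscaled PCA of a subjects-x-features beta matrix.

    Thin estimator over :class:`sklearn.decomposition.PCA` (full SVD solver)
    that keeps the fitted subjects' scores and exposes low-rank
    reconstruction.  Channels share physical units, so no per-feature
    standardization is applied.

    Attributes
    ----------
    components_ : (n_components, n_features) orthonormal rows.
    mean_ : (n_features,) centering offset.
    scores_ : (n_subjects, n_components) PC scores of the fitted matrix.
    explained_fraction_ : per-component fraction of total variance,
        non-increasing.
    """

    def __init__(self, n_components: int = 32):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n, p = X.shape
        limit = min(n - 1, p)
        if not 1 <= self.n_components <= limit:
            raise ValueError(
                f"n_components must be in [1, {limit}] for a {n} x {p} matrix"
            )
        if np.allclose(X, X[0]) or np.allclose(X.var(axis=0).sum(), 0.0):
            raise ValueError("matrix has zero variance; PCA is undefined")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self.scores_ = self._pca.fit_transform(X)
        self.components_ = self._pca.components_
        self.mean_ = self._pca.mean_
        self.explained_fraction_ = self._pca.explained_variance_ratio_
        self.singular_values_ = self._pca.singular_values_
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        return (_as_matrix(X) - self.mean_) @ self.components_.T

    def reconstruct(self, subject_index: int, k: int | None = None) -> np.ndarray:
        """Low-rank reconstruction of a fitted subject's beta map from its
        first ``k`` PC scores (``k=0`` gives the mean map)."""
        check_is_fitted(self, "scores_")
        n = self.scores_.shape[0]
        if not -n <= subject_index < n:
            raise IndexError(f"subject index {subject_index} out of range")
        k = self.scores_.shape[1] if k is None else k
        if not 0 <= k <= self.scores_.shape[1]:
            raise ValueError(f"k must be in [0, {self.scores_.shape[1]}]")
        return self.mean_ + self.scores_[subject_index, :k] @ self.components_[:k]


def fit_pca(beta_matrix, n_pc: int = 32) -> BetaPCA:
    """Fit a :class:`BetaPCA` with ``n_pc`` components and return it."""
    return BetaPCA(n_components=n_pc).fit(beta_matrix)


@dataclass
class PCRanking:
    """Feature ranking by |t|, with the subject subset it was fitted on
    recorded for leakage auditing."""

    order: np.ndarray
    t_values: np.ndarray
    fitted_on: np.ndarray


def _tstats_py(X, y_pm, kind: str) -> np.ndarray:
    return _smo.tstats(np.ascontiguousarray(X, dtype=float),
                       np.ascontiguousarray(y_pm, dtype=float),
                       kind == "welch")


def _encode(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError(f"need exactly two classes, got {classes.shape[0]}")
    return classes, np.where(labels == classes[1], 1.0, -1.0)


def rank_pcs(scores, labels, subject_subset=None, kind: str = "pooled") -> PCRanking:
    """Rank components by the absolute two-sample t statistic of their
    scores, computed ONLY on ``subject_subset`` (all subjects by default).

    t is signed ``classes_[1] minus classes_[0]`` (sorted label order, i.e.
    TD minus ASD for the default labels); the ranking uses |t| descending
    with ties broken by the lower component index.  ``kind`` selects the
    pooled-variance ("pooled", default) or Welch ("welch") statistic.
    """
    scores = _as_matrix(scores)
    labels = np.asarray(labels)
    subset = (
        np.arange(scores.shape[0]) if subject_subset is None
        else np.asarray(subject_subset)
    )
    sub_labels = labels[subset]
    classes = np.unique(sub_labels)
    if classes.shape[0] != 2 or min(
        (sub_labels == c).sum() for c in classes
    ) < 2:
        raise ValueError("subset must contain at least two subjects per class")
    _, y_pm = _encode(sub_labels)
    t = _tstats_py(scores[subset], y_pm, kind)
    order = np.lexsort((np.arange(t.shape[0]), -np.abs(t)))
    return PCRanking(order=order, t_values=t, fitted_on=subset)


class TScoreSelector(SelectorMixin, BaseEstimator):
    """Select the top-k features by absolute two-sample t statistic.

    A scikit-learn transformer, so that ``Pipeline([TScoreSelector, ...])``
    under ``cross_val_predict`` re-fits the ranking inside every training
    fold — the nested scheme.  Fitting it once on all subjects before
    cross-validating the downstream classifier reproduces the leaky pooled
    scheme.
    """

    def __init__(self, k: int = 10, kind: str = "pooled"):
        self.k = k
        self.kind = kind

    def fit(self, X, y):
        X = np.asarray(X, float)
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in [1, {X.shape[1]}]")
        _, y_pm = _encode(y)
        self.t_values_ = _tstats_py(X, y_pm, self.kind)
        self.order_ = np.lexsort(
            (np.arange(X.shape[1]), -np.abs(self.t_values_))
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "order_")
        mask = np.zeros(self.n_features_in_, bool)
        mask[self.order_[: self.k]] = True
        return mask


def group_contrast(beta_matrix, labels) -> pd.DataFrame:
    """Per-feature group mean difference and t map.

    The difference is ``classes_[1] minus classes_[0]`` in sorted label
    order: with the default TD/ASD labels, positive values mark channels
    where the control group responds more strongly.
    """
    X = _as_matrix(beta_matrix)
    classes, y_pm = _encode(labels)
    if min((np.asarray(labels) == c).sum() for c in classes) < 1:
        raise ValueError("both classes must be non-empty")
    diff = X[y_pm > 0].mean(axis=0) - X[y_pm < 0].mean(axis=0)
    t = _tstats_py(X, y_pm, "pooled")
    return pd.DataFrame(
        {
            "feature": np.arange(X.shape[1]),
            "mean_diff": diff,
            "t": t,
        }
    )


def svm_weight_map(svm_model, pc_model: BetaPCA, selected_pcs) -> np.ndarray:
    """Render a linear classifier trained on selected PC scores back into
    feature (channel) space: ``sum_j w_j * PC_{selected[j]}``.

    ``svm_model`` may be a fitted :class:`nirscv.svm.LinearSVM` (its
    ``coef_`` is used) or a bare weight vector.
    """
    selected = np.asarray(selected_pcs, int)
    w = np.asarray(getattr(svm_model, "coef_", svm_model), float).ravel()
    if w.shape[0] != selected.shape[0]:
        raise ValueError(
            f"{w.shape[0]} weights do not match {selected.shape[0]} selected PCs"
        )
    check_is_fitted(pc_model, "components_")
    return w @ pc_model.components_[selected]
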