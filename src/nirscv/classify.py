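"""Univariate and multivariate classification under leave-one-out
cross-validation, in two feature-selection modes.

``nested`` re-ranks the PC features by two-sample t statistic inside every
training fold, excluding the held-out subject; ``pooled`` ranks once on all
subjects (held-out included) — the leaky comparator whose optimistic bias on
null data the permutation experiments quantify.  Folds are deterministic:
leave-one-out has no fold-assignment randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from . import _smo
from .features import BetaPCA, _encode

__all__ = [
    "ThresholdClassifier",
    "CVResult",
    "TuningCurve",
    "fit_univariate",
    "univariate_loo",
    "loo_svm",
    "tuning_curve",
]

MODES = ("nested", "pooled")


class ThresholdClassifier(ClassifierMixin, BaseEstimator):
    """One-dimensional linear classifier ``s = w*x + b`` with orientation
    ``w`` in {+1, -1}: predicts ``classes_[1]`` when s > 0.

    Training is an exhaustive search over both orientations and all
    thresholds at midpoints of consecutive distinct sorted x values (plus
    below-minimum and above-maximum sentinels), maximizing training
    accuracy.  Ties prefer the smallest |b|, then w = +1.  If all x are
    identical with mixed classes the majority rule (accuracy = majority
    rate) is returned rather than an error.
    """

    def fit(self, X, y):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y)
        if x.size == 0:
            raise ValueError("empty input")
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] > 2:
            raise ValueError("ThresholdClassifier is binary")
        ypm = np.where(y == self.classes_[-1], 1.0, -1.0)

        xs = np.unique(x)
        mids = (xs[:-1] + xs[1:]) / 2.0
        span = max(np.ptp(xs), 1.0)
        cands = np.concatenate(([xs[0] - span], mids, [xs[-1] + span]))
        best = (-1.0, np.inf, -2.0)  # (accuracy, |b|, w) lexicographic
        for w in (1.0, -1.0):
            # s_i = w*x_i + b with b = -w*c for threshold c
            scores = w * x[None, :] - (w * cands)[:, None]
            acc = ((scores > 0) == (ypm > 0)[None, :]).mean(axis=1)
            for ci in range(cands.shape[0]):
                key = (acc[ci], -abs(-w * cands[ci]), w)
                if key > best:
                    best = key
                    self.w_ = w
                    self.b_ = -w * cands[ci]
        self.train_accuracy_ = best[0]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "w_")
        return self.w_ * np.asarray(X, float).reshape(-1) + self.b_

    def predict(self, X):
        idx = (self.decision_function(X) > 0).astype(int)
        if self.classes_.shape[0] == 1:
            return np.full(idx.shape, self.classes_[0])
        return self.classes_[idx]


def fit_univariate(x_values, labels) -> ThresholdClassifier:
    """Fit the exhaustive-search threshold rule; returns the fitted
    classifier with ``w_``, ``b_`` and ``train_accuracy_``."""
    return ThresholdClassifier().fit(x_values, labels)


@dataclass
class CVResult:
    """Leave-one-out predictions: one held-out prediction per subject."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    accuracy: float
    mode: str
    k: int
    classes: np.ndarray
    subject_ids: list[str] | None = None
    #: per-fold feature ranking actually used (leakage audit trail)
    fold_rankings: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "true": self.y_true,
            "predicted": self.y_pred,
            "decision_score": self.scores,
        }
        if self.subject_ids is not None:
            d = {"subject_id": self.subject_ids, **d}
        return pd.DataFrame(d)


def univariate_loo(x_values, labels, method: str = "threshold") -> CVResult:
    """Leave-one-out CV of the univariate rule on a single measurement.

    ``method="threshold"`` refits the exhaustive threshold rule per fold;
    ``method="logistic"`` substitutes a logistic-regression scorer.
    """
    x = np.asarray(x_values, float).reshape(-1)
    labels = np.asarray(labels)
    classes, _ = _encode(labels)
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need at least two subjects per class")
    n = x.shape[0]
    scores = np.empty(n)
    preds = np.empty(n, dtype=labels.dtype)
    for h in range(n):
        tr = np.arange(n) != h
        if method == "threshold":
            model = ThresholdClassifier().fit(x[tr], labels[tr])
            scores[h] = model.decision_function([x[h]])[0]
            preds[h] = model.predict([x[h]])[0]
        elif method == "logistic":
            model = LogisticRegression().fit(x[tr, None], labels[tr])
            scores[h] = model.decision_function([[x[h]]])[0]
            preds[h] = model.predict([[x[h]]])[0]
        else:
            raise ValueError(f"unknown method {method!r}")
    return CVResult(
        y_true=labels,
        y_pred=preds,
        scores=scores,
        accuracy=float((preds == labels).mean()),
        mode=f"univariate-{method}",
        k=1,
        classes=classes,
    )


def _features_of(features) -> np.ndarray:
    if isinstance(features, BetaPCA):
        check_is_fitted(features, "scores_")
        return features.scores_
    return np.asarray(features, float)


def loo_svm(
    features,
    labels,
    k: int = 10,
    mode: str = "nested",
    C: float = 1.0,
    t_kind: str = "pooled",
    subject_ids: list[str] | None = None,
) -> CVResult:
    """Leave-one-out linear-SVM CV with top-k t-score feature selection.

    ``features`` is a fitted :class:`BetaPCA` (its training scores are used)
    or a raw subjects-x-features matrix.  Per fold the selected features are
    z-scored with training-fold statistics, a linear SVM (soft margin,
    regularization ``C``) is fit, and the held-out subject's signed decision
    score is recorded; ``accuracy`` is the fraction of correct held-out
    predictions.  ``mode`` chooses nested (fold-internal) or pooled
    (all-subject, leaky) feature ranking.
    """
    X = _features_of(features)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    classes, y_pm = _encode(labels)
    if min((np.asarray(labels) == c).sum() for c in classes) < 2:
        raise ValueError("need at least two subjects per class")
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    Xc = np.ascontiguousarray(X, float)
    welch = t_kind == "welch"
    if mode == "pooled":
        order_full = _smo.rank_desc(np.abs(_smo.tstats(Xc, y_pm, welch)))
    else:
        order_full = np.arange(p)
    scores, orders = _smo.loo_scores(
        Xc, y_pm, int(k), float(C), mode == "nested", welch, order_full
    )
    pred_pm = np.where(scores > 0, 1, 0)
    preds = classes[pred_pm]
    y_true = np.asarray(labels)
    return CVResult(
        y_true=y_true,
        y_pred=preds,
        scores=scores,
        accuracy=float((preds == y_true).mean()),
        mode=mode,
        k=int(k),
        classes=classes,
        subject_ids=subject_ids,
        fold_rankings=orders,
    )


@dataclass
class TuningCurve:
    """Accuracy as a function of the number of selected components."""

    k_values: np.ndarray
    accuracy_per_k: np.ndarray
    mode: str
    #: smallest k attaining the maximum accuracy
    best_k: int = field(init=False)

    def __post_init__(self):
        if len(self.k_values) != len(self.accuracy_per_k):
            raise ValueError("k_values and accuracy_per_k must align")
        self.best_k = int(self.k_values[int(np.argmax(self.accuracy_per_k))])

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.accuracy_per_k))


def tuning_curve(
    features,
    labels,
    k_range=None,
    mode: str = "nested",
    C: float = 1.0,
    t_kind: str = "pooled",
) -> TuningCurve:
    """Leave-one-out accuracy for every k in ``k_range`` (default 1..p).

    Each value equals a standalone :func:`loo_svm` call at that k; the
    shared computation (per-fold ranking and incrementally grown Gram
    matrices) is reused across k for speed.
    """
    X = _features_of(features)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    classes, y_pm = _encode(labels)
    n, p = X.shape
    ks = np.arange(1, p + 1) if k_range is None else np.asarray(list(k_range), int)
    if ks.size == 0:
        raise ValueError("k_range is empty")
    if ks.min() < 1 or ks.max() > p:
        raise ValueError(f"k_range must lie within [1, {p}]")
    Xc = np.ascontiguousarray(X, float)
    welch = t_kind == "welch"
    if mode == "pooled":
        order_full = _smo.rank_desc(np.abs(_smo.tstats(Xc, y_pm, welch)))
    else:
        order_full = np.arange(p)
    acc_all = _smo.loo_curve(
        Xc, y_pm, int(ks.max()), float(C), mode == "nested", welch, order_full
    )
    return TuningCurve(k_values=ks, accuracy_per_k=acc_all[ks - 1], mode=mode)
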