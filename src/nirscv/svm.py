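"""Soft-margin linear SVM as a scikit-learn-style estimator.

The optimizer is the package's own SMO solver (:mod:`nirscv._smo`), which
solves the standard hinge-loss / L2-penalty dual QP with an unregularized
bias — the same problem libsvm solves — so its solution is interchangeable
with ``sklearn.svm.SVC(kernel="linear")`` up to the non-uniqueness of the
bias on degenerate inputs; the test suite asserts this equivalence.  The
local solver exists because the permutation experiments need ~10^6 fits of
tiny (n <= 36) problems, where per-fit overhead dominates.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _smo

__all__ = ["LinearSVM", "fit_linear_svm"]


class LinearSVM(ClassifierMixin, BaseEstimator):
    """Binary soft-margin linear SVM (hinge loss, L2 penalty).

    Parameters
    ----------
    C : float
        Inverse regularization strength of the soft margin (box constraint
        of the dual), default 1.
    standardize : bool
        Z-score features using training-set statistics before fitting; the
        stored coefficients are mapped back to the original feature scale so
        that :meth:`decision_function` is an affine function of raw inputs.
    tol, max_iter : float, int
        SMO stopping rule (maximal-violating-pair gap) and iteration guard.

    Attributes
    ----------
    classes_ : (2,) array — sorted class labels; the decision score is
        positive for ``classes_[1]``.
    coef_ : (1, n_features) array, intercept_ : (1,) array.
    dual_coef_ : (1, n_sv) array of alpha_i * y_i; support_ : SV indices.
    """

    def __init__(self, C: float = 1.0, standardize: bool = False,
                 tol: float = _smo.TOL, max_iter: int = _smo.MAX_ITER):
        self.C = C
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if self.C <= 0:
            raise ValueError("C must be positive")
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] != 2:
            raise ValueError("LinearSVM is a binary classifier; got "
                             f"{self.classes_.shape[0]} class(es)")
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)

        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd < 1e-12] = 1.0
            self.scale_sd_ = sd
            Z = (X - self.scale_mean_) / self.scale_sd_
        else:
            self.scale_mean_ = np.zeros(X.shape[1])
            self.scale_sd_ = np.ones(X.shape[1])
            Z = X

        w, b, alpha = _smo.svm_fit(Z, ypm, float(self.C), float(self.tol),
                                   int(self.max_iter))
        # map back to the raw feature scale
        w_raw = w / self.scale_sd_
        b_raw = b - float(w_raw @ self.scale_mean_)
        self.coef_ = w_raw[None, :]
        self.intercept_ = np.array([b_raw])
        sv = np.flatnonzero(alpha > 1e-10)
        self.support_ = sv
        self.dual_coef_ = (alpha[sv] * ypm[sv])[None, :]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        return X @ self.coef_[0] + self.intercept_[0]

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def fit_linear_svm(feature_matrix, labels, C: float = 1.0,
                   standardize: bool = True) -> LinearSVM:
    """Convenience wrapper: fit a :class:`LinearSVM` and return it."""
    return LinearSVM(C=C, standardize=standardize).fit(feature_matrix, labels)
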