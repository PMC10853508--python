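"""Low-level numba kernels.

Sequential-minimal-optimization (SMO) solver for the soft-margin linear SVM
dual, plus leave-one-out cross-validation loops with fold-internal t-score
feature ranking.  These loops are the hot path of the permutation machinery
(~10^6 SVM fits for a 1000-permutation tuning-curve null), which is why they
are compiled rather than composed from scikit-learn estimators; the estimator
layer in :mod:`nirscv.svm` is cross-checked against scikit-learn's libsvm
wrapper in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# SMO convergence: violating-pair gap tolerance and an iteration guard that is
# never reached on the problem sizes this package targets (n <= a few hundred).
# Tightening the gap below 1e-6 does not change the solution to 6 decimals on
# standardized inputs but can stall on a numerical plateau.
TOL = 1e-6
MAX_ITER = 200_000


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter, alpha):
    """Solve the SVM dual  min 0.5 a'Qa - e'a,  Q_ij = y_i y_j K_ij,
    s.t. y'a = 0, 0 <= a_i <= C,  by maximal-violating-pair SMO.

    ``alpha`` is used as a warm start (pass zeros for a cold start) and is
    updated in place.  Returns the bias term of the decision function
    f(x) = sum_i alpha_i y_i K(x_i, x) + b.
    """
    n = y.shape[0]
    # gradient of the dual objective: G = Q a - e
    grad = -np.ones(n)
    for i in range(n):
        if alpha[i] != 0.0:
            ai = alpha[i] * y[i]
            for t in range(n):
                grad[t] += y[t] * K[t, i] * ai

    for _ in range(max_iter):
        gmax = -1e300
        gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            yg = -y[t] * grad[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if yg > gmax:
                    gmax = yg
                    i = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                if yg < gmin:
                    gmin = yg
                    j = t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break

        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 1e-12:
            quad = 1e-12
        step = (gmax - gmin) / quad

        ai_old = alpha[i]
        aj_old = alpha[j]
        zeta = y[i] * ai_old + y[j] * aj_old
        # feasible interval for alpha_i along the constraint line
        if y[i] * y[j] > 0:
            s = y[i]
            lo = max(0.0, s * zeta - C)
            hi = min(C, s * zeta)
        else:
            lo = max(0.0, -y[j] * zeta)
            hi = min(C, C - y[j] * zeta)
        ai = ai_old + y[i] * step
        if ai < lo:
            ai = lo
        elif ai > hi:
            ai = hi
        aj = y[j] * (zeta - y[i] * ai)

        dai = ai - ai_old
        daj = aj - aj_old
        if dai == 0.0 and daj == 0.0:
            break
        alpha[i] = ai
        alpha[j] = aj
        for t in range(n):
            grad[t] += y[t] * (y[i] * K[t, i] * dai + y[j] * K[t, j] * daj)

    # bias from free support vectors; midpoint of the violating bounds if none
    nfree = 0
    bsum = 0.0
    for t in range(n):
        if 0.0 < alpha[t] < C:
            nfree += 1
            bsum += -y[t] * grad[t]
    if nfree > 0:
        return bsum / nfree
    gmax = -1e300
    gmin = 1e300
    for t in range(n):
        yg = -y[t] * grad[t]
        if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
            if yg > gmax:
                gmax = yg
            if yg < gmin:
                gmin = yg
        if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
            if yg < gmin:
                gmin = yg
            if yg > gmax:
                gmax = yg
    return 0.5 * (gmax + gmin)


@njit(cache=True)
def svm_fit(X, y, C, tol, max_iter):
    """Fit w, b of a linear soft-margin SVM on (X, y in {-1,+1})."""
    Xc = np.ascontiguousarray(X)
    K = Xc @ Xc.T
    alpha = np.zeros(Xc.shape[0])
    b = smo_solve(K, y, C, tol, max_iter, alpha)
    w = Xc.T @ (alpha * y)
    return w, b, alpha


@njit(cache=True)
def tstats(X, y, welch):
    """Two-sample t per column, class +1 minus class -1.

    Pooled-variance by default; Welch when ``welch`` is true.  Zero-variance
    columns yield t = 0.
    """
    n, p = X.shape
    out = np.zeros(p)
    n1 = 0
    for i in range(n):
        if y[i] > 0:
            n1 += 1
    n2 = n - n1
    for j in range(p):
        s1 = 0.0
        s2 = 0.0
        for i in range(n):
            if y[i] > 0:
                s1 += X[i, j]
            else:
                s2 += X[i, j]
        m1 = s1 / n1
        m2 = s2 / n2
        v1 = 0.0
        v2 = 0.0
        for i in range(n):
            if y[i] > 0:
                d = X[i, j] - m1
                v1 += d * d
            else:
                d = X[i, j] - m2
                v2 += d * d
        if welch:
            se2 = v1 / (n1 * (n1 - 1)) + v2 / (n2 * (n2 - 1))
        else:
            sp2 = (v1 + v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        if se2 > 0.0:
            out[j] = (m1 - m2) / np.sqrt(se2)
    return out


@njit(cache=True)
def rank_desc(a):
    """Indices sorting ``a`` descending; ties broken by the lower index."""
    p = a.shape[0]
    order = np.empty(p, np.int64)
    used = np.zeros(p, np.bool_)
    for r in range(p):
        best = -1
        bestv = -1e300
        for j in range(p):
            if not used[j] and a[j] > bestv:
                bestv = a[j]
                best = j
        order[r] = best
        used[best] = True
    return order


@njit(cache=True)
def _fold_standardize(Xtr, xte, cols):
    """Z-score the selected training columns; apply the same map to the
    held-out row.  Population SD; zero-variance columns pass through."""
    n, k = Xtr.shape[0], cols.shape[0]
    Z = np.empty((n, k))
    z = np.empty(k)
    for jj in range(k):
        c = cols[jj]
        m = 0.0
        for i in range(n):
            m += Xtr[i, c]
        m /= n
        v = 0.0
        for i in range(n):
            d = Xtr[i, c] - m
            v += d * d
        sd = np.sqrt(v / n)
        if sd < 1e-12:
            sd = 1.0
        for i in range(n):
            Z[i, jj] = (Xtr[i, c] - m) / sd
        z[jj] = (xte[c] - m) / sd
    return Z, z


@njit(cache=True)
def loo_scores(X, y, k, C, nested, welch, order_pooled):
    """Leave-one-out decision scores of the rank-select/standardize/SVM chain.

    ``nested`` re-ranks features by |t| inside each training fold; otherwise
    ``order_pooled`` (computed on all subjects) is used for every fold.
    Returns (scores, orders) with orders[h] the ranking used for fold h.
    """
    n, p = X.shape
    scores = np.empty(n)
    orders = np.empty((n, p), np.int64)
    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for h in range(n):
        m = 0
        for i in range(n):
            if i != h:
                for j in range(p):
                    Xtr[m, j] = X[i, j]
                ytr[m] = y[i]
                m += 1
        if nested:
            tv = tstats(Xtr, ytr, welch)
            order = rank_desc(np.abs(tv))
        else:
            order = order_pooled
        orders[h] = order
        cols = order[:k]
        Z, z = _fold_standardize(Xtr, X[h], cols)
        w, b, _ = svm_fit(Z, ytr, C, TOL, MAX_ITER)
        scores[h] = np.dot(w, z) + b
    return scores, orders


@njit(cache=True)
def loo_curve(X, y, kmax, C, nested, welch, order_pooled):
    """Leave-one-out accuracy for every k in 1..kmax.

    The per-fold ranking is k-independent, so the Gram matrix of the
    standardized selected features is grown one rank-1 update at a time and
    the SMO solution is warm-started from the previous k.
    """
    n, p = X.shape
    correct = np.zeros(kmax)
    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for h in range(n):
        m = 0
        for i in range(n):
            if i != h:
                for j in range(p):
                    Xtr[m, j] = X[i, j]
                ytr[m] = y[i]
                m += 1
        if nested:
            tv = tstats(Xtr, ytr, welch)
            order = rank_desc(np.abs(tv))
        else:
            order = order_pooled
        cols = order[:kmax]
        Z, z = _fold_standardize(Xtr, X[h], cols)
        K = np.zeros((n - 1, n - 1))
        kdot = np.zeros(n - 1)  # running Z[i,:k] . z[:k]
        alpha = np.zeros(n - 1)
        for kk in range(kmax):
            for a in range(n - 1):
                za = Z[a, kk]
                kdot[a] += za * z[kk]
                for bcol in range(n - 1):
                    K[a, bcol] += za * Z[bcol, kk]
            b = smo_solve(K, ytr, C, TOL, MAX_ITER, alpha)
            s = b
            for a in range(n - 1):
                s += alpha[a] * ytr[a] * kdot[a]
            pred = 1.0 if s > 0.0 else -1.0
            if pred == y[h]:
                correct[kk] += 1.0
    return correct / n
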