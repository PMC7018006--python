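"""L1-penalized logistic path solver (coordinate descent).

Minimizes  -(1/n) loglik(b0, beta) + lambda * ||beta||_1  over a
descending lambda grid with warm starts, in the classical way: an outer
iteratively-reweighted least-squares step builds the local quadratic
approximation, and an inner cyclic coordinate-descent loop with
soft-thresholding solves the penalized weighted least squares.
Screening follows the sequential strong rule (predictors whose gradient
at the previous solution is below 2*lam_l - lam_{l-1} are skipped), with
a full Karush-Kuhn-Tucker sweep at convergence so no violator is ever
missed.  Convergence is declared when the largest single-coordinate
objective improvement falls below ``thresh`` times the null deviance —
the natural scale-free criterion for penalized likelihood descent.
The intercept is never penalized.  Soft-thresholding yields exact
zeros, so at lambda >= lambda_max = max_j |x_j . (y - ybar)| / n every
coefficient is exactly 0.

The path stops early once the training deviance explained exceeds
``dev_max`` or improves fractionally by less than ``f_dev`` per step
(the model is saturated beyond that point).  Inputs are expected
standardized (zero mean, unit variance columns); the hot loops are
JIT-compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _cd_pass(X, w, wxx, r, beta, lam, n, candidate):
    """One cyclic coordinate pass; returns max objective decrease
    (wxx_j * delta_j^2 per coordinate, sum-of-weights * delta0^2 for the
    intercept handled by the caller)."""
    p = X.shape[1]
    omax = 0.0
    for j in range(p):
        if not candidate[j]:
            continue
        xj = X[:, j]
        rho = 0.0
        for i in range(n):
            rho += w[i] * xj[i] * r[i]
        rho = rho / n + wxx[j] * beta[j]
        # tiny slack so a coordinate sitting exactly on the threshold
        # (e.g. at lambda_max) stays exactly zero despite float rounding
        slack = lam * 1e-12
        if rho > lam + slack:
            bn = (rho - lam) / wxx[j]
        elif rho < -lam - slack:
            bn = (rho + lam) / wxx[j]
        else:
            bn = 0.0
        d = bn - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * xj[i]
            beta[j] = bn
            o = wxx[j] * d * d
            if o > omax:
                omax = o
    return omax


@njit(cache=True)
def _grad_all(X, w, r, n):
    """(1/n) X^T W r — KKT gradient for every coordinate."""
    p = X.shape[1]
    g = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * r[i]
        g[j] = s / n
    return g


@njit(cache=True)
def _deviance(y, eta, n):
    d = 0.0
    for i in range(n):
        e = eta[i]
        if e > 35.0:
            e = 35.0
        elif e < -35.0:
            e = -35.0
        pv = 1.0 / (1.0 + np.exp(-e))
        if y[i] > 0.5:
            d -= 2.0 * np.log(pv)
        else:
            d -= 2.0 * np.log(1.0 - pv)
    return d / n


@njit(cache=True)
def _logistic_path(X, y, lambdas, thresh, max_outer, max_inner, dev_max, f_dev):
    n, p = X.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    b0s = np.zeros(L)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    candidate = np.zeros(p, dtype=np.bool_)
    dev_null = _deviance(y, eta, n)
    otol = thresh * dev_null  # objective-scale convergence threshold
    prev_ratio = 0.0
    n_used = L
    for l in range(L):
        lam = lambdas[l]
        lam_prev = lambdas[l - 1] if l > 0 else lam
        # sequential strong rule at the previous solution
        pv0 = 1.0 / (1.0 + np.exp(-eta))
        thr = 2.0 * lam - lam_prev
        for j in range(p):
            if beta[j] != 0.0:
                candidate[j] = True
            else:
                s = 0.0
                for i in range(n):
                    s += X[i, j] * (y[i] - pv0[i])
                candidate[j] = abs(s) / n >= thr
        for _restart in range(5):  # re-enter if the KKT sweep finds violators
            for _outer in range(max_outer):
                pv = 1.0 / (1.0 + np.exp(-eta))
                w = pv * (1.0 - pv)
                for i in range(n):
                    if w[i] < 1e-5:
                        w[i] = 1e-5
                r = (y - pv) / w  # working residual z - eta
                wxx = np.empty(p)
                for j in range(p):
                    if candidate[j]:
                        s = 0.0
                        for i in range(n):
                            s += w[i] * X[i, j] * X[i, j]
                        wxx[j] = s / n
                    else:
                        wxx[j] = 1.0
                omax_first = -1.0
                for _inner in range(max_inner):
                    sw = 0.0
                    swr = 0.0
                    for i in range(n):
                        sw += w[i]
                        swr += w[i] * r[i]
                    d0 = swr / sw
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            r[i] -= d0
                    omax = _cd_pass(X, w, wxx, r, beta, lam, n, candidate)
                    o0 = (sw / n) * d0 * d0
                    if o0 > omax:
                        omax = o0
                    if omax_first < 0.0:
                        omax_first = omax
                    if omax < otol:
                        break
                # refresh eta from scratch (bounds drift of the residual trick)
                eta = np.full(n, b0)
                for j in range(p):
                    bj = beta[j]
                    if bj != 0.0:
                        for i in range(n):
                            eta[i] += bj * X[i, j]
                # IRLS converged when the re-solve barely moved anything
                if omax_first < otol:
                    break
            # KKT check over the full coordinate set
            pv = 1.0 / (1.0 + np.exp(-eta))
            w = pv * (1.0 - pv)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            r = (y - pv) / w
            g = _grad_all(X, w, r, n)
            violations = 0
            for j in range(p):
                if not candidate[j] and abs(g[j]) > lam * (1.0 + 1e-4):
                    candidate[j] = True
                    violations += 1
            if violations == 0:
                break
        coefs[l] = beta
        b0s[l] = b0
        # path early stopping on training-deviance saturation
        ratio = 1.0 - _deviance(y, eta, n) / dev_null
        if l > 0 and (ratio > dev_max or ratio - prev_ratio < f_dev * ratio):
            n_used = l + 1
            break
        prev_ratio = ratio
    return coefs, b0s, n_used


def lasso_logistic_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                        thresh: float = 1e-9, max_outer: int = 30,
                        max_inner: int = 1000, dev_max: float = 0.999,
                        f_dev: float = 1e-5, tol: float = None):
    """Coefficients and intercepts along a descending lambda grid.

    Returns ``(coefs, intercepts, n_used)`` with ``coefs`` of shape
    ``(len(lambdas), p)``; only the first ``n_used`` grid points were
    fitted (the rest hold the final solution's zeros).  ``thresh``
    bounds the per-coordinate objective improvement at convergence, in
    units of the null deviance.  X should be standardized.
    """
    if tol is not None:  # legacy alias
        thresh = tol
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if not np.all(np.diff(lambdas) <= 0):
        raise ValueError("lambda grid must be descending")
    return _logistic_path(X, y, lambdas, thresh, max_outer, max_inner,
                          dev_max, f_dev)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which every coefficient is exactly zero."""
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                        min_ratio: float = None) -> np.ndarray:
    """Log-spaced descending grid from lambda_max.

    ``min_ratio`` defaults to 1e-4 when n > p and 0.01 when p >= n —
    with more features than observations the deep end of the grid only
    re-fits an already saturated model.
    """
    if min_ratio is None:
        min_ratio = 1e-4 if X.shape[0] > X.shape[1] else 1e-2
    lm = lambda_max(X, y)
    return np.geomspace(lm, lm * min_ratio, n_lambdas)
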