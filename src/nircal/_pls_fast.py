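"""Compiled PLS1 kernels for the hot paths (sub-model CV inside BOSS, LOOCV).

These implement exactly the same NIPALS-for-univariate-y recursion as the
user-facing ``models.PLS`` (a test pins coefficient agreement to 1e-8); they
exist only because variable selection evaluates on the order of 10^4–10^5
small PLS fits per run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pls1_coefficients", "pls1_cv_rmse", "boss_iteration", "center"]

_TOL = 1e-12


@njit(cache=True)
def _fit_coefs(Xc: np.ndarray, yc: np.ndarray, a_max: int) -> np.ndarray:
    """Coefficient paths B[:, a] for 1..a_max components; Xc, yc centered.

    Uses the NIPALS/PLS1 recursion with X- and y-deflation; coefficients are
    accumulated through the R-weights r_a = w_a - sum_{k<a} (p_k . w_a) r_k,
    so B_a = sum_{k<=a} q_k r_k maps centered X to centered y. Degenerate
    components (zero residual) repeat the last valid column.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    B = np.zeros((p, a_max))
    R = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    b_cum = np.zeros(p)
    for a in range(a_max):
        w = X.T @ y
        nw = np.sqrt(np.sum(w * w))
        if nw < _TOL:
            for k in range(a, a_max):
                B[:, k] = b_cum
            break
        w = w / nw
        t = X @ w
        tt = np.sum(t * t)
        if tt < _TOL:
            for k in range(a, a_max):
                B[:, k] = b_cum
            break
        pv = (X.T @ t) / tt
        q = np.sum(y * t) / tt
        X -= np.outer(t, pv)
        y = y - q * t
        r = w.copy()
        for k in range(a):
            r -= np.sum(P[:, k] * w) * R[:, k]
        R[:, a] = r
        P[:, a] = pv
        b_cum = b_cum + q * r
        B[:, a] = b_cum
    return B


@njit(cache=True)
def _cv_rmse(X: np.ndarray, y: np.ndarray, fold_id: np.ndarray,
             n_folds: int, a_max: int) -> np.ndarray:
    """K-fold cross-validated RMSE for each component count 1..a_max."""
    n, p = X.shape
    sq = np.zeros(a_max)
    for f in range(n_folds):
        n_val = 0
        for i in range(n):
            if fold_id[i] == f:
                n_val += 1
        n_tr = n - n_val
        if n_val == 0 or n_tr < 2:
            continue
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        Xva = np.empty((n_val, p))
        yva = np.empty(n_val)
        it = 0
        iv = 0
        for i in range(n):
            if fold_id[i] == f:
                Xva[iv] = X[i]
                yva[iv] = y[i]
                iv += 1
            else:
                Xtr[it] = X[i]
                ytr[it] = y[i]
                it += 1
        xm = np.zeros(p)
        for j in range(p):
            xm[j] = np.mean(Xtr[:, j])
        ym = np.mean(ytr)
        Xtr -= xm
        ytr = ytr - ym
        Xva -= xm
        a_eff = min(a_max, n_tr - 1, p)
        if a_eff < 1:
            continue
        B = _fit_coefs(Xtr, ytr, a_eff)
        for a in range(a_max):
            col = a if a < a_eff else a_eff - 1
            pred = Xva @ B[:, col].copy() + ym
            for i in range(n_val):
                d = pred[i] - yva[i]
                sq[a] += d * d
    return np.sqrt(sq / n)


@njit(cache=True)
def boss_iteration(X: np.ndarray, y: np.ndarray, fold_id: np.ndarray,
                   n_folds: int, max_lv: int, cumw: np.ndarray,
                   unif: np.ndarray):
    """Score one BOSS iteration's sub-models.

    ``unif`` holds pre-drawn uniforms (one row per sub-model); each row is
    inverted through the weight CDF ``cumw`` to a weighted bootstrap draw,
    duplicates collapse to the unique variable set, and the sub-model's best
    cross-validated RMSE over 1..max_lv components is recorded.

    Returns (scores, best component counts, padded subsets, subset lengths).
    """
    n_sub, n_draws = unif.shape
    n, p = X.shape
    min_train = n - (n + n_folds - 1) // n_folds
    scores = np.empty(n_sub)
    best_as = np.empty(n_sub, np.int64)
    subsets = np.full((n_sub, n_draws), -1, dtype=np.int64)
    sub_lens = np.empty(n_sub, np.int64)
    for s in range(n_sub):
        idx = np.empty(n_draws, np.int64)
        for d in range(n_draws):
            idx[d] = np.searchsorted(cumw, unif[s, d], side="right")
        sub = np.unique(idx)
        m = sub.size
        subsets[s, :m] = sub
        sub_lens[s] = m
        a_max = min(max_lv, m, min_train - 1)
        if a_max < 1:
            a_max = 1
        Xs = np.empty((n, m))
        for j in range(m):
            Xs[:, j] = X[:, sub[j]]
        rmse = _cv_rmse(Xs, y, fold_id, n_folds, a_max)
        a_best = int(np.argmin(rmse))
        scores[s] = rmse[a_best]
        best_as[s] = a_best + 1
    return scores, best_as, subsets, sub_lens


def center(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    ym = float(y.mean())
    return X - xm, y - ym, xm, ym


def pls1_coefficients(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """Coefficient paths on raw (uncentered) data; returns B of shape (p, a_max)."""
    Xc, yc, _, _ = center(np.ascontiguousarray(X, dtype=np.float64),
                          np.ascontiguousarray(y, dtype=np.float64))
    return _fit_coefs(Xc, yc, int(a_max))


def pls1_cv_rmse(X: np.ndarray, y: np.ndarray, fold_id: np.ndarray,
                 n_folds: int, a_max: int) -> np.ndarray:
    """K-fold RMSECV per component count (fold_id: 0..n_folds-1 per sample)."""
    return _cv_rmse(np.ascontiguousarray(X, dtype=np.float64),
                    np.ascontiguousarray(y, dtype=np.float64),
                    np.ascontiguousarray(fold_id, dtype=np.int64),
                    int(n_folds), int(a_max))
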