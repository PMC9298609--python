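"""Calibration model families: PLS, LS-SVM (RBF), and MLR.

Each family follows the Model/Results pattern: construct the model from the
calibration arrays, call ``fit`` to obtain a Results object carrying the
estimates, then ``predict`` / ``summary`` on the results.

* **PLS** decomposes X = T Pᵀ + E and y = U qᵀ + F onto shared latent
  variables (LVs) and regresses the y-scores on the X-scores; the LV count is
  chosen by leave-one-out cross-validation when not given. The implementation
  is NIPALS for univariate y with X- and y-deflation; X and y are mean-centred,
  never autoscaled.
* **LS-SVM** is kernel ridge regression with a bias, solving the dual linear
  system ``[[0, 1ᵀ], [1, K + I/γ]] [b; α] = [0; y]`` with the RBF kernel
  ``K(x, x_k) = exp(-‖x − x_k‖² / (2σ²))``; γ and σ² come from a
  cross-validated grid search when not given.
* **MLR** is ordinary least squares with an intercept and requires more
  samples than variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from ._pls_fast import pls1_cv_rmse

__all__ = [
    "PLS", "PLSResults", "LSSVM", "LSSVMResults", "MLR", "MLRResults",
    "select_lv_loocv", "tune_lssvm", "load_model",
    "fit_pls", "predict_pls", "fit_lssvm", "predict_lssvm",
    "fit_mlr", "predict_mlr",
]

DEFAULT_MAX_LV = 15
DEFAULT_GAMMA_GRID = tuple(np.logspace(0, 7, 13))
DEFAULT_SIGMA2_GRID = tuple(np.logspace(0, 6, 13))


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    if X.shape[0] != y.size:
        raise ValueError("X and y sample counts differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X/y contain NaN or Inf")
    return X, y


def _arr(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _unarr(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


class _ResultsBase:
    """Shared serialization / summary plumbing."""

    kind: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(self._to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    def summary(self) -> str:
        lines = [f"{self.kind.upper()} calibration results",
                 "=" * 34]
        lines += [f"{k:>18}: {v}" for k, v in self._summary_fields()]
        return "\n".join(lines)


# --------------------------------------------------------------------------- PLS

class PLS:
    """Partial least squares calibration model (univariate y)."""

    def __init__(self, X, y):
        self.X, self.y = _as_xy(X, y)

    def fit(self, n_lv: int | None = None, max_lv: int = DEFAULT_MAX_LV) -> "PLSResults":
        """Fit with ``n_lv`` latent variables, or pick it by LOOCV when None."""
        rmsecv = None
        if n_lv is None:
            n_lv, rmsecv = select_lv_loocv(self.X, self.y, max_lv=max_lv)
        return _nipals_fit(self.X, self.y, int(n_lv), rmsecv)


@dataclass
class PLSResults(_ResultsBase):
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # W (p x A)
    x_loadings: np.ndarray   # P (p x A)
    y_loadings: np.ndarray   # q (A,)
    x_scores: np.ndarray     # T (n x A), training only
    y_scores: np.ndarray     # U (n x A), training only
    coef: np.ndarray         # B (p,), centred X -> centred y
    n_lv: int
    rmsecv: np.ndarray | None = None
    kind: str = "pls"

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"model has {self.coef.size} variables, data has {X.shape[1]}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean

    @property
    def n_variables(self) -> int:
        return int(self.coef.size)

    def _summary_fields(self):
        out = [("n latent vars", self.n_lv), ("n variables", self.n_variables)]
        if self.rmsecv is not None:
            out.append(("LOOCV RMSECV", f"{self.rmsecv[self.n_lv - 1]:.4f} °Brix"))
        return out

    def _to_dict(self) -> dict:
        return {
            "kind": self.kind, "n_lv": self.n_lv, "y_mean": self.y_mean,
            "x_mean": _arr(self.x_mean), "weights": _arr(self.weights),
            "x_loadings": _arr(self.x_loadings),
            "y_loadings": _arr(self.y_loadings),
            "x_scores": _arr(self.x_scores), "y_scores": _arr(self.y_scores),
            "coef": _arr(self.coef),
            "rmsecv": None if self.rmsecv is None else _arr(self.rmsecv),
        }

    @classmethod
    def _from_dict(cls, d: dict) -> "PLSResults":
        return cls(
            x_mean=_unarr(d["x_mean"]), y_mean=float(d["y_mean"]),
            weights=_unarr(d["weights"]), x_loadings=_unarr(d["x_loadings"]),
            y_loadings=_unarr(d["y_loadings"]), x_scores=_unarr(d["x_scores"]),
            y_scores=_unarr(d["y_scores"]), coef=_unarr(d["coef"]),
            n_lv=int(d["n_lv"]),
            rmsecv=None if d.get("rmsecv") is None else _unarr(d["rmsecv"]),
        )


def _nipals_fit(X: np.ndarray, y: np.ndarray, n_lv: int,
                rmsecv: np.ndarray | None = None) -> PLSResults:
    n, p = X.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xd = X - xm
    yd = y - ym
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    U = np.zeros((n, n_lv))
    R = np.zeros((p, n_lv))
    coef = np.zeros(p)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError(
                f"n_lv={n_lv} exceeds the effective rank of X ({a} components)"
            )
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            raise ValueError(
                f"n_lv={n_lv} exceeds the effective rank of X ({a} components)"
            )
        pv = Xd.T @ t / tt
        qa = (yd @ t) / tt
        U[:, a] = yd  # univariate y: the y-score is the current y residual
        Xd = Xd - np.outer(t, pv)
        yd = yd - qa * t
        r = w.copy()
        for k in range(a):
            r -= (P[:, k] @ w) * R[:, k]
        W[:, a], P[:, a], q[a], T[:, a], R[:, a] = w, pv, qa, t, r
        coef = coef + qa * r
    return PLSResults(x_mean=xm, y_mean=ym, weights=W, x_loadings=P,
                      y_loadings=q, x_scores=T, y_scores=U, coef=coef,
                      n_lv=n_lv, rmsecv=rmsecv)


def select_lv_loocv(X, y, max_lv: int = DEFAULT_MAX_LV) -> tuple[int, np.ndarray]:
    """Leave-one-out choice of the LV count; returns (n_lv, RMSECV per count).

    The returned vector has length ``min(max_lv, n - 2, p)``; ties pick the
    smaller (more parsimonious) count.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    a_max = min(int(max_lv), n - 2, p)
    if a_max < 1:
        raise ValueError("too few samples/variables for LOOCV")
    rmsecv = pls1_cv_rmse(X, y, np.arange(n), n, a_max)
    return int(np.argmin(rmsecv)) + 1, rmsecv


def fit_pls(X, y, n_lv: int) -> PLSResults:
    return PLS(X, y).fit(n_lv=n_lv)


def predict_pls(results: PLSResults, X) -> np.ndarray:
    return results.predict(X)


# ------------------------------------------------------------------------ LS-SVM

def _rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma2))


class LSSVM:
    """Least-squares support vector machine regression with an RBF kernel."""

    def __init__(self, X, y):
        self.X, self.y = _as_xy(X, y)

    def fit(self, gamma: float | None = None, sigma2: float | None = None,
            n_folds: int = 10, seed: int = 0,
            gamma_grid=None, sigma2_grid=None) -> "LSSVMResults":
        """Fit at (γ, σ²), or tune both on a CV grid when either is None."""
        cv_surface = None
        if gamma is None or sigma2 is None:
            gamma, sigma2, cv_surface = tune_lssvm(
                self.X, self.y,
                gamma_grid=gamma_grid, sigma2_grid=sigma2_grid,
                n_folds=n_folds, seed=seed)
        res = _solve_lssvm(self.X, self.y, float(gamma), float(sigma2))
        res.cv_surface = cv_surface
        return res


@dataclass
class LSSVMResults(_ResultsBase):
    alpha: np.ndarray
    b: float
    gamma: float
    sigma2: float
    X_train: np.ndarray
    y_train: np.ndarray
    cv_surface: np.ndarray | None = None
    kind: str = "lssvm"

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        K = _rbf_kernel(X, self.X_train, self.sigma2)
        return K @ self.alpha + self.b

    def dual_residual(self) -> float:
        """Relative residual of the KKT linear system (≤ ~1e-8 when healthy)."""
        n = self.X_train.shape[0]
        K = _rbf_kernel(self.X_train, self.X_train, self.sigma2)
        top = np.sum(self.alpha)
        body = self.b + (K + np.eye(n) / self.gamma) @ self.alpha - self.y_train
        num = np.sqrt(top ** 2 + np.sum(body ** 2))
        return float(num / max(1.0, np.linalg.norm(self.y_train)))

    @property
    def n_variables(self) -> int:
        return int(self.X_train.shape[1])

    def _summary_fields(self):
        return [("gamma", f"{self.gamma:.4g}"), ("sigma^2", f"{self.sigma2:.4g}"),
                ("n support values", self.alpha.size),
                ("n variables", self.n_variables)]

    def _to_dict(self) -> dict:
        return {"kind": self.kind, "b": self.b, "gamma": self.gamma,
                "sigma2": self.sigma2, "alpha": _arr(self.alpha),
                "X_train": _arr(self.X_train), "y_train": _arr(self.y_train)}

    @classmethod
    def _from_dict(cls, d: dict) -> "LSSVMResults":
        return cls(alpha=_unarr(d["alpha"]), b=float(d["b"]),
                   gamma=float(d["gamma"]), sigma2=float(d["sigma2"]),
                   X_train=_unarr(d["X_train"]), y_train=_unarr(d["y_train"]))


def _solve_lssvm(X: np.ndarray, y: np.ndarray, gamma: float,
                 sigma2: float) -> LSSVMResults:
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be > 0")
    n = X.shape[0]
    K = _rbf_kernel(X, X, sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = scipy.linalg.solve(A, rhs)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "LS-SVM dual system is singular; increase the ridge 1/γ "
            "(i.e. use a smaller γ)"
        ) from err
    res = LSSVMResults(alpha=sol[1:], b=float(sol[0]), gamma=gamma,
                       sigma2=sigma2, X_train=X.copy(), y_train=y.copy())
    if not np.all(np.isfinite(sol)) or res.dual_residual() > 1e-6:
        raise np.linalg.LinAlgError(
            "LS-SVM dual system is ill-conditioned; increase the ridge 1/γ "
            "(i.e. use a smaller γ)"
        )
    return res


def tune_lssvm(X, y, gamma_grid=None, sigma2_grid=None, n_folds: int = 10,
               seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Exhaustive CV grid search for (γ, σ²), ties toward smaller γ then σ².

    Returns the chosen pair plus the full CV-RMSE surface
    (len(gamma_grid) x len(sigma2_grid)). Grid points whose dual system fails
    are scored +inf. Fold assignment is seeded, so the choice is reproducible.
    """
    X, y = _as_xy(X, y)
    gammas = np.asarray(DEFAULT_GAMMA_GRID if gamma_grid is None else gamma_grid,
                        dtype=float)
    sigma2s = np.asarray(DEFAULT_SIGMA2_GRID if sigma2_grid is None else sigma2_grid,
                         dtype=float)
    if gammas.size == 0 or sigma2s.size == 0:
        raise ValueError("grids must be nonempty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = X.shape[0]
    n_folds = min(n_folds, n)
    fold_id = np.random.default_rng(seed).permutation(n) % n_folds
    D2 = cdist(X, X, "sqeuclidean")

    surface = np.full((gammas.size, sigma2s.size), np.inf)
    for js, s2 in enumerate(sigma2s):
        Kfull = np.exp(-D2 / (2.0 * s2))
        for jg, g in enumerate(gammas):
            sq = 0.0
            ok = True
            for f in range(n_folds):
                val = fold_id == f
                tr = ~val
                ntr = int(tr.sum())
                if ntr < 2 or not val.any():
                    continue
                A = np.zeros((ntr + 1, ntr + 1))
                A[0, 1:] = 1.0
                A[1:, 0] = 1.0
                A[1:, 1:] = Kfull[np.ix_(tr, tr)] + np.eye(ntr) / g
                rhs = np.concatenate([[0.0], y[tr]])
                try:
                    sol = scipy.linalg.solve(A, rhs)
                except scipy.linalg.LinAlgError:
                    ok = False
                    break
                pred = Kfull[np.ix_(val, tr)] @ sol[1:] + sol[0]
                sq += float(np.sum((pred - y[val]) ** 2))
            if ok:
                surface[jg, js] = np.sqrt(sq / n)
    best = surface.min()
    if not np.isfinite(best):
        raise np.linalg.LinAlgError(
            "every (gamma, sigma2) grid point produced a singular dual system"
        )
    # scan in ascending (gamma, sigma2) order so ties resolve toward the
    # smaller gamma, then the smaller sigma2
    for ig in np.argsort(gammas):
        for js in np.argsort(sigma2s):
            if surface[ig, js] == best:
                return float(gammas[ig]), float(sigma2s[js]), surface
    raise AssertionError("unreachable")


def fit_lssvm(X, y, gamma: float, sigma2: float) -> LSSVMResults:
    X, y = _as_xy(X, y)
    return _solve_lssvm(X, y, float(gamma), float(sigma2))


def predict_lssvm(results: LSSVMResults, X) -> np.ndarray:
    return results.predict(X)


# --------------------------------------------------------------------------- MLR

class MLR:
    """Multiple linear regression (OLS with intercept); needs n > p variables."""

    def __init__(self, X, y):
        self.X, self.y = _as_xy(X, y)

    def fit(self) -> "MLRResults":
        X, y = self.X, self.y
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(
                f"MLR requires more samples than variables (n={n}, p={p}); "
                "select fewer wavelengths first"
            )
        A = np.column_stack([np.ones(n), X])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p + 1:
            raise ValueError(
                "design matrix is rank deficient; MLR requires more (independent) "
                "samples than variables"
            )
        return MLRResults(coef=coef[1:], intercept=float(coef[0]))


@dataclass
class MLRResults(_ResultsBase):
    coef: np.ndarray
    intercept: float
    kind: str = "mlr"

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"model has {self.coef.size} variables, data has {X.shape[1]}"
            )
        return X @ self.coef + self.intercept

    @property
    def n_variables(self) -> int:
        return int(self.coef.size)

    def _summary_fields(self):
        return [("n variables", self.n_variables),
                ("intercept", f"{self.intercept:.4f}")]

    def _to_dict(self) -> dict:
        return {"kind": self.kind, "intercept": self.intercept,
                "coef": _arr(self.coef)}

    @classmethod
    def _from_dict(cls, d: dict) -> "MLRResults":
        return cls(coef=_unarr(d["coef"]), intercept=float(d["intercept"]))


def fit_mlr(X, y) -> MLRResults:
    return MLR(X, y).fit()


def predict_mlr(results: MLRResults, X) -> np.ndarray:
    return results.predict(X)


# ------------------------------------------------------------------- persistence

_KINDS = {"pls": PLSResults, "lssvm": LSSVMResults, "mlr": MLRResults}


def load_model(source: str | Path):
    """Load any serialized Results object from a JSON document or file path."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    d = json.loads(text)
    try:
        cls = _KINDS[d["kind"]]
    except KeyError:
        raise ValueError(f"unknown model kind {d.get('kind')!r}") from None
    return cls._from_dict(d)
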