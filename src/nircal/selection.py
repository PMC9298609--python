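"""Wavelength selection: bootstrapping soft shrinkage (BOSS), the successive
projections algorithm (SPA), and their combination (BOSS then SPA).

**BOSS** maintains a weight per wavelength (initially uniform). Each iteration
draws many random variable subsets by weighted bootstrap sampling (with
replacement, draw count = number of currently retained variables; duplicates
collapse to the unique set), fits a PLS sub-model to each and scores it by
cross-validated RMSECV. Model population analysis over the best fraction of
sub-models gives the next weights: each variable's weight is the normalised
sum of its absolute PLS regression coefficients across the kept sub-models.
Uninformative variables are never deleted outright — they receive weight 0 and
simply stop being sampled (soft shrinkage). Each iteration is scored by the
cross-validated RMSECV of a PLS model on the currently retained variable set
(this is the U-shaped RMSECV-vs-iteration curve: high with all channels,
falling as noise channels drop out, rising again once informative channels
start to go). Iteration continues until a single variable remains; the
retained set of the lowest-RMSECV iteration is returned.

**SPA** is greedy forward selection that minimises collinearity: from every
candidate starting wavelength it grows a chain, at each step projecting all
unselected columns onto the orthogonal complement of the selected span and
picking the column with the largest residual norm. Every (start, prefix)
candidate subset is scored by MLR RMSEP on a validation set; the subset with
the smallest RMSEP wins. Fully deterministic.

**BOSS-SPA** runs SPA restricted to the columns BOSS kept, so its selection is
always a subset of BOSS's (the full > BOSS > BOSS-SPA reduction pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pls_fast import boss_iteration, pls1_coefficients, pls1_cv_rmse
from .models import MLR

__all__ = ["BossConfig", "SelectionResult", "boss", "spa", "boss_spa"]


@dataclass
class BossConfig:
    """BOSS hyperparameters (the classical defaults; none are data-derived)."""

    n_submodels: int = 1000
    best_fraction: float = 0.1
    max_lv: int = 10
    cv_folds: int = 5
    seed: int = 0
    max_iter: int = 300
    #: iterations without support shrinkage before the termination safeguard
    #: starts shedding lowest-weight variables (see docs/methods.md)
    stall_patience: int = 5

    def validate(self) -> None:
        if not 0 < self.best_fraction <= 1:
            raise ValueError("best_fraction must lie in (0, 1]")
        if self.n_submodels < 10:
            raise ValueError("n_submodels must be >= 10")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")


@dataclass
class SelectionResult:
    """Selected channel indices plus per-iteration traces."""

    selected_indices: np.ndarray
    method: str
    nvar_trace: list[int] = field(default_factory=list)
    rmsecv_trace: list[float] = field(default_factory=list)
    weight_history: list[np.ndarray] = field(default_factory=list)
    #: sub-results of a combined method, keyed by stage name
    stages: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    @property
    def best_rmsecv(self) -> float:
        return float(np.min(self.rmsecv_trace))


def boss(X_cal: np.ndarray, y_cal: np.ndarray, config: BossConfig | None = None
         ) -> SelectionResult:
    """Run BOSS on the calibration block; deterministic under ``config.seed``."""
    config = config or BossConfig()
    config.validate()
    X = np.ascontiguousarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("BOSS needs at least 2 variables")
    if y.size != n:
        raise ValueError("X_cal and y_cal sample counts differ")

    rng = np.random.default_rng(config.seed)
    n_folds = min(config.cv_folds, n)
    fold_id = rng.permutation(n) % n_folds
    n_keep = max(1, int(round(config.n_submodels * config.best_fraction)))

    weights = np.full(p, 1.0 / p)
    support = np.arange(p)
    nvar_trace: list[int] = []
    rmsecv_trace: list[float] = []
    weight_history: list[np.ndarray] = []
    support_history: list[np.ndarray] = []
    stall = 0

    for _ in range(config.max_iter):
        n_current = support.size
        nvar_trace.append(n_current)
        support_history.append(support.copy())
        weight_history.append(weights.copy())

        # iteration score: CV error of a PLS model on the retained set
        a_full = max(1, min(config.max_lv, n_current,
                            n - int(np.ceil(n / n_folds)) - 1))
        rmse_full = pls1_cv_rmse(X[:, support], y, fold_id, n_folds, a_full)
        rmsecv_trace.append(float(np.min(rmse_full)))

        if n_current == 1:
            break

        # weighted bootstrap draws via CDF inversion of pre-drawn uniforms:
        # the numpy Generator stays the single source of randomness while the
        # per-sub-model scoring runs inside one compiled kernel.
        cumw = np.cumsum(weights)
        cumw[-1] = 1.0
        unif = rng.random((config.n_submodels, n_current))
        scores, best_as, subsets, sub_lens = boss_iteration(
            X, y, fold_id, n_folds, config.max_lv, cumw, unif)
        finite = np.isfinite(scores)
        if not finite.any():
            raise RuntimeError(
                f"all sub-models failed at iteration {len(nvar_trace) - 1}"
            )
        scores = np.where(finite, scores, np.inf)
        kept = np.argsort(scores, kind="stable")[:n_keep]
        new_w = np.zeros(p)
        for s in kept:
            sub = subsets[s, :sub_lens[s]]
            B = pls1_coefficients(X[:, sub], y, int(best_as[s]))[:, best_as[s] - 1]
            new_w[sub] += np.abs(B)
        total = new_w.sum()
        if total <= 0:
            raise RuntimeError(
                f"degenerate weight update at iteration {len(nvar_trace) - 1}"
            )
        weights = new_w / total
        new_support = np.nonzero(weights)[0]

        if new_support.size >= support.size:
            stall += 1
        else:
            stall = 0
        if stall >= config.stall_patience and new_support.size > 1:
            # Termination safeguard: the union of the kept sub-models' variables
            # can reach a fixed point above one variable; while stalled, shed
            # the lowest-weight 5% (at least one) per iteration so the count
            # still reaches 1 as the procedure requires.
            n_drop = max(1, int(0.05 * new_support.size))
            n_drop = min(n_drop, new_support.size - 1)
            order = new_support[np.argsort(weights[new_support], kind="stable")]
            weights[order[:n_drop]] = 0.0
            weights /= weights.sum()
            new_support = np.nonzero(weights)[0]
        support = new_support
    else:
        raise RuntimeError(f"BOSS did not converge within {config.max_iter} iterations")

    best_iter = int(np.argmin(rmsecv_trace))
    return SelectionResult(
        selected_indices=support_history[best_iter],
        method="boss",
        nvar_trace=nvar_trace,
        rmsecv_trace=rmsecv_trace,
        weight_history=weight_history,
    )


def spa_chain(X: np.ndarray, start: int, max_vars: int,
              rel_tol: float = 1e-10) -> list[int]:
    """One deterministic SPA projection chain from a given starting column.

    Truncates (never raises) when all remaining residual norms are ~0, i.e.
    the unselected columns are numerically in the span of the selected ones.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    R = X.copy()
    scale = max(float(np.max(np.linalg.norm(X, axis=0))), 1e-300)
    chain = [int(start)]
    in_chain = np.zeros(p, dtype=bool)
    in_chain[start] = True
    while len(chain) < max_vars:
        v = R[:, chain[-1]]
        nv2 = v @ v
        if nv2 <= (rel_tol * scale) ** 2:
            break
        R = R - np.outer(v, (v @ R) / nv2)
        norms = np.linalg.norm(R, axis=0)
        norms[in_chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= rel_tol * scale:
            break
        chain.append(nxt)
        in_chain[nxt] = True
    return chain


def spa(X_cal: np.ndarray, y_cal: np.ndarray, X_val: np.ndarray,
        y_val: np.ndarray, max_vars: int = 30) -> SelectionResult:
    """SPA with MLR-RMSEP subset scoring on an explicit validation block.

    Chains are grown from every candidate start; the prefix with the lowest
    validation RMSEP wins (ties: fewer variables, then lower start index).
    ``max_vars`` must stay below the calibration sample count (MLR needs more
    samples than variables).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    n, p = X_cal.shape
    if max_vars >= n - 1:
        raise ValueError(
            f"max_vars={max_vars} too large: MLR needs n_cal > vars + 1 (n_cal={n})"
        )
    if np.any(np.linalg.norm(X_cal, axis=0) == 0):
        raise ValueError("X_cal contains an all-zero column")
    max_vars = min(max_vars, p)

    best = (np.inf, np.inf, np.inf)  # (rmsep, k, start)
    best_subset: list[int] | None = None
    best_per_k = np.full(max_vars + 1, np.inf)
    for start in range(p):
        chain = spa_chain(X_cal, start, max_vars)
        for k in range(1, len(chain) + 1):
            sub = chain[:k]
            try:
                fit = MLR(X_cal[:, sub], y_cal).fit()
            except (ValueError, np.linalg.LinAlgError):
                continue
            resid = fit.predict(X_val[:, sub]) - y_val
            rmsep = float(np.sqrt(np.mean(resid ** 2)))
            best_per_k[k] = min(best_per_k[k], rmsep)
            cand = (rmsep, k, start)
            if cand < best:
                best = cand
                best_subset = sub
    if best_subset is None:
        raise RuntimeError("no SPA candidate subset could be fitted")
    ks = np.nonzero(np.isfinite(best_per_k))[0]
    return SelectionResult(
        selected_indices=np.sort(np.asarray(best_subset)),
        method="spa",
        nvar_trace=[int(k) for k in ks],
        rmsecv_trace=[float(best_per_k[k]) for k in ks],
    )


def boss_spa(X_cal: np.ndarray, y_cal: np.ndarray, X_val: np.ndarray,
             y_val: np.ndarray, boss_config: BossConfig | None = None,
             max_vars: int = 30,
             boss_result: SelectionResult | None = None) -> SelectionResult:
    """BOSS first, then SPA restricted to the BOSS-retained columns.

    Pass an existing ``boss_result`` (from the same calibration block) to skip
    re-running the BOSS stage.
    """
    stage1 = boss_result if boss_result is not None else boss(X_cal, y_cal, boss_config)
    cols = stage1.selected_indices
    if cols.size == 1:
        result = SelectionResult(selected_indices=cols.copy(), method="boss-spa",
                                 nvar_trace=list(stage1.nvar_trace),
                                 rmsecv_trace=list(stage1.rmsecv_trace))
        result.stages = {"boss": stage1}
        return result
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    eff_max = min(max_vars, cols.size)
    stage2 = spa(X_cal[:, cols], y_cal, X_val[:, cols], y_val, max_vars=eff_max)
    selected = cols[stage2.selected_indices]
    result = SelectionResult(selected_indices=np.sort(selected), method="boss-spa",
                             nvar_trace=list(stage1.nvar_trace),
                             rmsecv_trace=list(stage1.rmsecv_trace))
    result.stages = {"boss": stage1, "spa": stage2}
    return result
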