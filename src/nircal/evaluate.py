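"""Model evaluation: the study's goodness score and RMSE metrics, per-model
report rows, and the repeated-resampling stability protocol.

The headline score ``r = 1 - SSE/SST`` is an R²-form quantity (it equals 1 for
perfect prediction, 0 for predicting the mean, and can go negative). Because
the field often labels this a "correlation coefficient", the Pearson
correlation is computed alongside under its own, unambiguous name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .split import random_split

__all__ = [
    "r_score", "pearson_r", "rmse", "EvaluationRow", "evaluate_model",
    "StabilityReport", "stability_analysis",
]


def _pair(y_actual, y_predicted):
    ya = np.asarray(y_actual, dtype=float).ravel()
    yp = np.asarray(y_predicted, dtype=float).ravel()
    if ya.size != yp.size:
        raise ValueError("vectors have different lengths")
    if ya.size == 0:
        raise ValueError("empty input")
    return ya, yp


def r_score(y_actual, y_predicted) -> float:
    """``1 - SSE/SST``: 1 for perfect prediction, 0 for the mean predictor."""
    ya, yp = _pair(y_actual, y_predicted)
    if ya.size < 2:
        raise ValueError("need at least 2 samples")
    sst = float(np.sum((ya - ya.mean()) ** 2))
    if sst == 0:
        raise ValueError("y_actual is constant; score undefined")
    return 1.0 - float(np.sum((ya - yp) ** 2)) / sst


def pearson_r(y_actual, y_predicted) -> float:
    """Plain Pearson correlation between measured and predicted values.

    Returns NaN for a constant prediction vector (correlation undefined there,
    but a constant predictor is still a legitimate model to score by RMSE).
    """
    ya, yp = _pair(y_actual, y_predicted)
    if ya.std() == 0:
        raise ValueError("correlation undefined: y_actual is constant")
    if yp.std() == 0:
        return float("nan")
    return float(np.corrcoef(ya, yp)[0, 1])


def rmse(y_actual, y_predicted, which: str = "prediction") -> float:
    """Root mean square error in °Brix; ``which`` only labels the quantity."""
    if which not in ("calibration", "prediction", "cv"):
        raise ValueError("which must be 'calibration', 'prediction' or 'cv'")
    ya, yp = _pair(y_actual, y_predicted)
    return float(np.sqrt(np.mean((yp - ya) ** 2)))


@dataclass
class EvaluationRow:
    """One model's table row: hyperparameters + the four headline metrics."""

    model: str
    hyperparams: str
    n_variables: int
    r_c: float
    rmsec: float
    r_p: float
    rmsep: float
    pearson_c: float
    pearson_p: float

    def as_dict(self) -> dict:
        return {
            "model": self.model, "hyperparams": self.hyperparams,
            "n_variables": self.n_variables,
            "r_c": self.r_c, "RMSEC": self.rmsec,
            "r_p": self.r_p, "RMSEP": self.rmsep,
            "pearson_c": self.pearson_c, "pearson_p": self.pearson_p,
        }


def _describe(results) -> str:
    kind = getattr(results, "kind", "model")
    if kind == "pls":
        return f"LV={results.n_lv}"
    if kind == "lssvm":
        return f"gamma={results.gamma:.3g}, sigma2={results.sigma2:.3g}"
    if kind == "mlr":
        return "-"
    return "-"


def evaluate_model(results, X_cal, y_cal, X_pred, y_pred,
                   model_tag: str | None = None) -> EvaluationRow:
    """Compute r_c/RMSEC on the calibration block and r_p/RMSEP on the
    prediction block for a fitted Results object."""
    yc_hat = results.predict(X_cal)
    yp_hat = results.predict(X_pred)
    return EvaluationRow(
        model=model_tag or getattr(results, "kind", "model"),
        hyperparams=_describe(results),
        n_variables=int(getattr(results, "n_variables", np.asarray(X_cal).shape[1])),
        r_c=r_score(y_cal, yc_hat),
        rmsec=rmse(y_cal, yc_hat, "calibration"),
        r_p=r_score(y_pred, yp_hat),
        rmsep=rmse(y_pred, yp_hat, "prediction"),
        pearson_c=pearson_r(y_cal, yc_hat),
        pearson_p=pearson_r(y_pred, yp_hat),
    )


@dataclass
class StabilityReport:
    """Per-repeat metric rows for each model plus mean ± S.D. summaries."""

    rows: pd.DataFrame
    n_repeats: int
    failed: list[tuple[int, str, str]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and sample S.D. of each metric per model (the error bars)."""
        metrics = ["r_c", "RMSEC", "r_p", "RMSEP"]
        g = self.rows.groupby("model")[metrics]
        out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)
        out.columns = [f"{m}_{s}" for s, m in out.columns]
        return out

    def metrics_for(self, model: str) -> pd.DataFrame:
        return self.rows[self.rows["model"] == model].reset_index(drop=True)


ModelBuilder = Callable[[np.ndarray, np.ndarray, int], object]
Selector = Callable[[np.ndarray, np.ndarray, int], np.ndarray]


def stability_analysis(X: np.ndarray, y: np.ndarray,
                       builders: Mapping[str, ModelBuilder],
                       n_repeats: int = 20, cal_fraction: float = 0.75,
                       base_seed: int = 0,
                       selector: Selector | None = None) -> StabilityReport:
    """Repeated random-resampling stability protocol.

    For each repeat ``r`` the samples are randomly re-divided 3:1 (seed
    ``base_seed + r``), the optional ``selector(X_cal, y_cal, seed)`` picks a
    column subset once per repeat (shared by all builders, mirroring a single
    selection step feeding several model families), every builder fits on the
    calibration block and is scored on the held-out block. A failing repeat is
    recorded and excluded from the summary with a warning rather than aborting
    the protocol.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if y.size != X.shape[0]:
        raise ValueError("X and y sample counts differ")

    records: list[dict] = []
    failed: list[tuple[int, str, str]] = []
    for r in range(n_repeats):
        seed = base_seed + r
        split = random_split(X.shape[0], cal_fraction, seed=seed)
        ci, pi = split.calibration_indices, split.prediction_indices
        Xc, yc, Xp, yp = X[ci], y[ci], X[pi], y[pi]
        try:
            cols = (np.arange(X.shape[1]) if selector is None
                    else np.asarray(selector(Xc, yc, seed), dtype=int))
        except Exception as err:  # noqa: BLE001 - protocol must survive one bad repeat
            for name in builders:
                failed.append((r, name, f"selector: {err}"))
            warnings.warn(f"repeat {r}: selector failed ({err}); repeat excluded",
                          stacklevel=2)
            continue
        for name, build in builders.items():
            try:
                fitted = build(Xc[:, cols], yc, seed)
                row = evaluate_model(fitted, Xc[:, cols], yc, Xp[:, cols], yp,
                                     model_tag=name)
            except Exception as err:  # noqa: BLE001
                failed.append((r, name, str(err)))
                warnings.warn(f"repeat {r}, model {name}: {err}; excluded",
                              stacklevel=2)
                continue
            rec = row.as_dict()
            rec.update({"repeat": r, "seed": seed, "n_selected": cols.size})
            records.append(rec)
    rows = pd.DataFrame.from_records(records)
    return StabilityReport(rows=rows, n_repeats=n_repeats, failed=failed)
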