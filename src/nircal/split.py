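"""Sample-set partitioning: deterministic Kennard-Stone and seeded random splits.

A calibration study fixes one Kennard-Stone (KS) calibration/prediction split
for all model comparisons, and re-draws random 3:1 splits only for the final
stability protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "kennard_stone", "random_split"]


@dataclass
class SplitResult:
    """Disjoint calibration/prediction index sets covering all samples."""

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=int)
        pred = np.asarray(self.prediction_indices, dtype=int)
        n = cal.size + pred.size
        combined = np.sort(np.concatenate([cal, pred]))
        if not np.array_equal(combined, np.arange(n)):
            raise ValueError("index sets must be disjoint and cover 0..n-1")
        self.calibration_indices = np.sort(cal)
        self.prediction_indices = np.sort(pred)

    @property
    def n_samples(self) -> int:
        return self.calibration_indices.size + self.prediction_indices.size

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "method": self.method,
            "seed": self.seed,
            "calibration_indices": self.calibration_indices.tolist(),
            "prediction_indices": self.prediction_indices.tolist(),
        }, indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitResult":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(np.asarray(d["calibration_indices"]),
                   np.asarray(d["prediction_indices"]),
                   d.get("method", "unknown"), d.get("seed"))


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitResult:
    """Kennard-Stone max–min Euclidean selection of ``n_cal`` calibration samples.

    The first two picks are the sample pair at maximal distance; each later
    pick maximises the minimum distance to the already-selected set. Ties are
    broken toward the lowest sample index, so the result is deterministic —
    duplicate rows never raise.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    n = X.shape[0]
    if not (2 <= n_cal <= n):
        raise ValueError("require 2 <= n_cal <= n_samples")

    D = squareform(pdist(X))
    # argmax on the flattened matrix gives the lexicographically first (i, j)
    # among tied maxima -> lowest-index tie-break for free.
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    mind = np.minimum(D[selected[0]], D[selected[1]])
    mind[selected] = -np.inf
    for _ in range(n_cal - 2):
        nxt = int(np.argmax(mind))
        selected.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    cal = np.sort(np.asarray(selected))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, method="kennard-stone")


def random_split(n: int, cal_fraction: float = 0.75, seed: int = 0) -> SplitResult:
    """Uniform random partition with ``round(n * cal_fraction)`` calibration samples."""
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    n_cal = int(np.floor(n * cal_fraction + 0.5))
    if n_cal == 0 or n_cal == n:
        raise ValueError(
            f"cal_fraction {cal_fraction} yields an empty set for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(perm[:n_cal], perm[n_cal:], method="random", seed=seed)
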