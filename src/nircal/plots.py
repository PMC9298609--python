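"""Minimal plotting helpers: stability bars and predicted-vs-measured scatter."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_stability", "plot_predicted_vs_measured", "plot_selection_trace"]


def plot_stability(report, metric: str = "RMSEP", ax=None):
    """Bar chart of a stability metric's per-model mean with S.D. error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = report.summary()
    models = list(s.index)
    means = s[f"{metric}_mean"].to_numpy()
    sds = s[f"{metric}_sd"].to_numpy()
    ax.bar(models, means, yerr=sds, capsize=4, color="#4878a8")
    ax.set_ylabel(f"{metric} (°Brix)" if "RMSE" in metric else metric)
    ax.set_title(f"{report.n_repeats}-resample stability")
    return ax


def plot_predicted_vs_measured(y_actual, y_predicted, ax=None, label=None):
    """Scatter of predicted vs measured SSC with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ya = np.asarray(y_actual, float).ravel()
    yp = np.asarray(y_predicted, float).ravel()
    ax.scatter(ya, yp, s=18, alpha=0.8, label=label)
    lo, hi = min(ya.min(), yp.min()), max(ya.max(), yp.max())
    ax.plot([lo, hi], [lo, hi], "r-", lw=1)
    ax.set_xlabel("measured SSC (°Brix)")
    ax.set_ylabel("predicted SSC (°Brix)")
    if label:
        ax.legend()
    return ax


def plot_selection_trace(result, ax=None):
    """nVAR and best-RMSECV traces of an iterative selection run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    it = np.arange(len(result.nvar_trace))
    ax.plot(it, result.nvar_trace, "o-", ms=3, label="nVAR")
    ax.set_xlabel("iteration")
    ax.set_ylabel("retained variables")
    ax2 = ax.twinx()
    ax2.plot(it[:len(result.rmsecv_trace)], result.rmsecv_trace, "s-", ms=3,
             color="#b0413e", label="RMSECV")
    ax2.set_ylabel("best RMSECV (°Brix)")
    ax.set_title(result.method)
    return ax
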