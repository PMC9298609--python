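"""Spectral pretreatments: Savitzky-Golay smoothing/derivatives, SNV, MSC.

The six pipelines a pear-SSC calibration study compares are exposed by name
(``none``, ``sg``, ``sg-msc``, ``sg-snv``, ``d1-sg-msc``, ``d2-sg-msc``) as
composable transforms with train/apply semantics: MSC learns its reference
spectrum from calibration rows only, so held-out samples are corrected without
any information leaking back from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet

__all__ = [
    "savitzky_golay", "snv", "msc_fit", "msc_apply",
    "PreprocessPipeline", "build_pipeline", "PIPELINE_NAMES",
]


def savitzky_golay(spectra: SpectrumSet, window: int = 11, polyorder: int = 2,
                   deriv: int = 0) -> SpectrumSet:
    """Per-row Savitzky-Golay polynomial filtering.

    ``deriv >= 1`` scales by the channel spacing so derivative units are per
    nm (the grid must be uniform). Derivatives are obtained from the SG
    polynomial fit itself, not finite differences.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    if polyorder < deriv:
        raise ValueError("polyorder must be >= deriv")
    if window > spectra.n_channels:
        raise ValueError(
            f"window {window} exceeds channel count {spectra.n_channels}"
        )
    delta = spectra.channel_spacing() if deriv else 1.0
    X = savgol_filter(spectra.intensities, window_length=window,
                      polyorder=polyorder, deriv=deriv, delta=delta, axis=1)
    return spectra.replace(intensities=X)


def snv(spectra: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: centre each row, scale to unit (n-1) S.D."""
    X = spectra.intensities
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(
            f"SNV undefined for constant spectrum of sample "
            f"'{spectra.sample_ids[flat[0]]}'"
        )
    return spectra.replace(intensities=(X - mu) / sd)


def msc_fit(calibration: SpectrumSet) -> np.ndarray:
    """MSC reference spectrum: the mean calibration spectrum."""
    ref = calibration.intensities.mean(axis=0)
    if ref.std() == 0:
        raise ValueError("MSC reference spectrum has no spread")
    return ref


def msc_apply(spectra: SpectrumSet, reference: np.ndarray) -> SpectrumSet:
    """Invert per-sample affine scatter: fit x_i ≈ a_i·ref + b_i, return (x_i − b_i)/a_i."""
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != spectra.n_channels:
        raise ValueError("reference length does not match channel count")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference spectrum has no spread")
    X = spectra.intensities
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    zero = np.nonzero(a == 0)[0]
    if zero.size:
        raise ValueError(
            f"MSC slope is zero for sample '{spectra.sample_ids[zero[0]]}'"
        )
    b = X.mean(axis=1) - a * ref.mean()
    return spectra.replace(intensities=(X - b[:, None]) / a[:, None])


@dataclass
class PreprocessPipeline:
    """Ordered pretreatment steps with fit (calibration) / apply semantics."""

    steps: list[tuple[str, dict]] = field(default_factory=list)
    msc_reference_: np.ndarray | None = None

    @property
    def needs_fit(self) -> bool:
        return any(name == "msc" for name, _ in self.steps)

    def fit(self, calibration: SpectrumSet) -> "PreprocessPipeline":
        """Learn fitted state (the MSC reference) from calibration rows only."""
        current = calibration
        for name, params in self.steps:
            if name == "msc":
                self.msc_reference_ = msc_fit(current)
                current = msc_apply(current, self.msc_reference_)
            else:
                current = _apply_step(current, name, params, None)
        return self

    def apply(self, spectra: SpectrumSet) -> SpectrumSet:
        if self.needs_fit and self.msc_reference_ is None:
            raise RuntimeError("pipeline contains MSC: call fit() before apply()")
        current = spectra
        for name, params in self.steps:
            current = _apply_step(current, name, params, self.msc_reference_)
        return current

    def fit_apply(self, calibration: SpectrumSet) -> SpectrumSet:
        return self.fit(calibration).apply(calibration)


def _apply_step(s: SpectrumSet, name: str, params: dict,
                msc_reference: np.ndarray | None) -> SpectrumSet:
    if name == "savgol":
        return savitzky_golay(s, **params)
    if name == "snv":
        return snv(s)
    if name == "msc":
        return msc_apply(s, msc_reference)
    raise ValueError(f"unknown pipeline step '{name}'")


# Canonical short names -> ordered steps; derivative first where the study's
# row label names it, then MSC/SNV. The SG defaults (window 11, polyorder 2)
# suit a 2 nm grid and are overridable per pipeline via build_pipeline kwargs.
_SG = ("savgol", {"deriv": 0})
_RECIPES: dict[str, list[tuple[str, dict]]] = {
    "none": [],
    "sg": [_SG],
    "sg-msc": [_SG, ("msc", {})],
    "sg-snv": [_SG, ("snv", {})],
    "d1-sg-msc": [("savgol", {"deriv": 1}), ("msc", {})],
    "d2-sg-msc": [("savgol", {"deriv": 2}), ("msc", {})],
}
_ALIASES = {
    "sg": "sg",
    "sg-msc": "sg-msc",
    "sg-snv": "sg-snv",
    "first derivative-sg-msc": "d1-sg-msc",
    "second derivative-sg-msc": "d2-sg-msc",
    "d1-sg-msc": "d1-sg-msc",
    "d2-sg-msc": "d2-sg-msc",
    "none": "none",
}
PIPELINE_NAMES = tuple(_RECIPES)


def build_pipeline(name: str, window: int = 11, polyorder: int = 2) -> PreprocessPipeline:
    """Build one of the six named pretreatment pipelines.

    Accepts the short CLI names and the descriptive labels
    ("SG-MSC", "First derivative-SG-MSC", ...), case-insensitively.
    """
    key = _ALIASES.get(str(name).strip().lower())
    if key is None:
        raise ValueError(
            f"unknown pipeline '{name}'; valid names: {', '.join(PIPELINE_NAMES)}"
        )
    steps = []
    for sname, params in _RECIPES[key]:
        p = dict(params)
        if sname == "savgol":
            p.setdefault("window", window)
            p.setdefault("polyorder", max(polyorder, p.get("deriv", 0)))
        steps.append((sname, p))
    return PreprocessPipeline(steps=steps)
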