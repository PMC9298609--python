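"""Spectral data container, instrument relative-reflectance transform, cropping, CSV I/O.

A :class:`SpectrumSet` holds one shared wavelength grid (the portable device has a
fixed grid) together with an ``n_samples x n_channels`` intensity matrix and, when
available, one reference soluble-solids-content (SSC) value per sample in °Brix.

The instrument records a raw sample spectrum ``R`` along with dark (``D``, source
off) and white (``W``, source on, no sample) references; the relative spectrum used
for all modelling is ``Rc = (R - D) / (W - D)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "relative_spectrum", "crop", "read_csv", "write_csv"]


@dataclass
class SpectrumSet:
    """Wavelength grid + sample x channel intensities + optional SSC labels.

    Parameters
    ----------
    wavelengths : array-like of float, shape (p,)
        Channel wavelengths in nm. Stored strictly increasing; columns are
        re-sorted (with the intensity matrix permuted consistently) if supplied
        in another order.
    intensities : array-like of float, shape (n, p)
        Reflectance- or absorbance-like values (dimensionless).
    sample_ids : sequence of str, optional
        One label per sample; defaults to ``s0 .. s{n-1}``.
    ssc : array-like of float, shape (n,), optional
        Reference SSC in °Brix; all values must be > 0 when present.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    ssc: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths contain NaN or Inf")
        if not np.all(np.isfinite(X)):
            raise ValueError("intensities contain NaN or Inf")
        if X.shape[1] != wl.size:
            raise ValueError(
                f"intensity matrix has {X.shape[1]} columns but {wl.size} wavelengths"
            )
        if np.unique(wl).size != wl.size:
            raise ValueError("duplicate wavelengths in grid")
        order = np.argsort(wl)
        if not np.all(order == np.arange(wl.size)):
            wl = wl[order]
            X = X[:, order]
        self.wavelengths = wl
        self.intensities = X
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(X.shape[0])]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != X.shape[0]:
                raise ValueError("sample_ids length does not match sample count")
        if self.ssc is not None:
            y = np.asarray(self.ssc, dtype=float).ravel()
            if y.size != X.shape[0]:
                raise ValueError("ssc length does not match sample count")
            if not np.all(np.isfinite(y)):
                raise ValueError("ssc contains NaN or Inf")
            if np.any(y <= 0):
                raise ValueError("ssc values must be > 0 °Brix")
            self.ssc = y

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def replace(self, **kwargs) -> "SpectrumSet":
        """Return a copy with the given fields replaced."""
        data = dict(
            wavelengths=self.wavelengths.copy(),
            intensities=self.intensities.copy(),
            sample_ids=list(self.sample_ids),
            ssc=None if self.ssc is None else self.ssc.copy(),
        )
        data.update(kwargs)
        return SpectrumSet(**data)

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        """Row subset (e.g. a calibration or prediction split)."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            wavelengths=self.wavelengths.copy(),
            intensities=self.intensities[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            ssc=None if self.ssc is None else self.ssc[idx],
        )

    def channel_spacing(self) -> float:
        """Uniform grid step in nm; raises if the grid is not uniform."""
        d = np.diff(self.wavelengths)
        if d.size == 0:
            raise ValueError("single-channel set has no spacing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
            raise ValueError("wavelength grid is not uniformly spaced")
        return float(d[0])


def _check_same_grid(a: SpectrumSet, b: SpectrumSet, what: str) -> None:
    if a.n_channels != b.n_channels or not np.allclose(
        a.wavelengths, b.wavelengths, rtol=0, atol=1e-9
    ):
        raise ValueError(f"wavelength grids of raw and {what} spectra differ")


def relative_spectrum(
    raw: SpectrumSet, dark: SpectrumSet, white: SpectrumSet
) -> SpectrumSet:
    """Apply the instrument transform ``Rc = (R - D) / (W - D)`` channel-wise.

    ``dark`` and ``white`` may hold a single reference spectrum (broadcast over
    samples) or one row per sample of ``raw``. Sample ids and SSC labels are
    carried over from ``raw``.
    """
    _check_same_grid(raw, dark, "dark")
    _check_same_grid(raw, white, "white")
    for ref, name in ((dark, "dark"), (white, "white")):
        if ref.n_samples not in (1, raw.n_samples):
            raise ValueError(
                f"{name} reference must have 1 row or match the sample count"
            )
    D = dark.intensities
    W = white.intensities
    denom = W - D
    bad = np.nonzero(np.any(np.abs(denom) < 1e-300, axis=0))[0]
    if bad.size:
        lam = raw.wavelengths[bad[0]]
        raise ValueError(
            f"white and dark references coincide at channel {bad[0]} ({lam:g} nm)"
        )
    rc = (raw.intensities - D) / denom
    return SpectrumSet(raw.wavelengths.copy(), rc, list(raw.sample_ids),
                       None if raw.ssc is None else raw.ssc.copy())


def crop(spectra: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Retain channels with ``lo <= wavelength <= hi`` (closed interval).

    The study device covers 500–1,010 nm but both spectral ends are noisy, so
    modelling uses 550–1,000 nm; that crop is the caller's choice here.
    """
    if not lo < hi:
        raise ValueError("crop requires lo < hi")
    mask = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"cropping to [{lo:g}, {hi:g}] nm leaves {int(mask.sum())} channel(s); "
            "at least 2 required"
        )
    return SpectrumSet(
        spectra.wavelengths[mask],
        spectra.intensities[:, mask],
        list(spectra.sample_ids),
        None if spectra.ssc is None else spectra.ssc.copy(),
    )


_CSV_ID, _CSV_SSC = "sample_id", "ssc"


def write_csv(spectra: SpectrumSet, path: str | Path) -> None:
    """Write to CSV: columns ``sample_id``, ``ssc`` (if present), then wavelengths."""
    cols: dict[str, object] = {_CSV_ID: spectra.sample_ids}
    if spectra.ssc is not None:
        cols[_CSV_SSC] = spectra.ssc
    for j, wl in enumerate(spectra.wavelengths):
        cols[repr(float(wl))] = spectra.intensities[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_csv(path: str | Path) -> SpectrumSet:
    """Read a spectra CSV written by :func:`write_csv` (or hand-assembled).

    Header must contain ``sample_id`` and numeric wavelength column names;
    an ``ssc`` column is optional. Decreasing wavelength columns are re-sorted
    ascending with the matrix permuted consistently.
    """
    df = pd.read_csv(path, dtype=str)
    if _CSV_ID not in df.columns:
        raise ValueError(f"{path}: missing required '{_CSV_ID}' column")
    wl_cols = [c for c in df.columns if c not in (_CSV_ID, _CSV_SSC)]
    wls = []
    for c in wl_cols:
        try:
            wls.append(float(c))
        except ValueError:
            raise ValueError(
                f"{path}: column '{c}' is neither '{_CSV_ID}', '{_CSV_SSC}' "
                "nor a numeric wavelength"
            ) from None
    if len(set(wls)) != len(wls):
        dupes = sorted({w for w in wls if wls.count(w) > 1})
        raise ValueError(f"{path}: duplicate wavelength column(s) {dupes}")

    def _numeric(col: str) -> np.ndarray:
        vals = np.empty(len(df), dtype=float)
        for i, cell in enumerate(df[col].tolist()):
            try:
                vals[i] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i}, column '{col}'"
                ) from None
        return vals

    X = np.column_stack([_numeric(c) for c in wl_cols]) if wl_cols else np.empty((len(df), 0))
    ssc = _numeric(_CSV_SSC) if _CSV_SSC in df.columns else None
    return SpectrumSet(np.asarray(wls), X, df[_CSV_ID].tolist(), ssc)
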