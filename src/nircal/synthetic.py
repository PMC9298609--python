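"""Synthetic Vis/NIR interactance spectra with a known SSC -> spectrum structure.

The generator emulates the statistical shape of a portable-spectrometer pear
study — n ≈ 120 fruit, SSC distributed around 12.6 °Brix (S.D. 0.8, range
11.0–14.5), spectra on a 550–1,000 nm grid at 2 nm — without any claim of
radiative-transfer realism. Each spectrum is

    x(λ) = baseline(λ) + Σ_b coef_b(SSC) · exp(-(λ - c_b)² / (2 w_b²))

where the coefficient of *informative* bands is affine in the sample's SSC
(a Beer–Lambert-like limit), then a per-sample multiplicative slope (1 + s_i)
and additive offset o_i emulate size-dependent scatter (exactly the distortion
MSC/SNV are designed to remove), and i.i.d. Gaussian noise is added last.
Amplitudes are in arbitrary absorbance-like units; the device defines none.

Default band centres follow the absorption features a pear spectrum shows:
~680 nm (chlorophyll), ~750 nm (4th overtone C–H) and ~950 nm (2nd overtone
O–H); the two overtone bands are SSC-informative, the chlorophyll band is not.

The ground truth records exactly the channels where any informative band's
Gaussian exceeds half its peak height, giving downstream variable-selection
tests an unambiguous recovery criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import SpectrumSet

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "planted_config"]

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # half-width at half max = _HALF_MAX * w


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the emulated study population."""

    n_samples: int = 120
    wavelength_start: float = 550.0
    wavelength_end: float = 1000.0
    step: float = 2.0
    ssc_mean: float = 12.6
    ssc_sd: float = 0.8
    ssc_min: float = 11.0
    ssc_max: float = 14.5
    band_centers: tuple[float, ...] = (680.0, 750.0, 950.0)
    band_widths: tuple[float, ...] = (15.0, 35.0, 25.0)
    band_amplitudes: tuple[float, ...] = (0.55, 0.35, 0.25)
    #: amplitude change per °Brix deviation from ssc_mean, per band
    band_ssc_slopes: tuple[float, ...] = (0.0, 0.06, 0.05)
    #: per-sample random amplitude S.D. per band (varying non-sugar
    #: constituents, e.g. chlorophyll); informative bands stay exactly
    #: affine in SSC when their entry is 0
    band_amplitude_sds: tuple[float, ...] | None = None
    informative_band_ids: tuple[int, ...] = (1, 2)
    baseline_coeffs: tuple[float, ...] = (0.40, 0.15, -0.10)
    scatter_slope_sd: float = 0.12
    scatter_offset_sd: float = 0.06
    noise_sd: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("wavelength_start", "wavelength_end", "step", "ssc_mean",
                     "ssc_sd", "ssc_min", "ssc_max", "scatter_slope_sd",
                     "scatter_offset_sd", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value: {name}")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength_end must exceed wavelength_start")
        if not (self.ssc_min <= self.ssc_mean <= self.ssc_max):
            raise ValueError("require ssc_min <= ssc_mean <= ssc_max")
        nb = len(self.band_centers)
        if self.band_amplitude_sds is None:
            self.band_amplitude_sds = (0.0,) * nb
        if not (len(self.band_widths) == len(self.band_amplitudes)
                == len(self.band_ssc_slopes)
                == len(self.band_amplitude_sds) == nb):
            raise ValueError("band parameter tuples must have equal length")
        if not all(np.isfinite(v) for v in
                   (*self.band_centers, *self.band_widths,
                    *self.band_amplitudes, *self.band_ssc_slopes,
                    *self.band_amplitude_sds)):
            raise ValueError("non-finite band parameter")
        if any(s < 0 for s in self.band_amplitude_sds):
            raise ValueError("band amplitude S.D.s must be >= 0")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be > 0")
        for c in self.band_centers:
            if not (self.wavelength_start <= c <= self.wavelength_end):
                raise ValueError(f"band centre {c} nm outside the wavelength range")
        if any(b < 0 or b >= nb for b in self.informative_band_ids):
            raise ValueError("informative_band_ids out of range")

    def wavelength_grid(self) -> np.ndarray:
        n = int(np.floor((self.wavelength_end - self.wavelength_start) / self.step + 0.5))
        return self.wavelength_start + self.step * np.arange(n + 1)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis is asked to recover."""

    informative_channel_indices: np.ndarray
    true_ssc: np.ndarray
    noise_sd_used: float

    def write_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.informative_channel_indices, fmt="%d")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Rejection sampling; simplest way to match both moments and range."""
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    have = 0
    while have < n:
        draw = rng.normal(mean, sd, size=2 * (n - have) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - have)
        out[have:have + take] = keep[:take]
        have += take
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[SpectrumSet, GroundTruth]:
    """Draw a seeded synthetic dataset; bit-identical under the same config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelength_grid()
    p = wl.size

    ssc = _truncated_normal(rng, config.ssc_mean, config.ssc_sd,
                            config.ssc_min, config.ssc_max, config.n_samples)

    u = (wl - config.wavelength_start) / (config.wavelength_end - config.wavelength_start)
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(config.baseline_coeffs))

    X = np.tile(baseline, (config.n_samples, 1))
    informative = set(config.informative_band_ids)
    for b, (c, w, amp, slope, amp_sd) in enumerate(
            zip(config.band_centers, config.band_widths,
                config.band_amplitudes, config.band_ssc_slopes,
                config.band_amplitude_sds)):
        shape = np.exp(-((wl - c) ** 2) / (2.0 * w ** 2))
        if b in informative:
            coef = amp + slope * (ssc - config.ssc_mean)
        else:
            coef = np.full(config.n_samples, amp)
        if amp_sd > 0:
            coef = coef + rng.normal(0.0, amp_sd, size=config.n_samples)
        X += coef[:, None] * shape[None, :]

    slopes = 1.0 + rng.normal(0.0, config.scatter_slope_sd, size=config.n_samples)
    offsets = rng.normal(0.0, config.scatter_offset_sd, size=config.n_samples)
    X = X * slopes[:, None] + offsets[:, None]
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    mask = np.zeros(p, dtype=bool)
    for b in config.informative_band_ids:
        c, w = config.band_centers[b], config.band_widths[b]
        mask |= np.abs(wl - c) <= _HALF_MAX * w
    truth = GroundTruth(np.nonzero(mask)[0], ssc.copy(), config.noise_sd)

    spectra = SpectrumSet(wl, X, [f"s{i}" for i in range(config.n_samples)], ssc)
    return spectra, truth


def planted_config(seed: int = 0, n_samples: int = 120,
                   noise_sd: float = 0.025) -> SyntheticConfig:
    """A sparse "planted" design for variable-selection benchmarks.

    Two narrow SSC-informative bands whose half-maximum support covers exactly
    4 channels each on the default 2 nm grid — 8 planted channels out of 226.
    Each informative band hides a narrow *interfering* band inside its own
    support, centred slightly off the band centre, whose amplitude varies
    randomly from sample to sample but carries no SSC information (a varying
    non-sugar constituent). Because the interferent can only be observed
    through the planted channels themselves, separating signal from
    interferent requires combining several channels of the band — so a good
    selection method is genuinely rewarded for keeping the planted channels
    rather than collapsing each band to one representative. The interferent is
    kept mild so every planted channel still carries a clearly positive
    signal-to-noise ratio on its own. All other channels carry only baseline,
    mild scatter and noise.
    """
    return SyntheticConfig(
        n_samples=n_samples,
        band_centers=(681.0, 949.0, 679.5, 950.5),
        band_widths=(2.9, 2.9, 1.8, 1.8),
        band_amplitudes=(0.5, 0.45, 0.25, 0.25),
        band_ssc_slopes=(0.12, 0.11, 0.0, 0.0),
        band_amplitude_sds=(0.0, 0.0, 0.02, 0.02),
        informative_band_ids=(0, 1),
        baseline_coeffs=(0.2,),
        scatter_slope_sd=0.02,
        scatter_offset_sd=0.01,
        noise_sd=noise_sd,
        seed=seed,
    )
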