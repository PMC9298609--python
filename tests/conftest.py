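import numpy as np
import pytest

from nircal import SpectrumSet, SyntheticConfig, generate_dataset, planted_config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_set():
    """A tiny hand-checkable spectrum set (3 samples x 5 channels)."""
    wl = np.array([550.0, 552.0, 554.0, 556.0, 558.0])
    X = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [0.5, 0.4, 0.3, 0.2, 0.1],
        [2.0, 2.0, 2.1, 2.2, 2.0],
    ])
    return SpectrumSet(wl, X, ["a", "b", "c"], np.array([12.0, 11.5, 13.0]))


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the default synthetic population (120 x 226)."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def planted_dataset():
    """Sparse design: exactly 8 SSC-informative channels out of 226."""
    return generate_dataset(planted_config(seed=7))


@pytest.fixture(scope="session")
def clean_linear_dataset():
    """Noise-free, scatter-free spectra: intensities exactly affine in SSC."""
    cfg = SyntheticConfig(seed=3, noise_sd=0.0, scatter_slope_sd=0.0,
                          scatter_offset_sd=0.0)
    return generate_dataset(cfg)
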