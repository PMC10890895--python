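import numpy as np
import pytest

from sfl.histograms import SpectralTemporalHistogram
from sfl.simulate import SimulationConfig, exponential_irf


@pytest.fixture
def small_config():
    """Reduced instrument geometry used to keep unit tests fast."""
    return SimulationConfig(n_channels=24, n_bins=160, dt_ns=0.05, seed=11)


@pytest.fixture
def small_irf(small_config):
    return exponential_irf(small_config)


@pytest.fixture
def full_config():
    """The full measurement geometry: 160 channels x 490 bins of 0.05 ns."""
    return SimulationConfig(seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240126)


@pytest.fixture
def toy_histogram():
    """Tiny integer-count histogram on an irregular wavelength grid."""
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 50, size=(5, 12)).astype(float)
    return SpectralTemporalHistogram(
        counts=counts,
        wavelengths_nm=np.array([560.0, 570.5, 581.0, 600.0, 630.0]),
        bin_centers_ns=(np.arange(12) + 0.5) * 0.05,
        label="toy",
        group="simulated",
    )
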