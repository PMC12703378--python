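import numpy as np
import pytest
from hypothesis import settings

from vinispec import SimulationConfig, generate_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def small_config(**overrides) -> SimulationConfig:
    """A reduced simulation (60 samples, 700-1100 nm at 2 nm) that keeps all
    default planted bands inside the grid but runs every selector fast."""
    defaults = dict(n_samples=60, wavelength_start_nm=700.0,
                    wavelength_end_nm=1100.0, wavelength_step_nm=2.0, seed=5)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Scatter-free, noise-free small dataset: spectra are exact linear
    functions of the reference values."""
    cfg = small_config(noise_sd=0.0, scatter_gain_range=(1.0, 1.0),
                       scatter_offset_sd=0.0)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
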