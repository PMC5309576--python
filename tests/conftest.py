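import numpy as np
import pytest
from hypothesis import settings

from tidalcompare import SimConfig, simulate_recording

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Noise-free, drift-free, perfectly synchronised configuration."""
    return SimConfig(
        cv_timing=0.0,
        artifact_rate=0.0,
        noise_sd_pnt=0.0,
        noise_sd_slp=0.0,
        drift_amplitude=0.0,
        inter_device_offset=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return simulate_recording(clean_config, seed=1)


@pytest.fixture(scope="session")
def noisy_recording():
    return simulate_recording(SimConfig(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
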