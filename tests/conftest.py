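import numpy as np
import pytest

from bloommap import LGPHyperparams, VolumeConfig


@pytest.fixture
def field_volume() -> VolumeConfig:
    """Field-trial operational volume (1500x1500x50 m, 15x15x10 grid)."""
    return VolumeConfig(
        origin_lat=78.9548,
        origin_lon=11.9475,
        orientation_theta=-45.0,
        extent=(1500.0, 1500.0, 50.0),
        grid_dims=(15, 15, 10),
    )


@pytest.fixture
def sim_volume() -> VolumeConfig:
    """Reduced simulation volume (1000x1000x50 m, 10x10x5 grid)."""
    return VolumeConfig(
        origin_lat=78.9548,
        origin_lon=11.9475,
        orientation_theta=-45.0,
        extent=(1000.0, 1000.0, 50.0),
        grid_dims=(10, 10, 5),
    )


@pytest.fixture
def field_hp() -> LGPHyperparams:
    """Field-trial model hyperparameters."""
    return LGPHyperparams(M=(600.0, 600.0, 3.0, 10_000.0), sigma_c=1.6, sigma_n=0.7)


@pytest.fixture
def sim_hp() -> LGPHyperparams:
    """Simulation-scale hyperparameters (lengths scaled with the domain)."""
    return LGPHyperparams(M=(400.0, 400.0, 6.0, 10_000.0), sigma_c=1.6, sigma_n=0.7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240508)
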