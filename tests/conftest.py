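import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wmhtract import SimulationConfig, make_atlas, make_lesions

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    """Small, fast study configuration shared across unit tests."""
    return SimulationConfig(
        seed=7,
        n_patients=10,
        n_controls=8,
        grid_shape=(16, 16, 16),
        n_rois=12,
        n_volumes=70,
        window_length=30,
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_cfg):
    return make_atlas(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_lesions(tiny_cfg, tiny_atlas):
    return make_lesions(tiny_cfg, tiny_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
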