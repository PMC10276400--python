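import numpy as np
import pytest

from leafpheno.synth import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scene config used across tests (128 px, 64 cm frame)."""
    return SceneConfig(width_px=128, height_px=128)


@pytest.fixture(scope="session")
def midseason_scene(small_config):
    return generate_scene(small_config, day=45.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
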