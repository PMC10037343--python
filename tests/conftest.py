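import numpy as np
import pytest

from fibrojoint import synthetic as syn


@pytest.fixture(scope="session")
def scene():
    """Default fiber-bundle scene (2.5 mm field, 100 px sensor), shared."""
    return syn.make_bundle_scene(syn.SceneConfig(rng_seed=1))


@pytest.fixture(scope="session")
def sensor_center(scene):
    c = (scene.sensor_px - 1) / 2.0
    return (c, c)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
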