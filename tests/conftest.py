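import numpy as np
import pytest

from carcasskit.phantom import default_config, generate_phantom


@pytest.fixture(scope="session")
def small_cfg():
    """Default phantom geometry rendered at 10 px/cm (fast)."""
    return default_config().with_scale(0.4)


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return generate_phantom(small_cfg, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
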