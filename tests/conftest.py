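import numpy as np
import pytest

from svdfuse import RGBImage, make_phantom_pair


@pytest.fixture(scope="session")
def phantom64():
    """Small phantom pair shared across tests."""
    return make_phantom_pair(seed=7, size=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_rgb(rng):
    return RGBImage(*rng.random((3, 16, 16)))
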