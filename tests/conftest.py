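import numpy as np
import pytest

from mirsim.phantom import make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mri_phantom64():
    return make_phantom(64, seed=2, mode="mri")


@pytest.fixture(scope="session")
def ct_phantom36():
    return make_phantom(36, seed=5, mode="ct")
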