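import numpy as np
import pytest

from emegscan.forward import HeadModelSpec
from emegscan.phantom import make_phantom


@pytest.fixture(scope="session")
def head():
    return HeadModelSpec()


@pytest.fixture(scope="session")
def phantom_small():
    """Coarse phantom (12 mm grid, ~600 sources) for fast inverse tests."""
    return make_phantom(spacing_mm=12.0, seed=1)


@pytest.fixture(scope="session")
def phantom_default():
    """Default-resolution phantom (8 mm grid) shared across slower tests."""
    return make_phantom(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
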