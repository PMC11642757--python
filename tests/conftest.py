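import numpy as np
import pytest

from mosaicabc import make_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def geometry():
    return make_geometry(256)
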