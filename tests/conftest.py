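import numpy as np
import pytest

from spindlescale.params import STATE_DEFAULTS


@pytest.fixture(scope="session")
def esc():
    return STATE_DEFAULTS["ESC"]


@pytest.fixture(scope="session")
def dif():
    return STATE_DEFAULTS["DIF"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
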