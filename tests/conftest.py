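import numpy as np
import pytest

from spindlequant.core import OpticsParams
from spindlequant.synthetic_spindle import make_spindle_model


@pytest.fixture(scope="session")
def confocal():
    return OpticsParams.confocal()


@pytest.fixture(scope="session")
def sted():
    return OpticsParams.sted()


@pytest.fixture()
def small_model():
    return make_spindle_model(n_pairs=4, spindle_length=8.0, spindle_width=5.0,
                              seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
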