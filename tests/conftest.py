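import numpy as np
import pytest

from rootzone import ModelParameters, NitrogenRegime


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def ammonium():
    return NitrogenRegime.constant(0)


@pytest.fixture
def nitrate():
    return NitrogenRegime.constant(1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
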