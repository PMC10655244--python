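import numpy as np
import pytest

from ringstack.model import ForceField


@pytest.fixture
def ff():
    return ForceField()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
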