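import numpy as np
import pytest

from fluidmark import fixtures as fx


@pytest.fixture(scope="session")
def saliva():
    return fx.saliva_table()


@pytest.fixture(scope="session")
def serum():
    return fx.serum_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
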