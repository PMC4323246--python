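import numpy as np
import pytest

from exomefunnel.simulate import table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)
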