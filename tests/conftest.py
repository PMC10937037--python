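import numpy as np
import pytest

from oscicycle import cbg_graph, motif_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cbg():
    return cbg_graph()


@pytest.fixture
def iii_graph():
    return motif_graph("III")
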