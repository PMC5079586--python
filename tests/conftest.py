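import numpy as np
import pytest

from lenassess import SelectivityParams
from lenassess.datasets import bacalao_life_history


@pytest.fixture(scope="session")
def lh():
    """Bacalao life history: L∞=110, Lm50=65.3, M=0.29, M/k=2.7, Tmax=21."""
    return bacalao_life_history()


@pytest.fixture(scope="session")
def sel_2012():
    """Published fitted gear selectivity for the 2012 fishery."""
    return SelectivityParams(39.0, 46.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
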