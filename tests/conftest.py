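import numpy as np
import pytest

from structdrift import canonical_machine


@pytest.fixture
def alternating():
    return canonical_machine("alternating")


@pytest.fixture
def fair_coin():
    return canonical_machine("fair_coin")


@pytest.fixture
def golden_mean():
    return canonical_machine("golden_mean", p=0.5)


@pytest.fixture
def even_process():
    return canonical_machine("even", p=0.5)


@pytest.fixture
def fixed_coin():
    return canonical_machine("fixed_coin", symbol="1")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
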