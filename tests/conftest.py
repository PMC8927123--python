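import numpy as np
import pytest

from dyncomm import QuotientSpec, planted_equitable_network
from dyncomm.network import random_quotient

#: cluster sizes of the reference 50-node synthetic network
SIZES_50 = (10, 4, 7, 20, 9)
#: proportionally scaled-down 30-node variant
SIZES_30 = (6, 3, 4, 12, 5)


@pytest.fixture(scope="session")
def planted50():
    """Reference 50-node network with 5 planted equitable clusters."""
    spec = QuotientSpec(SIZES_50, random_quotient(5, seed=1))
    return planted_equitable_network(spec, seed=1)


@pytest.fixture(scope="session")
def planted30():
    spec = QuotientSpec(SIZES_30, random_quotient(5, seed=1))
    return planted_equitable_network(spec, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
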