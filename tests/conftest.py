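import numpy as np
import pytest

from coopnet.experiments import cascade_matrix, cycle_matrix
from coopnet.networks import CommunityInteractions


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def cycle7():
    """Directed 7-species cooperation cycle (all weights 1)."""
    return cycle_matrix(7)


@pytest.fixture
def cascade7():
    """Support chain 1->2->...->7 with a terminal self-link: pruning
    cascades down to the single self-sustaining species."""
    return cascade_matrix(7)


@pytest.fixture
def cycle7_inter(cycle7):
    zero = np.zeros_like(cycle7)
    return CommunityInteractions(cycle7, zero, zero, 1.0, 0.0, 0.0)


def pure_cooperation(M, eps1=1.0):
    zero = np.zeros_like(M)
    return CommunityInteractions(M, zero, zero, eps1, 0.0, 0.0, validate=False)


@pytest.fixture
def make_pure_cooperation():
    return pure_cooperation
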