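import numpy as np
import pytest

from cprstab import CommunityParameters, SpecialistCommunity


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_params():
    """One consumer on one resource with unit rates; equilibrium at (1, 1)."""
    return CommunityParameters(C=[[1.0]], rho=[1.0], mu=[1.0], epsilon=1.0)


@pytest.fixture
def reciprocal_pair():
    """Two specialists exchanging 0.4 of each other's resource."""
    P = np.array([[0.0, 0.4], [0.4, 0.0]])
    return SpecialistCommunity(c=1.0, s=1.0, r=1.0, P=P, epsilon=1.0)
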