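import numpy as np
import pytest

from mbw.reaction_network import PAPER_ALPHA, PAPER_KDS, build_network


@pytest.fixture(scope="session")
def estimated_kds():
    """Relative dissociation constants estimated from the pull-down data."""
    return dict(PAPER_KDS)


@pytest.fixture(scope="session")
def estimated_alpha():
    return PAPER_ALPHA


@pytest.fixture(scope="session")
def dimer_network():
    """22-species network: GL3 homodimerization, GL1 + TTG1, no inhibitor."""
    return build_network(include_try=False, include_gl3_dimer=True)


@pytest.fixture(scope="session")
def try_network():
    """Inhibitor-extended network (TRY competing for the MYB site)."""
    return build_network(include_try=True, include_gl3_dimer=True)


@pytest.fixture(scope="session")
def trimer_network():
    """Minimal cooperative model as a network: x, y, z, xy, xz, xyz."""
    return build_network(include_try=False, include_gl3_dimer=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
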