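import numpy as np
import pytest

from bioflink import synthetic_community as syn


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_community():
    """One small community exercising all four evidence channels."""
    plan = tuple(
        (4 + (i % 6), i % 4, frozenset({syn.CHANNELS[i % 4]})) for i in range(8)
    )
    spec = syn.CommunitySpec(
        n_hosts=4,
        n_phages=10,
        link_plan=plan,
        seed=101,
        closed_phages=(0, 1),
        provirus_phages=(2,),
        da_n_genes=60,
        da_n_shifted=8,
    )
    return syn.generate_community(spec)


@pytest.fixture(scope="session")
def dtr_panel():
    return syn.generate_dtr_panel(3, n_clean=20)
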