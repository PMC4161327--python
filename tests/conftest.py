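import numpy as np
import pytest

from regvar.motif import load_foxa_core_pfm, pfm_to_pwm
from regvar.simulate import paper_like, simulate_haplotype_panel


@pytest.fixture(scope="session")
def foxa_pfm():
    return load_foxa_core_pfm()


@pytest.fixture(scope="session")
def foxa_pwm(foxa_pfm):
    return pfm_to_pwm(foxa_pfm)


@pytest.fixture(scope="session")
def paper_panel():
    """Exact-count haplotype panel for the default 11-proxy scenario."""
    return simulate_haplotype_panel(paper_like(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20140911)
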