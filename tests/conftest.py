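import pytest

import emsmap as em

from ._util import small_genome


@pytest.fixture(scope="session")
def genome():
    """Default 3 x 100 kb fixture genome with the causal gene on chr3."""
    return em.simulate_genome(seed=11)


@pytest.fixture(scope="session")
def two_chrom_genome():
    """Smaller 2-chromosome genome for Monte-Carlo heavy tests."""
    return small_genome()


@pytest.fixture()
def config():
    return em.CrossSimConfig(seed=7)
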