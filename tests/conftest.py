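import numpy as np
import pytest

from mhctyper.qc import make_amplicon
from mhctyper.simulate import SimConfig, generate_pool, generate_population
from mhctyper.targets import DEFAULT_TARGETS

EXONS = sorted(DEFAULT_TARGETS)


@pytest.fixture(scope="session")
def targets():
    return DEFAULT_TARGETS


@pytest.fixture
def amplicon_factory():
    """Build an AmpliconSet for one individual x exon from {seq: count}."""
    def build(counts, individual="ind1", exon="DQAe3"):
        return make_amplicon(individual, exon, counts)
    return build


@pytest.fixture(scope="session")
def small_population():
    """A small ground-truthed population (no reads), shared across tests."""
    config = SimConfig(seed=11, n_founder_haplotypes=4, n_individuals=12,
                       n_triads=8, allele_pool_size=10)
    rng = config.rng()
    pools = {e: generate_pool(config, e, rng, DEFAULT_TARGETS[e])
             for e in EXONS}
    metas, truth, triads = generate_population(config, pools, rng)
    return config, metas, truth, triads
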