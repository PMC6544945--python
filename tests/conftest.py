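import numpy as np
import pytest

from helikit import synthetic_data as sd
from helikit.homology_search import index_genome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_bundle():
    """2 x 100 kb genome with 30 planted copies at d = 0.05."""
    cfg = sd.SimConfig(
        seed=1, n_contigs=2, contig_len=100_000, copies_per_element=30, divergence_d=0.05
    )
    genomes, truth = sd.simulate_bundle(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def small_index(small_bundle):
    _, genomes, _ = small_bundle
    return index_genome(genomes)
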