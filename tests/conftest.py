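import numpy as np
import pytest

from skyscan import m4_paper, simulate_genome
from skyscan.io import make_annotation


@pytest.fixture(scope="session")
def m4():
    return m4_paper()


@pytest.fixture(scope="session")
def small_genome(m4):
    """20 windows of 50 kb under the study M4 scenario (8+8 haplotypes)."""
    return simulate_genome(m4, 8, 8, 20, 50_000, seed=1234)


@pytest.fixture(scope="session")
def gene_set(small_genome):
    windows = [(b.contig, b.start, b.end) for b in small_genome]
    return make_annotation(300, 0.2, windows, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
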