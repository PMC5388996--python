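import numpy as np
import pytest

from nbscensus import classify, synthetic_data
from nbscensus.models import DomainClass, DomainHit, GeneModel


def make_gene(gene_id, seq_id="Chr01", start=1, end=1000, species="sp", **kw):
    return GeneModel(gene_id=gene_id, species=species, seq_id=seq_id, start=start, end=end, **kw)


def make_hit(gene_id, dclass, p_start, p_end, score=50.0):
    return DomainHit(gene_id, DomainClass[dclass], p_start, p_end, score)


@pytest.fixture(scope="session")
def small_genome():
    """A 30-gene arboreum-like synthetic diploid (fixed seed)."""
    cfg = synthetic_data.preset("arboreum-like", n_genes=30, n_chromosomes=4, seed=7)
    return synthetic_data.generate_diploid(cfg)


@pytest.fixture(scope="session")
def small_records(small_genome):
    return classify.build_records(small_genome.hits, small_genome.genes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
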