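import numpy as np
import pytest

from repliorg.genome_model import CircularGenome, GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_genome():
    return CircularGenome(100, (0, 40))


def make_gene(gene_id, start, end, strand="+", categories=("protein_coding",),
              expression=None, cog_id=None):
    return GeneRecord(gene_id, start, end, strand, frozenset(categories),
                      expression, cog_id)


def random_genes(n=40, length=10_000, seed=0):
    """Sorted, non-overlapping genes on a circle, mixed strands."""
    r = np.random.default_rng(seed)
    cuts = np.sort(r.choice(np.arange(length), size=2 * n, replace=False))
    genes = []
    for i in range(n):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if e == s:
            continue
        genes.append(make_gene(
            f"g{i}", s, e,
            strand="+" if r.random() < 0.5 else "-",
            expression=float(r.normal()),
        ))
    return genes
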