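import numpy as np
import pytest

from syntelink.genome_io import GeneModel, GenomeAnnotation
from syntelink.homology import FamilyAssignment


def make_genome(species="toy", chrom_sizes=(10,), spacing=1000, gene_len=500):
    """Regularly spaced toy genome: gene ids '<chrom>_g<rank>'."""
    genes = {}
    for ci, n in enumerate(chrom_sizes):
        chrom = f"chr{ci + 1:02d}"
        genes[chrom] = [
            GeneModel(f"{chrom}_g{i}", chrom, 1 + i * spacing,
                      i * spacing + gene_len, "+", i)
            for i in range(n)
        ]
    return GenomeAnnotation(species, genes)


def make_assignment(genome, gene_id, family, **overrides):
    lookup = gene_id if gene_id in genome else overrides.get("merged_from", (gene_id,))[0]
    g = genome.gene(lookup)
    kwargs = dict(
        gene_id=gene_id, family=family, seed_id=f"seed_{family}", c_score=1.0,
        chromosome=g.chromosome, rank=g.rank, rank_max=g.rank,
        start=g.start, end=g.end,
    )
    kwargs.update(overrides)
    return FamilyAssignment(**kwargs)


@pytest.fixture
def toy_genome():
    return make_genome(chrom_sizes=(20, 15))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """Small shared clade simulation reused by several test modules."""
    from syntelink.simgenome import easy_clade_config, simulate

    return simulate(easy_clade_config(seed=7, n_genes=120, n_chromosomes=3))
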