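import numpy as np
import pytest

from termindex import CohortSimParams, GeneSet, SignalTrack, simulate_cohort
from helpers import make_gene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_gene_set():
    """Two plus-strand genes and one minus-strand gene, well separated."""
    return GeneSet(
        [
            make_gene("gA", "chrI", "+", polya=2000),
            make_gene("gB", "chrI", "+", polya=8000),
            make_gene("gC", "chrII", "-", polya=3000),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-gene mixed-strand cohort with half the genes planted defective."""
    params = CohortSimParams(
        n_genes=30, replicates=3, expression=5.0, r_wt=0.01,
        defective_fraction=0.5, defective_fold=8.0, minus_fraction=0.5,
        genes_per_chrom=10, seed=7,
    )
    genes, truth, wt, mut = simulate_cohort(params)
    return params, genes, truth, wt, mut


def uniform_track(genes, density: int, lo_offset=-1500, hi_offset=600,
                  sample_id="u1", strain="WT", replicate=1) -> SignalTrack:
    """Track with a constant integer count per nucleotide across each gene's
    offset range (body plus downstream), on the gene's strand."""
    t = SignalTrack(sample_id=sample_id, strain=strain, replicate=replicate)
    for g in genes:
        a = g.offset_to_genomic(lo_offset)
        b = g.offset_to_genomic(hi_offset)
        t.set_interval(g.chrom, g.strand, max(1, min(a, b)), max(a, b), density)
    return t
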