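import numpy as np
import pytest
from hypothesis import settings

from nascentkit.genome import GeneModel, derive_regions

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def plus_gene():
    """The two-exon reference gene used across region examples."""
    return GeneModel(
        gene_id="gplus",
        chrom="chr1",
        strand="+",
        tx_start=1000,
        tx_end=1500,
        exons=((1000, 1100), (1400, 1500)),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gminus",
        chrom="chr1",
        strand="-",
        tx_start=1000,
        tx_end=1500,
        exons=((1000, 1100), (1400, 1500)),
    )


@pytest.fixture
def three_gene_index():
    """Three well-separated genes on one contig plus the lookup index."""
    from nascentkit.classify import GeneIndex

    contig = {"chr1": 400_000}
    genes = [
        GeneModel("gA", "chr1", "+", 30_000, 33_000,
                  ((30_000, 30_500), (31_000, 31_600), (32_500, 33_000))),
        GeneModel("gB", "chr1", "-", 120_000, 124_000,
                  ((120_000, 120_800), (122_000, 124_000))),
        GeneModel("gC", "chr1", "+", 250_000, 250_900, ((250_000, 250_900),)),
    ]
    regions = [derive_regions(g, contig) for g in genes]
    return GeneIndex(regions), contig
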