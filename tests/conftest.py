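import numpy as np
import pytest

from invkit.gene_model import GeneAnnotation, GeneModel
from invkit.model import Callset, InversionCall
from invkit.simulate import builtin_profile, make_callset, make_genes, make_genome


def make_call(chrom, start, end, *, id=None, dataset="test", af=None, n_homalt=None):
    return InversionCall(
        id=id or f"{dataset}_{chrom}_{start}_{end}",
        chrom=chrom,
        start=start,
        end=end,
        dataset=dataset,
        allele_frequency=af,
        n_homalt=n_homalt,
    )


def make_callset_from(coords, dataset="test", **kw):
    calls = sorted(
        (make_call(c, s, e, dataset=dataset, **kw) for c, s, e in coords),
        key=InversionCall.sort_key,
    )
    return Callset(dataset=dataset, calls=calls)


@pytest.fixture
def two_exon_gene():
    # exons [100,200) and [300,400); one intron [200,300)
    return GeneModel(
        gene_id="G1",
        symbol="GENE1",
        chrom="chr1",
        start=100,
        end=400,
        strand="+",
        exons=((100, 200), (300, 400)),
    )


@pytest.fixture
def synthetic_world():
    """Toy genome + 150 genes + annotations + a planted callset with truth."""
    genome = make_genome(n_chroms=3, chrom_length=20_000_000, seed=7)
    genes, annotations = make_genes(genome, 150, seed=8)
    profile = builtin_profile("gnomad", n_calls=200)
    planted = {
        "gene_spanning": 15,
        "gene_disrupting": 15,
        "intragenic_single_intron": 15,
        "intragenic_multi": 8,
        "intergenic": 10,
    }
    callset, truth = make_callset(profile, genes, planted=planted, seed=9, genome=genome)
    return genome, genes, annotations, callset, truth


def random_regions(rng, n, n_chroms=2, span=10_000, max_len=400):
    out = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(make_call(chrom, start, start + length, id=f"r{i}"))
    return out
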