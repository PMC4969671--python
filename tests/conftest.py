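import numpy as np
import pytest

from haplocycle.genemodel import NONSYNONYMOUS, SYNONYMOUS
from haplocycle.variant_ingest import FilteredVariant, HaplotypeMatrix


def make_matrix(gene, columns, classes, hap_prefix="H"):
    """HaplotypeMatrix from a list of per-site allele columns."""
    matrix = np.array(columns, dtype=np.int8).T
    n_hap = matrix.shape[0]
    sites = [
        FilteredVariant(
            contig=gene, pos=10 * (i + 1), ref="A", alt="T",
            alleles=tuple(int(x) for x in matrix[:, i]),
            consequence=cls, gene=gene,
        )
        for i, cls in enumerate(classes)
    ]
    return HaplotypeMatrix(
        gene=gene, sites=sites, matrix=matrix,
        haplotype_ids=[f"{hap_prefix}{k // 2}_{k % 2 + 1}" for k in range(n_hap)],
        classes=np.array(classes),
    )


@pytest.fixture
def fig1_matrix():
    """The worked four-haplotype example: two nonsynonymous sites (positions
    10 and 20), haplotypes {AA, TA, AG, TG} -> codes {00, 10, 01, 11}."""
    return make_matrix(
        "FIG1",
        columns=[[0, 1, 0, 1], [0, 0, 1, 1]],
        classes=[NONSYNONYMOUS, NONSYNONYMOUS],
    )


@pytest.fixture
def mixed_matrix():
    """Six haplotypes, two nonsynonymous + two synonymous sites."""
    return make_matrix(
        "MIX",
        columns=[
            [0, 1, 0, 1, 0, 1],  # nonsyn
            [0, 0, 1, 1, 0, 0],  # nonsyn
            [0, 1, 1, 0, 0, 1],  # syn
            [0, 0, 0, 1, 1, 1],  # syn
        ],
        classes=[NONSYNONYMOUS, NONSYNONYMOUS, SYNONYMOUS, SYNONYMOUS],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
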