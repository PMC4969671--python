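"""End-to-end conveniences tying the pipeline stages together.

These helpers cover the two common entry paths — a phased VCF plus
annotation on disk, or an in-memory synthetic cohort — and run the
network / census / null-model chain per gene.
"""

from __future__ import annotations

import numpy as np

from . import cyclecensus, hapnet, nullmodels_mutation
from .synthetic_cohort import Cohort, SimulatedGene
from .variant_ingest import (
    FilteredVariant,
    FilterSummary,
    HaplotypeMatrix,
    annotate_variants,
    build_haplotypes,
    filter_vcf,
    read_consequence_table,
)


def matrix_from_simulated_gene(cohort: Cohort, gene: SimulatedGene) -> HaplotypeMatrix:
    """Direct in-memory conversion of a simulated gene, bypassing VCF I/O.

    Produces the same matrix the write->ingest round trip would.
    """
    variants = [
        FilteredVariant(
            contig=site.contig, pos=site.pos + 1, ref=site.ref, alt=site.alt,
            alleles=tuple(int(x) for x in gene.matrix[:, i]),
            consequence=site.consequence, gene=site.gene,
        )
        for i, site in enumerate(gene.sites)
    ]
    return build_haplotypes(variants, cohort.sample_names)


def cohort_matrices(cohort: Cohort) -> dict[str, HaplotypeMatrix]:
    return {g.spec.name: matrix_from_simulated_gene(cohort, g) for g in cohort.genes}


def ingest_files(vcf_path, annotation_path, maf_threshold: float = 0.01):
    """Filter a VCF, annotate, and build one haplotype matrix per gene.

    Returns ``(matrices, filter_summary)``; genes whose annotated variants
    include no site at all are absent from the result.
    """
    summary = FilterSummary()
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
    variants = list(filter_vcf(vcf_path, maf_threshold=maf_threshold, summary=summary))
    annotation = read_consequence_table(annotation_path)
    annotated = annotate_variants(variants, annotation)
    matrices = {}
    for gene in sorted({v.gene for v in annotated}):
        gene_vars = [v for v in annotated if v.gene == gene]
        matrices[gene] = build_haplotypes(gene_vars, samples)
    return matrices, summary


def gene_square_census(matrix: HaplotypeMatrix, level: str = "protein"):
    """Build the network, take its giant component, and count its cycles."""
    network = hapnet.build_network(matrix, level=level)
    giant = hapnet.giant(network)
    census = cyclecensus.census(giant, max_len=8)
    return network, giant, census


def excess_square_scan(
    matrices: dict[str, HaplotypeMatrix],
    variant: str = "constrained",
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    gene_models: dict | None = None,
):
    """Square-excess test for every gene with a usable giant component.

    Genes whose protein-level giant component has fewer than 4 nodes cannot
    contain a square and are reported with observed 0 and p 1 without
    simulation.  Returns ``(distributions, called_genes)``.
    """
    distributions = []
    for gene, matrix in matrices.items():
        network = hapnet.build_network(matrix, level="protein")
        giant = hapnet.giant(network)
        observed = len(cyclecensus.count_squares(giant))
        if giant.number_of_nodes() < 4:
            distributions.append(
                nullmodels_mutation.NullDistribution(
                    gene=gene, variant=variant, observed_squares=observed,
                    replicate_counts=[0] * n_reps,
                )
            )
            continue
        n_sites = int(np.count_nonzero(matrix.classes == "nonsynonymous"))
        distributions.append(
            nullmodels_mutation.null_distribution(
                giant, variant, observed,
                n_reps=n_reps, seed=seed, gene=gene,
                gene_model=(gene_models or {}).get(gene),
                n_sites=n_sites,
            )
        )
    called = nullmodels_mutation.call_excess_genes(distributions, alpha=alpha)
    return distributions, called
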