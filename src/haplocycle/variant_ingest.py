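"""Ingest phased population VCFs into per-gene haplotype matrices.

Filtering reproduces the standard preparation of phased cohort data for
haplotype-network analysis: drop records whose FILTER is not PASS, indels,
multiallelic records, unphased or incomplete genotypes, and sites with minor
allele frequency below a threshold (default 0.01, computed over the 2N
haplotypes).  Every retained record is a biallelic SNP with complete phased
genotypes, so each individual contributes exactly two haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genemodel import NONSYNONYMOUS, OTHER, SYNONYMOUS, GeneModel

NONSYN_CODE = NONSYNONYMOUS
CONSEQUENCE_CLASSES = (SYNONYMOUS, NONSYNONYMOUS)


class IngestError(ValueError):
    pass


@dataclass(frozen=True)
class FilteredVariant:
    """One biallelic phased PASS SNP surviving all filters."""

    contig: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    alleles: tuple  # per-haplotype codes in {0,1}; 0 is always REF
    consequence: str | None = None
    gene: str | None = None

    @property
    def maf(self) -> float:
        freq = sum(self.alleles) / len(self.alleles)
        return min(freq, 1.0 - freq)


@dataclass
class FilterSummary:
    """Tally of why records were dropped; retained count for bookkeeping."""

    retained: int = 0
    dropped: dict[str, int] = field(
        default_factory=lambda: {
            "filter_not_pass": 0,
            "indel": 0,
            "multiallelic": 0,
            "unphased": 0,
            "missing_genotype": 0,
            "low_maf": 0,
            "monomorphic": 0,
        }
    )

    def drop(self, reason: str) -> None:
        self.dropped[reason] += 1


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes x polymorphic sites for one gene.

    Row ``2j`` / ``2j+1`` hold the first / second haplotype of individual
    ``j``; entries are allele codes in {0, 1} with 0 = REF.
    """

    gene: str
    sites: list[FilteredVariant]
    matrix: np.ndarray  # shape (2N, S), dtype int8
    haplotype_ids: list[str]
    classes: np.ndarray  # per-site consequence class strings

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        if self.matrix.shape != (len(self.haplotype_ids), len(self.sites)):
            raise IngestError("matrix shape inconsistent with labels")
        if not np.isin(self.matrix, (0, 1)).all():
            raise IngestError("allele codes must be 0/1")
        col_sums = self.matrix.sum(axis=0)
        if ((col_sums == 0) | (col_sums == self.n_haplotypes)).any():
            raise IngestError("monomorphic column in haplotype matrix")


def filter_vcf(path, maf_threshold: float = 0.01, summary: FilterSummary | None = None):
    """Yield :class:`FilteredVariant` for records passing all filters.

    A record with no GT field at all is a malformed input and raises;
    unphased or incomplete genotypes merely drop the record, counted in
    ``summary``.  Filtering is idempotent: re-filtering retained records
    changes nothing.
    """
    if summary is None:
        summary = FilterSummary()
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if "GT" not in rec.format:
                raise IngestError(f"record {rec.contig}:{rec.pos} has no GT field")
            if "PASS" not in rec.filter:
                summary.drop("filter_not_pass")
                continue
            if rec.alts is None or len(rec.alts) != 1:
                summary.drop("multiallelic")
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                summary.drop("indel")
                continue
            codes: list[int] = []
            state = "ok"
            for sample in samples:
                call = rec.samples[sample]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    state = "missing_genotype"
                    break
                if len(gt) == 2 and not call.phased:
                    state = "unphased"
                    break
                codes.extend(int(a) for a in gt)
            if state != "ok":
                summary.drop(state)
                continue
            freq = sum(codes) / len(codes)
            if min(freq, 1 - freq) < maf_threshold:
                reason = "monomorphic" if freq in (0.0, 1.0) else "low_maf"
                summary.drop(reason)
                continue
            summary.retained += 1
            yield FilteredVariant(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                alleles=tuple(codes),
            )


def read_consequence_table(path) -> pd.DataFrame:
    """Read the (gene, contig, pos, ref, alt, class) annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"gene", "contig", "pos", "ref", "alt", "class"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"consequence table lacks columns: {sorted(missing)}")
    bad = set(df["class"]) - set(CONSEQUENCE_CLASSES)
    if bad:
        raise IngestError(f"unknown consequence class labels: {sorted(bad)}")
    return df


def annotate_variants(variants, annotation: pd.DataFrame) -> list[FilteredVariant]:
    """Attach gene id and consequence class from the annotation table.

    Unannotated sites (outside any gene's CDS) are skipped; a position with
    conflicting duplicate annotations is a contract violation.
    """
    key_cols = ["contig", "pos", "ref", "alt"]
    dup = annotation.duplicated(subset=key_cols, keep=False)
    if dup.any():
        conflicting = annotation[dup].drop_duplicates(subset=key_cols + ["class", "gene"])
        if conflicting.duplicated(subset=key_cols, keep=False).any():
            raise IngestError("conflicting consequence classes for one variant")
    lookup = {
        (r.contig, int(r.pos), r.ref, r.alt): (r.gene, r["class"])
        for _, r in annotation.iterrows()
    }
    out = []
    for var in variants:
        hit = lookup.get((var.contig, var.pos, var.ref, var.alt))
        if hit is None:
            continue
        gene, cls = hit
        out.append(
            FilteredVariant(
                contig=var.contig, pos=var.pos, ref=var.ref, alt=var.alt,
                alleles=var.alleles, consequence=cls, gene=gene,
            )
        )
    return out


def split_by_consequence(variants, gene: str):
    """Partition one gene's variants into (nonsyn, syn, both), order kept."""
    nonsyn, syn = [], []
    seen: dict[tuple, str] = {}
    for var in variants:
        if var.gene != gene:
            continue
        key = (var.contig, var.pos)
        if key in seen and seen[key] != var.consequence:
            raise IngestError(f"conflicting classes at {key} in gene {gene}")
        seen[key] = var.consequence
        if var.consequence == NONSYNONYMOUS:
            nonsyn.append(var)
        elif var.consequence == SYNONYMOUS:
            syn.append(var)
        else:
            raise IngestError(f"unknown class {var.consequence!r} at {key}")
    both = sorted(nonsyn + syn, key=lambda v: (v.contig, v.pos))
    return nonsyn, syn, both


def build_haplotypes(variants, samples) -> HaplotypeMatrix:
    """Assemble the 2N x S haplotype matrix for one gene's variants."""
    variants = list(variants)
    if not variants:
        raise IngestError("no variants to build haplotypes from")
    genes = {v.gene for v in variants}
    if len(genes) != 1:
        raise IngestError(f"variants span multiple genes: {sorted(map(str, genes))}")
    n_hap = len(variants[0].alleles)
    if n_hap != 2 * len(samples):
        raise IngestError("allele vector length does not match 2 x samples")
    for var in variants:
        if len(var.alleles) != n_hap:
            raise IngestError(f"ragged GT at {var.contig}:{var.pos}")
    matrix = np.array([v.alleles for v in variants], dtype=np.int8).T
    hap_ids = [f"{s}_{i}" for s in samples for i in (1, 2)]
    hm = HaplotypeMatrix(
        gene=genes.pop(),
        sites=variants,
        matrix=matrix,
        haplotype_ids=hap_ids,
        classes=np.array([v.consequence for v in variants]),
    )
    hm.validate()
    return hm


def classify_consequence(gene_model: GeneModel, pos: int, ref: str, alt: str) -> str:
    """Consequence of a substitution given a gene model (0-based ``pos``).

    Nonsynonymous in any transcript wins; outside all CDS -> ``other``
    (excluded from network building).
    """
    return gene_model.classify(pos, ref, alt)


def write_matrix_tsv(hm: HaplotypeMatrix, path) -> None:
    site_ids = [f"{v.contig}:{v.pos}" for v in hm.sites]
    df = pd.DataFrame(hm.matrix, index=hm.haplotype_ids, columns=site_ids)
    df.index.name = "haplotype"
    df.to_csv(path, sep="\t")


def diploid_genotypes(hm: HaplotypeMatrix) -> np.ndarray:
    """Per-individual allele sums (0/1/2) at every site, shape (N, S)."""
    return hm.matrix[0::2].astype(np.int16) + hm.matrix[1::2].astype(np.int16)


__all__ = [
    "FilteredVariant", "FilterSummary", "HaplotypeMatrix", "IngestError",
    "filter_vcf", "read_consequence_table", "annotate_variants",
    "split_by_consequence", "build_haplotypes", "classify_consequence",
    "write_matrix_tsv", "diploid_genotypes", "NONSYN_CODE",
]
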