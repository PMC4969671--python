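"""Synthetic phased cohorts with controllable homoplasy.

The generator emulates the statistical shape of a phased population variant
panel: diploid individuals, biallelic SNPs with minor allele frequency above
the ingest threshold, a mix of synonymous and nonsynonymous coding sites, and
haplotypes related by a genealogy.  Two features of real data matter for the
downstream homoplasy analysis and can be switched on per gene:

* **recurrent mutation** — the same derived allele arising on independent
  lineages (true homoplasy), realised by assigning a site's derived allele to
  the union of two disjoint clades of the genealogy;
* **planted squares** — explicit four-haplotype motifs {00, 01, 10, 11} at a
  pair of nonsynonymous sites on a shared background, the minimal cycle a
  haplotype network can show.

Haplotypes descend from a random binary branching genealogy (not a
calibrated coalescent): the analysis consumes only haplotype sets, so clade
structure — which the branching process provides — is all that is required.
Under ``mutation_model="tree"`` every site's derived allele marks exactly one
clade, which makes the site patterns a perfect phylogeny, so the resulting
networks are guaranteed acyclic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .genemodel import (
    NONSYNONYMOUS,
    NUCLEOTIDES,
    SYNONYMOUS,
    GeneModel,
    GeneModelError,
    Transcript,
)

MIN_MAF = 0.01  # must match the ingest filter

#: fraction of sites given a two-clade (homoplastic) origin in recurrent mode
RECURRENT_SITE_FRACTION = 0.25


class CohortConfigError(ValueError):
    pass


@dataclass
class GeneSpec:
    name: str
    cds_length_nt: int = 300
    n_transcripts: int = 1
    n_nonsyn_sites: int = 12
    n_syn_sites: int = 6
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted_squares: int = 0
    recomb_events: float = 0.0
    mutation_model: str = "tree"

    def __post_init__(self) -> None:
        if self.cds_length_nt < 3 or self.cds_length_nt % 3:
            raise CohortConfigError(
                f"{self.name}: cds_length_nt must be a positive codon multiple"
            )
        if self.n_transcripts < 1:
            raise CohortConfigError(f"{self.name}: need at least one transcript")
        if self.maf_range[0] < MIN_MAF or not self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise CohortConfigError(
                f"{self.name}: maf_range must lie in [{MIN_MAF}, 0.5]"
            )
        if self.mutation_model not in ("tree", "recurrent"):
            raise CohortConfigError(f"{self.name}: unknown mutation model")
        if self.planted_squares and self.n_nonsyn_sites < 2:
            raise CohortConfigError(f"{self.name}: planting needs >= 2 nonsyn sites")


@dataclass
class CohortSpec:
    n_individuals: int
    genes: list[GeneSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise CohortConfigError("need at least two diploid individuals")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise CohortConfigError("duplicate gene names")


@dataclass
class SiteRecord:
    gene: str
    contig: str
    pos: int  # 0-based on the synthetic contig
    ref: str
    alt: str
    consequence: str


@dataclass
class GeneTruth:
    site_classes: list[str]
    planted_square_states: list[list[str]]  # each: 4 nonsyn-vector strings
    genealogy: dict
    recomb_breakpoints: list[tuple[int, int, int]]  # (hap_a, hap_b, breakpoint)
    recurrent_sites: list[int]


@dataclass
class SimulatedGene:
    spec: GeneSpec
    model: GeneModel
    sites: list[SiteRecord]
    matrix: np.ndarray  # (2N, S) allele codes
    truth: GeneTruth

    @property
    def nonsyn_columns(self) -> np.ndarray:
        classes = np.array([s.consequence for s in self.sites])
        return np.flatnonzero(classes == NONSYNONYMOUS)


@dataclass
class Cohort:
    spec: CohortSpec
    genes: list[SimulatedGene]
    sample_names: list[str] = field(default_factory=list)

    def gene(self, name: str) -> SimulatedGene:
        for g in self.genes:
            if g.spec.name == name:
                return g
        raise KeyError(name)


def make_gene_model(spec: GeneSpec, rng: np.random.Generator) -> GeneModel:
    """Random coding sequence plus ``n_transcripts`` frame-aligned transcripts.

    Transcript 1 spans the whole coding stretch; further transcripts are
    overlapping in-frame sub-intervals, so every transcript agrees on codon
    boundaries and consequence classes are consistent across transcripts.
    """
    length = spec.cds_length_nt
    seq = "".join(rng.choice(list(NUCLEOTIDES), size=length))
    transcripts = [Transcript(name=f"{spec.name}.t1", cds=((0, length),))]
    n_codons = length // 3
    for t in range(1, spec.n_transcripts):
        start_codon = int(rng.integers(0, max(1, n_codons // 2)))
        end_codon = int(rng.integers(start_codon + 1, n_codons + 1))
        transcripts.append(
            Transcript(
                name=f"{spec.name}.t{t + 1}",
                cds=((3 * start_codon, 3 * end_codon),),
            )
        )
    try:
        return GeneModel(
            name=spec.name, contig=spec.name, sequence=seq, transcripts=transcripts
        )
    except GeneModelError as exc:  # pragma: no cover - guarded by GeneSpec
        raise CohortConfigError(str(exc)) from exc


def _candidate_sites(model: GeneModel) -> tuple[list, list]:
    """Per-position (pos, ref, alt) candidates by consequence class.

    Single pass over every transcript's codons; a change nonsynonymous in
    any transcript is nonsynonymous overall.
    """
    from .genemodel import CODON_TABLE

    nonsyn_any: dict[tuple[int, str], bool] = {}
    for tr in model.transcripts:
        pos_list = tr.positions()
        for c0 in range(0, len(pos_list), 3):
            codon_pos = pos_list[c0 : c0 + 3]
            codon = "".join(model.sequence[p] for p in codon_pos)
            aa = CODON_TABLE[codon]
            for frame, pos in enumerate(codon_pos):
                ref = codon[frame]
                for alt in NUCLEOTIDES:
                    if alt == ref:
                        continue
                    alt_aa = CODON_TABLE[codon[:frame] + alt + codon[frame + 1 :]]
                    key = (pos, alt)
                    nonsyn_any[key] = nonsyn_any.get(key, False) or (aa != alt_aa)
    nonsyn, syn = [], []
    for (pos, alt), is_nonsyn in sorted(nonsyn_any.items()):
        entry = (pos, model.sequence[pos], alt)
        (nonsyn if is_nonsyn else syn).append(entry)
    return nonsyn, syn


def _pick_sites(candidates, n, taken: set, rng) -> list:
    """Choose n candidates with pairwise-distinct, untaken positions."""
    chosen = []
    for idx in rng.permutation(len(candidates)):
        pos, ref, alt = candidates[int(idx)]
        if pos in taken:
            continue
        taken.add(pos)
        chosen.append((pos, ref, alt))
        if len(chosen) == n:
            return chosen
    raise CohortConfigError(f"only {len(chosen)} of {n} requested sites available")


def _random_genealogy(n_leaves: int, rng) -> tuple[dict, list[np.ndarray]]:
    """Random binary branching of leaves; returns (nested tree, clade list)."""
    clades: list[np.ndarray] = []

    def split(leaves: np.ndarray) -> dict:
        if leaves.size == 1:
            return {"leaf": int(leaves[0])}
        cut = int(rng.integers(1, leaves.size))
        perm = rng.permutation(leaves)
        left, right = np.sort(perm[:cut]), np.sort(perm[cut:])
        clades.extend([left, right])
        return {"left": split(left), "right": split(right)}

    tree = split(np.arange(n_leaves))
    return tree, clades


def _maf_ok(count: int, n_hap: int, lo: float, hi: float) -> bool:
    freq = count / n_hap
    maf = min(freq, 1.0 - freq)
    return lo <= maf <= hi and 0 < count < n_hap


def plant_square_motif(
    pool: np.ndarray,
    site_pair: tuple[int, int],
    rng,
    protected: set | None = None,
    background_row: int | None = None,
) -> tuple:
    """Ensure the pool holds all four states {00, 01, 10, 11} at ``site_pair``
    on a shared background (equal at every other pooled site).

    By default the most common background is used; ``background_row`` pins
    the background to a specific row instead, which lets several plantings
    share one background so that their squares form a single connected
    cluster.  Rows carrying duplicate states inside the background group,
    then rows outside the group, are overwritten to supply missing states.
    Rows listed in ``protected`` (e.g. quartets of earlier plantings) are
    never overwritten.  Applying the motif when all four states already
    exist is a no-op.  Returns ``(pool, quartet_row_indices)``.
    """
    protected = protected or set()
    i, j = site_pair
    n_rows, n_cols = pool.shape
    if n_rows < 4:
        raise CohortConfigError("pool too small to hold a square motif")
    if i == j or not (0 <= i < n_cols and 0 <= j < n_cols):
        raise CohortConfigError("invalid site pair")
    other = [c for c in range(n_cols) if c not in (i, j)]
    groups: dict[tuple, list[int]] = {}
    for r in range(n_rows):
        groups.setdefault(tuple(int(x) for x in pool[r, other]), []).append(r)
    if background_row is not None:
        background = tuple(int(x) for x in pool[background_row, other])
        rows = groups[background]
    else:
        background, rows = max(groups.items(), key=lambda kv: (len(kv[1]), kv[0]))
    present: dict[tuple, list[int]] = {}
    for r in rows:
        present.setdefault((int(pool[r, i]), int(pool[r, j])), []).append(r)
    needed = [(0, 0), (0, 1), (1, 0), (1, 1)]
    missing = [c for c in needed if c not in present]
    if missing:
        spare = [
            r for combo in present.values() for r in combo[1:] if r not in protected
        ]
        outsiders = [
            r
            for r in range(n_rows)
            if r not in protected
            and tuple(int(x) for x in pool[r, other]) != background
        ]
        writable = spare + [int(r) for r in rng.permutation(outsiders)]
        if len(writable) < len(missing):
            raise CohortConfigError("sites saturated: cannot plant square motif")
        for combo in missing:
            r = writable.pop(0)
            pool[r, other] = background
            pool[r, i], pool[r, j] = combo
            present[combo] = [r]
    quartet = tuple(present[c][0] for c in needed)
    return pool, quartet


def _crossover_rows(matrix: np.ndarray, a: int, b: int, breakpoint: int) -> None:
    tail_a = matrix[a, breakpoint:].copy()
    matrix[a, breakpoint:] = matrix[b, breakpoint:]
    matrix[b, breakpoint:] = tail_a


def _repair_maf(matrix: np.ndarray, protected_rows: set, n_hap: int, rng) -> None:
    """Flip alleles in unprotected rows until every column passes the MAF filter."""
    min_count = max(1, math.ceil(MIN_MAF * n_hap))
    free = [r for r in range(n_hap) if r not in protected_rows]
    for col in range(matrix.shape[1]):
        for _ in range(4 * n_hap):
            ones = int(matrix[:, col].sum())
            minor_allele = 1 if ones <= n_hap - ones else 0
            minor = ones if minor_allele == 1 else n_hap - ones
            if minor >= min_count:
                break
            donors = [r for r in free if matrix[r, col] != minor_allele]
            if not donors:
                raise CohortConfigError("cannot satisfy MAF filter after planting")
            matrix[int(rng.choice(donors)), col] = minor_allele
        else:  # pragma: no cover
            raise CohortConfigError("MAF repair did not converge")


def simulate_gene(spec: GeneSpec, n_individuals: int, rng) -> SimulatedGene:
    n_hap = 2 * n_individuals
    lo, hi = spec.maf_range
    min_count = max(1, math.ceil(lo * n_hap))
    if min_count >= n_hap - min_count + 1 and min_count > n_hap // 2:
        raise CohortConfigError(
            f"{spec.name}: requested MAF unattainable with {n_individuals} individuals"
        )
    model = make_gene_model(spec, rng)
    nonsyn_cand, syn_cand = _candidate_sites(model)
    taken: set[int] = set()
    nonsyn_sites = _pick_sites(nonsyn_cand, spec.n_nonsyn_sites, taken, rng)
    syn_sites = _pick_sites(syn_cand, spec.n_syn_sites, taken, rng)
    site_defs = sorted(
        [(p, r, a, NONSYNONYMOUS) for p, r, a in nonsyn_sites]
        + [(p, r, a, SYNONYMOUS) for p, r, a in syn_sites]
    )
    sites = [
        SiteRecord(gene=spec.name, contig=model.contig, pos=p, ref=r, alt=a, consequence=c)
        for p, r, a, c in site_defs
    ]
    n_sites = len(sites)

    tree, clades = _random_genealogy(n_hap, rng)
    usable = [c for c in clades if _maf_ok(c.size, n_hap, lo, hi)]
    if not usable:
        raise CohortConfigError(
            f"{spec.name}: no genealogy clade satisfies maf_range {spec.maf_range}"
        )
    matrix = np.zeros((n_hap, n_sites), dtype=np.int8)
    recurrent_sites: list[int] = []
    n_recurrent = (
        max(1, round(RECURRENT_SITE_FRACTION * n_sites))
        if spec.mutation_model == "recurrent"
        else 0
    )
    recurrent_cols = set(
        int(c) for c in rng.choice(n_sites, size=min(n_recurrent, n_sites), replace=False)
    ) if n_recurrent else set()
    for col in range(n_sites):
        if col in recurrent_cols:
            carriers = _two_clade_union(usable, n_hap, lo, hi, rng)
            if carriers is None:
                carriers = usable[int(rng.integers(len(usable)))]
            else:
                recurrent_sites.append(col)
        else:
            carriers = usable[int(rng.integers(len(usable)))]
        matrix[carriers, col] = 1

    # planted squares live on nonsynonymous columns only: the cycles of
    # interest are those of the protein-level network
    classes = np.array([s.consequence for s in sites])
    nonsyn_cols = np.flatnonzero(classes == NONSYNONYMOUS)
    planted_states: list[list[str]] = []
    protected: set[int] = set()
    sub = matrix[:, nonsyn_cols]
    if spec.planted_squares:
        from itertools import combinations as _combos

        all_pairs = list(_combos(range(len(nonsyn_cols)), 2))
        if spec.planted_squares > len(all_pairs):
            raise CohortConfigError(
                f"{spec.name}: cannot plant {spec.planted_squares} squares on "
                f"{len(nonsyn_cols)} nonsynonymous sites"
            )
        order = rng.permutation(len(all_pairs))
        # chain the plantings: each square's background is the far corner of
        # the previous square, so the squares form one connected ladder-like
        # cluster (hence lie in the giant) without any high-degree hub node
        patterns: dict[tuple, list[int]] = {}
        for r in range(sub.shape[0]):
            patterns.setdefault(tuple(int(x) for x in sub[r]), []).append(r)
        _, anchor_rows = max(patterns.items(), key=lambda kv: (len(kv[1]), kv[0]))
        anchor = anchor_rows[0]
        protected.add(anchor)
        for p_idx in order[: spec.planted_squares]:
            pair = all_pairs[int(p_idx)]
            sub, quartet = plant_square_motif(
                sub, pair, rng, protected=protected, background_row=anchor
            )
            protected.update(quartet)
            planted_states.append(
                ["".join(str(int(x)) for x in sub[r]) for r in quartet]
            )
            anchor = quartet[-1]  # the (1,1) corner seeds the next square
    matrix[:, nonsyn_cols] = sub

    breakpoints: list[tuple[int, int, int]] = []
    if spec.recomb_events > 0:
        n_events = _allocate(spec.recomb_events, rng)
        for _ in range(n_events):
            a, b = (int(x) for x in rng.choice(n_hap, size=2, replace=False))
            bp = int(rng.integers(1, n_sites)) if n_sites > 1 else 0
            if bp:
                _crossover_rows(matrix, a, b, bp)
                breakpoints.append((a, b, bp))

    _repair_maf(matrix, protected, n_hap, rng)

    truth = GeneTruth(
        site_classes=list(classes),
        planted_square_states=planted_states,
        genealogy=tree,
        recomb_breakpoints=breakpoints,
        recurrent_sites=recurrent_sites,
    )
    return SimulatedGene(spec=spec, model=model, sites=sites, matrix=matrix, truth=truth)


def _allocate(x: float, rng) -> int:
    """Fractional event allocation: floor(x)+1 with probability x-floor(x)."""
    if x < 0:
        raise ValueError("negative expected count")
    k = math.floor(x)
    if x == k:
        return k
    return k + 1 if rng.random() < (x - k) else k


def _two_clade_union(usable, n_hap: int, lo: float, hi: float, rng, attempts: int = 200):
    """Union of two disjoint clades whose combined frequency stays in range."""
    for _ in range(attempts):
        i, j = (int(x) for x in rng.integers(0, len(usable), size=2))
        a, b = usable[i], usable[j]
        if i == j or np.intersect1d(a, b).size:
            continue
        union = np.union1d(a, b)
        if _maf_ok(union.size, n_hap, lo, hi):
            return union
    return None


def tree_gene_spec(name: str, **overrides) -> GeneSpec:
    """A typical gene evolving without homoplasy: a dozen nonsynonymous and a
    handful of synonymous biallelic sites on one tree genealogy."""
    params = dict(
        cds_length_nt=300, n_transcripts=1, n_nonsyn_sites=12, n_syn_sites=6,
        maf_range=(0.05, 0.5), planted_squares=0, recomb_events=0.0,
        mutation_model="tree",
    )
    params.update(overrides)
    return GeneSpec(name=name, **params)


def homoplastic_gene_spec(name: str, **overrides) -> GeneSpec:
    """A gene with strong recurrent evolution: a ladder of a dozen planted
    squares over many nonsynonymous sites, the regime in which real genes
    show a square excess (tens of squares in giants of a few dozen nodes)."""
    params = dict(
        cds_length_nt=1200, n_transcripts=1, n_nonsyn_sites=60, n_syn_sites=10,
        maf_range=(0.05, 0.5), planted_squares=12, recomb_events=0.0,
        mutation_model="recurrent",
    )
    params.update(overrides)
    return GeneSpec(name=name, **params)


def demo_cohort_spec(
    n_genes: int = 50,
    n_homoplastic: int = 5,
    n_individuals: int = 100,
    seed: int = 0,
) -> CohortSpec:
    """The reference study conditions: a cohort of mostly tree-like genes
    with a small minority of strongly homoplastic ones."""
    if not 0 <= n_homoplastic <= n_genes:
        raise CohortConfigError("n_homoplastic must be within n_genes")
    genes = [
        homoplastic_gene_spec(f"HOM{i:03d}") for i in range(n_homoplastic)
    ] + [
        tree_gene_spec(f"TREE{i:03d}") for i in range(n_genes - n_homoplastic)
    ]
    return CohortSpec(n_individuals=n_individuals, genes=genes, seed=seed)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate every gene of the cohort; per-gene RNG streams are derived
    from the cohort seed by fixed spawn keys, so gene g is reproducible
    independently of the others."""
    genes = []
    for g_idx, gene_spec in enumerate(spec.genes):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(g_idx,))
        )
        genes.append(simulate_gene(gene_spec, spec.n_individuals, rng))
    samples = [f"IND{j:04d}" for j in range(spec.n_individuals)]
    return Cohort(spec=spec, genes=genes, sample_names=samples)


# ---------------------------------------------------------------------------
# serialisation


def write_vcf(cohort: Cohort, path) -> None:
    """Write the cohort as one sorted, phased VCF 4.2 text file."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
    ]
    for gene in sorted(cohort.genes, key=lambda g: g.model.contig):
        lines.append(f"##contig=<ID={gene.model.contig},length={len(gene.model.sequence)}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header_cols + cohort.sample_names))

    rows = []
    for gene in cohort.genes:
        for s_idx, site in enumerate(gene.sites):
            col = gene.matrix[:, s_idx]
            gts = [f"{col[2 * j]}|{col[2 * j + 1]}" for j in range(len(cohort.sample_names))]
            rows.append(
                (
                    site.contig,
                    site.pos + 1,
                    [site.contig, str(site.pos + 1), ".", site.ref, site.alt, ".", "PASS", ".", "GT"]
                    + gts,
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    last = None
    for contig, pos, _ in rows:
        if last is not None and (contig, pos) < last:
            raise ValueError("records unsorted")  # pragma: no cover
        last = (contig, pos)
    lines.extend("\t".join(map(str, fields)) for _, _, fields in rows)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_consequence_table(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcontig\tpos\tref\talt\tclass\n")
        for gene in cohort.genes:
            for site in gene.sites:
                fh.write(
                    f"{site.gene}\t{site.contig}\t{site.pos + 1}\t"
                    f"{site.ref}\t{site.alt}\t{site.consequence}\n"
                )


def write_gene_models_gff3(cohort: Cohort, path) -> None:
    """GFF3 with one gene + mRNA/CDS features per transcript (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in cohort.genes:
            model = gene.model
            length = len(model.sequence)
            fh.write(
                f"{model.contig}\thaplocycle\tgene\t1\t{length}\t.\t+\t.\t"
                f"ID={model.name}\n"
            )
            for tr in model.transcripts:
                fh.write(
                    f"{model.contig}\thaplocycle\tmRNA\t{tr.cds[0][0] + 1}\t"
                    f"{tr.cds[-1][1]}\t.\t+\t.\tID={tr.name};Parent={model.name}\n"
                )
                for start, end in tr.cds:
                    fh.write(
                        f"{model.contig}\thaplocycle\tCDS\t{start + 1}\t{end}\t.\t+\t0\t"
                        f"Parent={tr.name}\n"
                    )


def write_ground_truth(cohort: Cohort, path) -> None:
    payload = {
        gene.spec.name: {
            "site_classes": gene.truth.site_classes,
            "planted_square_states": gene.truth.planted_square_states,
            "genealogy": gene.truth.genealogy,
            "recomb_breakpoints": gene.truth.recomb_breakpoints,
            "recurrent_sites": gene.truth.recurrent_sites,
            "mutation_model": gene.spec.mutation_model,
        }
        for gene in cohort.genes
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write VCF, consequence table, gene models and ground truth to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "consequences": out / "consequences.tsv",
        "genes": out / "genes.gff3",
        "truth": out / "truth.json",
    }
    write_vcf(cohort, paths["vcf"])
    write_consequence_table(cohort, paths["consequences"])
    write_gene_models_gff3(cohort, paths["genes"])
    write_ground_truth(cohort, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
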