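"""Mutation-only null models for square excess in haplotype networks.

The null asks: how many squares would a network with the same amount of
evolutionary change show if every change were an independent random
mutation?  A replicate regrows the observed giant component: a random node
is given a random starting sequence, and a traversal of the observed graph
spends exactly one mutation per original edge — when a node is processed,
each of its still-unprocessed incident edges generates one mutant of the
node's assigned sequence, credited to the neighbour.  A neighbour reached a
second time does not change its assigned sequence; the extra mutant simply
joins the sequence pool.  The pool (root + one sequence per edge) is merged
by identity and rebuilt into a distance-1 network whose squares are counted.

Two starting-sequence variants bracket the biological constraints:

* ``fulllength`` — a uniform-random nucleotide sequence over the gene's
  coding stretch; each mutation picks a random transcript and a random site
  inside it and rejects candidate changes until one is nonsynonymous in that
  transcript.
* ``constrained`` — a binary vector with one position per observed
  nonsynonymous polymorphic site; a mutation toggles one position between
  its two allowed states.  This respects the biallelic, few-sites structure
  of the data and is the conservative null (it produces far more chance
  squares, hence far fewer significant genes).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .cyclecensus import count_squares
from .genemodel import CODON_TABLE, NUCLEOTIDES, GeneModel
from .hapnet import network_from_sequences

VARIANTS = ("fulllength", "constrained")

_MUTATION_CAP = 100_000


class NullModelError(ValueError):
    pass


@dataclass
class NullDistribution:
    gene: str
    variant: str
    observed_squares: int
    replicate_counts: list[int]
    p_empirical: float = field(init=False)
    q_bh: float | None = None

    def __post_init__(self) -> None:
        if not self.replicate_counts:
            raise NullModelError("no replicates")
        self.p_empirical = empirical_pvalue(self.observed_squares, self.replicate_counts)

    @property
    def n_reps(self) -> int:
        return len(self.replicate_counts)


def mutate_constrained(seq: tuple, rng: np.random.Generator) -> tuple:
    """Toggle one uniformly chosen site of a binary site-vector."""
    if not seq:
        raise NullModelError("empty constrained sequence")
    i = int(rng.integers(len(seq)))
    return seq[:i] + (1 - seq[i],) + seq[i + 1 :]


def random_constrained_root(n_sites: int, rng: np.random.Generator) -> tuple:
    if n_sites < 1:
        raise NullModelError("constrained model needs >= 1 nonsynonymous site")
    return tuple(int(x) for x in rng.integers(0, 2, size=n_sites))


def random_fulllength_root(gene_model: GeneModel, rng: np.random.Generator) -> str:
    """Uniform-random nucleotides over the gene's coding stretch.

    The sequence is represented over the coding positions only (the union of
    all transcripts' CDS coverage), as a string indexed by coding position.
    """
    positions = gene_model.coding_positions
    return "".join(str(x) for x in rng.choice(list(NUCLEOTIDES), size=len(positions)))


class FullLengthMutator:
    """Random nonsynonymous single-nucleotide mutator for one gene model.

    Caches the coding-position index and each transcript's spliced layout so
    repeated mutation calls inside a replicate stay cheap.
    """

    def __init__(self, gene_model: GeneModel):
        self.model = gene_model
        positions = gene_model.coding_positions
        self.pos_index = {p: i for i, p in enumerate(positions)}
        self.transcripts = []
        for tr in gene_model.transcripts:
            spliced = tr.positions()
            self.transcripts.append(
                (spliced, {p: k for k, p in enumerate(spliced)})
            )

    def __call__(self, seq: str, rng: np.random.Generator) -> str:
        """One random nonsynonymous change in a random transcript.

        Rejection-samples (site, new base) until the change is nonsynonymous
        in the chosen transcript; bounded to guard degenerate models.
        """
        for _ in range(_MUTATION_CAP):
            spliced, spliced_index = self.transcripts[
                int(rng.integers(len(self.transcripts)))
            ]
            pos = spliced[int(rng.integers(len(spliced)))]
            i = self.pos_index[pos]
            ref = seq[i]
            alt = NUCLEOTIDES[int(rng.integers(4))]
            if alt == ref:
                continue
            idx = spliced_index[pos]
            frame = idx % 3
            codon_start = idx - frame
            codon = "".join(
                seq[self.pos_index[p]] for p in spliced[codon_start : codon_start + 3]
            )
            alt_codon = codon[:frame] + alt + codon[frame + 1 :]
            if CODON_TABLE[codon] != CODON_TABLE[alt_codon]:
                return seq[:i] + alt + seq[i + 1 :]
        raise NullModelError("no nonsynonymous change found within retry cap")


def mutate_nonsynonymous_fulllength(
    seq: str, gene_model: GeneModel, rng: np.random.Generator
) -> str:
    """Functional form of :class:`FullLengthMutator` for one-off calls."""
    return FullLengthMutator(gene_model)(seq, rng)


def propagate_degrees(
    giant: nx.Graph,
    root_seq: tuple,
    mutator,
    rng: np.random.Generator,
    per_node_degree: bool = False,
) -> list[tuple]:
    """Regrow the giant component, one mutation per original edge.

    Breadth-first from a random node; processing a node generates one mutant
    per incident unprocessed edge and attributes it to the neighbour (first
    arrival fixes the neighbour's own sequence).  With
    ``per_node_degree=True`` every node instead mutates once per incident
    edge regardless of processing state (2|E| events), the stricter literal
    per-degree reading, kept for sensitivity analysis.

    Returns the sequence pool: root plus one sequence per mutation event.
    """
    if giant.number_of_nodes() == 0:
        raise NullModelError("empty giant component")
    if not nx.is_connected(giant):
        raise NullModelError("degree propagation requires a connected component")
    nodes = sorted(giant.nodes, key=repr)
    start = nodes[int(rng.integers(len(nodes)))]
    assigned: dict = {start: root_seq}
    pool = [root_seq]
    processed_edges: set[frozenset] = set()
    queue = [start]
    head = 0
    while head < len(queue):
        node = queue[head]
        head += 1
        for nb in sorted(giant.neighbors(node), key=repr):
            edge = frozenset((node, nb))
            if not per_node_degree and edge in processed_edges:
                continue
            processed_edges.add(edge)
            mutant = mutator(assigned[node], rng)
            pool.append(mutant)
            if nb not in assigned:
                assigned[nb] = mutant
                queue.append(nb)
    expected = (
        2 * giant.number_of_edges() if per_node_degree else giant.number_of_edges()
    )
    if len(pool) != 1 + expected:  # pragma: no cover - internal consistency
        raise NullModelError("mutation event count does not match edge count")
    return pool


def replicate_square_count(
    giant: nx.Graph,
    variant: str,
    rng: np.random.Generator,
    gene_model: GeneModel | None = None,
    n_sites: int | None = None,
    per_node_degree: bool = False,
) -> int:
    """One null replicate: regrow, merge, rebuild, count squares."""
    if variant == "fulllength":
        if gene_model is None:
            raise NullModelError("fulllength variant needs a gene model")
        root = random_fulllength_root(gene_model, rng)
        mutator = FullLengthMutator(gene_model)
    elif variant == "constrained":
        if n_sites is None:
            raise NullModelError("constrained variant needs the nonsyn site count")
        root = random_constrained_root(n_sites, rng)
        mutator = mutate_constrained
    else:
        raise NullModelError(f"unknown variant {variant!r}")
    pool = propagate_degrees(giant, root, mutator, rng, per_node_degree=per_node_degree)
    network = network_from_sequences(pool)
    return len(count_squares(network))


def null_distribution(
    giant: nx.Graph,
    variant: str,
    observed_squares: int,
    n_reps: int = 1000,
    seed: int = 0,
    gene: str = "",
    gene_model: GeneModel | None = None,
    n_sites: int | None = None,
    per_node_degree: bool = False,
) -> NullDistribution:
    """Replicate square-count distribution and empirical p for one gene.

    Replicates use counter-based seeding: replicate k draws from a stream
    spawned as (seed, gene-tag, k), so results are independent of execution
    order and reproducible per replicate.
    """
    if n_reps < 1:
        raise NullModelError("n_reps must be >= 1")
    if giant.number_of_nodes() < 4:
        raise NullModelError("giant component must have >= 4 nodes")
    gene_tag = zlib.crc32(gene.encode()) if gene else 0
    counts = []
    for k in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(gene_tag, k))
        )
        counts.append(
            replicate_square_count(
                giant, variant, rng,
                gene_model=gene_model, n_sites=n_sites,
                per_node_degree=per_node_degree,
            )
        )
    return NullDistribution(
        gene=gene, variant=variant,
        observed_squares=observed_squares, replicate_counts=counts,
    )


def empirical_pvalue(observed: int, replicate_counts) -> float:
    """Empirical upper-tail p with the 1/n floor.

    A network with more squares than every replicate gets p = 1/n_reps (the
    smallest resolvable value), not 0.
    """
    counts = list(replicate_counts)
    if not counts:
        raise NullModelError("no replicates")
    ge = sum(1 for c in counts if c >= observed)
    return max(ge, 1) / len(counts)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise NullModelError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_excess_genes(distributions: list[NullDistribution], alpha: float = 0.05) -> list[str]:
    """Genes with BH-adjusted q <= alpha among genes showing >= 1 square.

    Genes without any square cannot show an excess and are excluded from the
    FDR universe.  Mixed replicate counts would make p floors incomparable
    and are rejected.
    """
    if not distributions:
        return []
    n_reps = {d.n_reps for d in distributions}
    if len(n_reps) != 1:
        raise NullModelError("mixed n_reps across genes")
    eligible = [d for d in distributions if d.observed_squares >= 1]
    if not eligible:
        return []
    qvals = bh_fdr([d.p_empirical for d in eligible])
    called = []
    for dist, q in zip(eligible, qvals):
        dist.q_bh = float(q)
        if q <= alpha:
            called.append(dist.gene)
    return called
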