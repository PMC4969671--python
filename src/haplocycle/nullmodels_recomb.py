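"""Recombination null model for square excess.

Squares can also arise when recombination between two lineages recreates a
haplotype, so the mutation-only null is complemented by a one-round diploid
population simulation: start a population (half as many individuals as the
giant component has nodes) fixed for a random homozygous sequence over the
gene's nonsynonymous polymorphic sites, spend a mutation budget equal to the
number of giant-component edges, apply the expected number of within-pair
crossovers, then form offspring by sampling one haplotype per parent (with
replacement, two offspring per random pair) and count the squares of the
network built from the offspring haplotypes.

The expected crossover count per sequence pair is anchored on the observed
synonymous diversity of the gene: the number of generations back to common
ancestry is taken as S / (L * mu * Ne) with S the gene's observed synonymous
site count, L its genomic length (introns included), mu the per-nucleotide
per-generation mutation rate and Ne the effective population size; this
generation count times the genome-average crossover rate times L, divided by
the sample size, gives the per-pair expectation r.  The formula is kept
behind a single function so alternative calibrations can be swapped in.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .cyclecensus import count_squares
from .hapnet import network_from_sequences
from .nullmodels_mutation import NullDistribution, NullModelError, mutate_constrained

#: cM/Mb -> crossovers per bp per generation (1 cM = 1 % crossover probability)
CM_PER_MB_TO_PER_BP = 1e-8

PRESETS = ("baseline", "Ne10x", "rho2x")


@dataclass(frozen=True)
class RecombParams:
    """Parameters of the recombination null for one gene."""

    S: int  # observed synonymous polymorphic site count
    L: int  # gene length in bp, introns included
    mu: float = 1.1e-8  # per-nucleotide per-generation mutation rate
    Ne: float = 10_000.0  # effective population size
    rho_cM_per_Mb: float = 0.952  # genome-average crossover rate
    sample_size: int = 1_092  # haplotype-pair divisor of the study sample

    def __post_init__(self) -> None:
        if self.S < 0 or self.L <= 0:
            raise NullModelError("S must be >= 0 and L positive")
        if min(self.mu, self.Ne, self.rho_cM_per_Mb) <= 0 or self.sample_size <= 0:
            raise NullModelError("rates and sizes must be positive")

    def with_preset(self, preset: str) -> "RecombParams":
        """Sensitivity presets: ten-fold Ne, or doubled recombination rate."""
        if preset == "baseline":
            return self
        if preset == "Ne10x":
            return replace(self, Ne=self.Ne * 10)
        if preset == "rho2x":
            return replace(self, rho_cM_per_Mb=self.rho_cM_per_Mb * 2)
        raise NullModelError(f"unknown preset {preset!r}")


def generations_to_ancestry(S: float, L: float, mu: float, Ne: float) -> float:
    """Generations back to common ancestry implied by synonymous diversity:
    S / (L * mu * Ne)."""
    denom = L * mu * Ne
    if denom == 0:
        raise NullModelError("zero denominator in generations estimate")
    return S / denom


def expected_recomb_per_pair(params: RecombParams) -> float:
    """Expected crossovers per sequence pair over the gene's history."""
    generations = generations_to_ancestry(params.S, params.L, params.mu, params.Ne)
    per_gen = params.rho_cM_per_Mb * CM_PER_MB_TO_PER_BP * params.L
    return per_gen * generations / params.sample_size


def allocate_integer_events(x: float, rng: np.random.Generator) -> int:
    """Integerise a fractional expected event count without bias.

    An integer x is returned as-is; otherwise floor(x)+1 is drawn with
    probability x - floor(x), floor(x) with the complement, so the
    expectation equals x.
    """
    if x < 0:
        raise NullModelError("negative expected event count")
    k = math.floor(x)
    if x == k:
        return k
    return k + 1 if rng.random() < (x - k) else k


def crossover(
    hap_v: tuple, hap_w: tuple, rng: np.random.Generator, breakpoint: int | None = None
) -> tuple[tuple, tuple]:
    """Reciprocal suffix exchange after a uniformly chosen breakpoint.

    The breakpoint is the index of the first exchanged site, drawn from
    1..len-1 so that each product carries material from both parents; the
    same breakpoint applied twice restores the originals.
    """
    if len(hap_v) != len(hap_w):
        raise NullModelError("haplotype length mismatch in crossover")
    n = len(hap_v)
    if n < 2:
        return hap_v, hap_w
    if breakpoint is None:
        breakpoint = int(rng.integers(1, n))
    if not 1 <= breakpoint < n:
        raise NullModelError("breakpoint outside sequence")
    return (
        hap_v[:breakpoint] + hap_w[breakpoint:],
        hap_w[:breakpoint] + hap_v[breakpoint:],
    )


def simulate_recomb_replicate(
    giant: nx.Graph, params: RecombParams, n_sites: int, rng: np.random.Generator
) -> int:
    """One mutation+recombination replicate; returns its square count.

    The mutation budget |E(giant)| is spread uniformly: each haplotype
    receives allocate(M) single-site toggles with M = |E| / n_haplotypes, so
    the expected total equals the edge count.  Crossovers happen after
    mutation, within each individual's pair.
    """
    if giant.number_of_nodes() < 4:
        raise NullModelError("giant component must have >= 4 nodes")
    if n_sites < 1:
        raise NullModelError("need >= 1 nonsynonymous polymorphic site")
    n_edges = giant.number_of_edges()
    pop_size = math.ceil(giant.number_of_nodes() / 2)
    n_haplotypes = 2 * pop_size
    root = tuple(int(x) for x in rng.integers(0, 2, size=n_sites))
    population = [[root, root] for _ in range(pop_size)]

    m_per_hap = n_edges / n_haplotypes
    for ind in population:
        for h in (0, 1):
            for _ in range(allocate_integer_events(m_per_hap, rng)):
                ind[h] = mutate_constrained(ind[h], rng)

    r = expected_recomb_per_pair(params)
    for ind in population:
        for _ in range(allocate_integer_events(r, rng)):
            ind[0], ind[1] = crossover(ind[0], ind[1], rng)

    order = rng.permutation(pop_size)
    offspring_haps: list[tuple] = []
    for i in range(0, pop_size - 1, 2):
        pa, pb = population[int(order[i])], population[int(order[i + 1])]
        for _ in range(2):  # two offspring per pair
            offspring_haps.append(pa[int(rng.integers(2))])
            offspring_haps.append(pb[int(rng.integers(2))])
    if pop_size % 2:  # odd population: last individual pairs with a random other
        pa = population[int(order[-1])]
        pb = population[int(order[int(rng.integers(pop_size - 1))])]
        for _ in range(2):
            offspring_haps.append(pa[int(rng.integers(2))])
            offspring_haps.append(pb[int(rng.integers(2))])

    network = network_from_sequences(offspring_haps)
    return len(count_squares(network))


def recomb_null_test(
    giant: nx.Graph,
    params: RecombParams,
    observed_squares: int,
    n_sites: int,
    n_reps: int = 1000,
    seed: int = 0,
    gene: str = "",
    preset: str = "baseline",
) -> NullDistribution:
    """Empirical square-excess test against the recombination null."""
    if n_reps < 1:
        raise NullModelError("n_reps must be >= 1")
    params = params.with_preset(preset)
    gene_tag = zlib.crc32(f"recomb:{gene}".encode())
    counts = []
    for k in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(gene_tag, k))
        )
        counts.append(simulate_recomb_replicate(giant, params, n_sites, rng))
    return NullDistribution(
        gene=gene, variant=f"recomb-{preset}",
        observed_squares=observed_squares, replicate_counts=counts,
    )


def shared_synonymous_fraction(graph: nx.Graph, matrix) -> dict:
    """Fraction of each edge's synonymous changes seen on some other edge.

    An edge's synonymous changes are the synonymous sites at which at least
    one member-haplotype pair of its endpoints differs.  If such sharing were
    pervasive, the synonymous site count S would overstate the gene's age
    and hence the recombination budget; empirically it is small.  Returns
    per-edge fractions plus their median and mean; edges without synonymous
    changes carry no information and are skipped.
    """
    from .variant_ingest import NONSYN_CODE

    syn_cols = np.flatnonzero(matrix.classes != NONSYN_CODE)
    hap_index = {h: i for i, h in enumerate(matrix.haplotype_ids)}
    syn = matrix.matrix[:, syn_cols]
    per_edge_sites: dict[tuple, frozenset] = {}
    for u, v in graph.edges:
        changed: set[int] = set()
        for hu in graph.nodes[u]["members"]:
            for hv in graph.nodes[v]["members"]:
                diff = np.flatnonzero(syn[hap_index[hu]] != syn[hap_index[hv]])
                changed.update(int(c) for c in diff)
        per_edge_sites[(u, v)] = frozenset(changed)

    fractions: dict[tuple, float] = {}
    for edge, sites in per_edge_sites.items():
        if not sites:
            continue
        others: set[int] = set()
        for other_edge, other_sites in per_edge_sites.items():
            if other_edge != edge:
                others.update(other_sites)
        fractions[edge] = len(sites & others) / len(sites)
    if not fractions:
        return {"fractions": {}, "median": None, "mean": None, "empty": True}
    values = np.array(list(fractions.values()))
    return {
        "fractions": fractions,
        "median": float(np.median(values)),
        "mean": float(values.mean()),
        "empty": False,
    }
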