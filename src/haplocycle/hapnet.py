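"""Haplotype (genotype) network construction and topology summaries.

A haplotype network has one node per distinct sequence observed in the
sample and an edge between nodes that differ at exactly one site.  Two levels
are supported:

* ``dna`` — nodes are distinct haplotypes over all polymorphic sites
  (synonymous and nonsynonymous alike);
* ``protein`` — haplotypes identical at every nonsynonymous site are merged
  into one node, so adjacent nodes differ by a single amino-acid change.

On protein-level networks each edge additionally carries ``mean_syn``: the
average number of synonymous differences over all member-haplotype pairs of
its two endpoints, kept as an exact :class:`fractions.Fraction`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
from scipy import stats

from .variant_ingest import NONSYN_CODE, HaplotypeMatrix

LEVELS = ("dna", "protein")


@dataclass
class NetworkSummary:
    gene: str
    level: str
    n_nodes: int
    n_edges: int
    n_components: int
    giant_size: int
    giant_fraction: float
    degree_histogram: dict[int, int]
    assortativity: float | None


def network_from_sequences(
    sequences, members=None, graph_attrs: dict | None = None
) -> nx.Graph:
    """Build a distance-1 network from a pool of hashable sequences.

    Identical sequences are merged into one node; nodes are consecutive
    integers with attributes ``seq``, ``multiplicity`` and ``members``.
    Adjacency (Hamming distance exactly 1) is found by bucketing each
    sequence once per site with that site masked, which is equivalent to the
    quadratic all-pairs comparison: two sequences share a bucket at site i
    iff they agree everywhere else.
    """
    members_by_seq: dict = {}
    seq_list = list(sequences)
    member_list = list(range(len(seq_list))) if members is None else list(members)
    if len(member_list) != len(seq_list):
        raise ValueError("sequences and members length mismatch")
    for seq, mem in zip(seq_list, member_list):
        members_by_seq.setdefault(seq, []).append(mem)

    graph = nx.Graph(**(graph_attrs or {}))
    node_of: dict = {}
    for i, (seq, mems) in enumerate(members_by_seq.items()):
        node_of[seq] = i
        graph.add_node(i, seq=seq, multiplicity=len(mems), members=tuple(mems))

    if not seq_list:
        return graph
    length = len(seq_list[0])
    buckets: dict = {}
    for seq in members_by_seq:
        if len(seq) != length:
            raise ValueError("ragged sequence pool")
        for i in range(length):
            key = (i, seq[:i], seq[i + 1 :])
            buckets.setdefault(key, []).append(seq)
    for (i, _, _), group in buckets.items():
        if len(group) < 2:
            continue
        for a_idx in range(len(group)):
            for b_idx in range(a_idx + 1, len(group)):
                a, b = group[a_idx], group[b_idx]
                if a[i] != b[i]:
                    graph.add_edge(node_of[a], node_of[b], site=i)
    return graph


def build_network(matrix: HaplotypeMatrix, level: str = "protein") -> nx.Graph:
    """Build the haplotype network for one gene at the given level."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if matrix.n_haplotypes == 0 or matrix.n_sites == 0:
        raise ValueError(f"empty haplotype matrix for gene {matrix.gene}")
    if level == "protein":
        active = np.flatnonzero(matrix.classes == NONSYN_CODE)
        if active.size == 0:
            raise ValueError(
                f"gene {matrix.gene} has no nonsynonymous site; no protein network"
            )
    else:
        active = np.arange(matrix.n_sites)
    seqs = [tuple(row) for row in matrix.matrix[:, active]]
    graph = network_from_sequences(
        seqs,
        members=matrix.haplotype_ids,
        graph_attrs={"gene": matrix.gene, "level": level},
    )
    if level == "protein":
        syn_cols = np.flatnonzero(matrix.classes != NONSYN_CODE)
        hap_index = {h: i for i, h in enumerate(matrix.haplotype_ids)}
        syn = matrix.matrix[:, syn_cols]
        for u, v in graph.edges:
            graph.edges[u, v]["mean_syn"] = _edge_mean_syn(
                graph.nodes[u]["members"], graph.nodes[v]["members"], syn, hap_index
            )
    return graph


def _edge_mean_syn(members_u, members_v, syn_matrix, hap_index) -> Fraction:
    total = 0
    for hu in members_u:
        row_u = syn_matrix[hap_index[hu]]
        for hv in members_v:
            total += int(np.count_nonzero(row_u != syn_matrix[hap_index[hv]]))
    return Fraction(total, len(members_u) * len(members_v))


def edge_mean_synonymous(graph: nx.Graph, u, v, matrix: HaplotypeMatrix) -> Fraction:
    """Average synonymous differences over all member pairs of edge (u, v).

    Symmetric in u and v; exact rational.  When the gene has no synonymous
    site the mean is 0 for every edge (flagged by the caller).
    """
    syn_cols = np.flatnonzero(matrix.classes != NONSYN_CODE)
    hap_index = {h: i for i, h in enumerate(matrix.haplotype_ids)}
    return _edge_mean_syn(
        graph.nodes[u]["members"], graph.nodes[v]["members"],
        matrix.matrix[:, syn_cols], hap_index,
    )


def components(graph: nx.Graph) -> list[set]:
    """Connected components as node sets, largest (then lexicographic) first."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), sorted(map(repr, c))))
    return comps


def giant(graph: nx.Graph) -> nx.Graph:
    """The giant (largest) component; ties broken by smallest node-id set."""
    return graph.subgraph(components(graph)[0]).copy()


def assortativity(graph: nx.Graph) -> float | None:
    """Degree assortativity: Pearson correlation of degrees across edges.

    Every edge contributes both orientations.  Returns None (flagged
    undefined) when all degrees are equal, where the correlation has zero
    variance.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("assortativity needs at least one edge")
    deg = dict(graph.degree)
    xs, ys = [], []
    for u, v in graph.edges:
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.ptp(xs) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def summarize(graph: nx.Graph) -> NetworkSummary:
    comps = components(graph)
    degrees = [d for _, d in graph.degree]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return NetworkSummary(
        gene=graph.graph.get("gene", ""),
        level=graph.graph.get("level", ""),
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_components=len(comps),
        giant_size=len(comps[0]),
        giant_fraction=len(comps[0]) / graph.number_of_nodes(),
        degree_histogram=hist,
        assortativity=assortativity(graph) if graph.number_of_edges() else None,
    )


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact for small tie-free samples, else
    tie-corrected normal approximation with continuity correction."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_giant_fractions(dna_summaries, protein_summaries) -> dict:
    """Mann–Whitney U comparison of giant-component fractions (protein vs DNA).

    In protein-level networks synonymous variation is collapsed away, so
    their giant components typically cover a larger fraction of nodes.
    """
    dna = [s.giant_fraction for s in dna_summaries]
    prot = [s.giant_fraction for s in protein_summaries]
    u, p = mann_whitney(prot, dna)
    return {
        "U": u,
        "p": p,
        "mean_dna": float(np.mean(dna)),
        "mean_protein": float(np.mean(prot)),
    }


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export; tuple/Fraction attributes stringified for portability."""
    g = graph.copy()
    for _, data in g.nodes(data=True):
        data["seq"] = "".join(map(str, data.get("seq", ())))
        data["members"] = ",".join(map(str, data.get("members", ())))
    for _, _, data in g.edges(data=True):
        if "mean_syn" in data:
            data["mean_syn"] = float(data["mean_syn"])
    nx.write_graphml(g, path)


def write_edgelist(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_u\tnode_v\tsite\tmean_syn\n")
        for u, v, data in graph.edges(data=True):
            ms = data.get("mean_syn", "")
            fh.write(f"{u}\t{v}\t{data.get('site', '')}\t{ms}\n")
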