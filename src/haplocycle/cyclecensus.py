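"""Elementary-cycle census of haplotype networks.

In a network built from biallelic sites every edge toggles exactly one site,
so a closed path must toggle each site an even number of times: the graph is
bipartite and the shortest possible cycle is a square (4-cycle).  Squares are
the signature of homoplasy — two lineages acquiring the same change
independently — and this module enumerates them, together with elementary
hexagons and octagons, exactly.

A cycle is *elementary* when it is not decomposable into shorter cycles.  We
operationalize this as chordlessness: the subgraph induced by the cycle's
nodes contains exactly the cycle's own edges.  Any extra induced edge is a
chord and splits the cycle into two shorter ones; conversely a chordless
cycle of length L induces a graph where every node has degree 2, which is a
single L-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

SUPPORTED_LENGTHS = (4, 6, 8)


@dataclass
class CycleCensus:
    """Elementary cycles of length 4/6/8 found in one network."""

    squares: set[frozenset] = field(default_factory=set)
    #: canonical node sequences (rotation+reflection normalised)
    hexagons: set[tuple] = field(default_factory=set)
    octagons: set[tuple] = field(default_factory=set)

    @property
    def n_squares(self) -> int:
        return len(self.squares)

    @property
    def n_hexagons(self) -> int:
        return len(self.hexagons)

    @property
    def n_octagons(self) -> int:
        return len(self.octagons)

    @property
    def nodes_in_squares(self) -> set:
        out: set = set()
        for sq in self.squares:
            out |= sq
        return out

    def counts(self) -> dict[int, int]:
        return {4: self.n_squares, 6: self.n_hexagons, 8: self.n_octagons}

    def node_set_counts(self) -> dict[int, int]:
        """Counts after collapsing cycles that share a node set.

        For elementary (chordless) cycles the node set determines the cycle,
        so these normally equal :meth:`counts`; both views are kept because
        distinct cyclic orderings of one node set are conceivable in
        degenerate graphs.
        """
        return {
            4: len(self.squares),
            6: len({frozenset(c) for c in self.hexagons}),
            8: len({frozenset(c) for c in self.octagons}),
        }


def is_elementary(cycle: tuple, graph: nx.Graph) -> bool:
    """True iff ``cycle`` (a node sequence) is a chordless cycle of ``graph``.

    Raises ``ValueError`` when the sequence is not a cycle at all.
    """
    n = len(cycle)
    if n < 3 or len(set(cycle)) != n:
        raise ValueError("input is not a simple cycle")
    for i in range(n):
        if not graph.has_edge(cycle[i], cycle[(i + 1) % n]):
            raise ValueError("input is not a cycle of the graph")
    induced_edges = sum(1 for u, v in combinations(cycle, 2) if graph.has_edge(u, v))
    return induced_edges == n


def _canonical_cycle(seq: tuple) -> tuple:
    """Canonical form of a cyclic node sequence under rotation and reflection."""
    n = len(seq)
    best = None
    for rot in (seq, tuple(reversed(seq))):
        for i in range(n):
            cand = rot[i:] + rot[:i]
            if best is None or cand < best:
                best = cand
    return best


def count_squares(graph: nx.Graph) -> set[frozenset]:
    """Enumerate all elementary squares, returned as 4-node sets.

    Walks closed paths of length four from every node (each square would be
    met eight times — two directions, four starting corners) and deduplicates
    by sorted node set; chorded 4-cycles are discarded as non-elementary.
    In bipartite networks no chord can exist, so there the census equals the
    count of all 4-cycles.
    """
    squares: set[frozenset] = set()
    adj = {u: set(graph.neighbors(u)) for u in graph.nodes}
    nodes = sorted(graph.nodes, key=repr)
    for u in nodes:
        nu = adj[u]
        # u - a - w - b - u with a, b common neighbours of u and w
        for a, b in combinations(nu, 2):
            if b in adj[a]:
                continue  # chord a-b: cannot be elementary
            for w in adj[a] & adj[b]:
                if w == u or w in nu:
                    continue  # w==u degenerate; chord u-w otherwise
                squares.add(frozenset((u, a, w, b)))
    return squares


def _closed_walks(graph: nx.Graph, length: int):
    """Yield simple closed walks of ``length`` edges, one canonical copy each."""
    adj = {u: sorted(graph.neighbors(u), key=repr) for u in graph.nodes}
    order = {u: i for i, u in enumerate(sorted(graph.nodes, key=repr))}

    def extend(path: list):
        start = path[0]
        if len(path) == length:
            if start in adj[path[-1]]:
                yield tuple(path)
            return
        for nxt in adj[path[-1]]:
            # prune: only walks whose minimal node is the start are kept
            if order[nxt] <= order[start] or nxt in seen:
                continue
            seen.add(nxt)
            path.append(nxt)
            yield from extend(path)
            path.pop()
            seen.discard(nxt)

    for u in graph.nodes:
        seen = {u}
        yield from extend([u])


def count_longer_cycles(graph: nx.Graph, length: int) -> set[tuple]:
    """Enumerate elementary cycles of ``length`` 6 or 8 (canonical sequences)."""
    if length not in (6, 8):
        raise ValueError(f"cycle length must be 6 or 8, got {length}")
    found: set[tuple] = set()
    for walk in _closed_walks(graph, length):
        canon = _canonical_cycle(walk)
        if canon in found:
            continue
        if is_elementary(canon, graph):
            found.add(canon)
    return found


def census(graph: nx.Graph, max_len: int = 8) -> CycleCensus:
    """Full elementary-cycle census up to ``max_len`` (4, 6 or 8).

    Longer cycles are computationally out of reach for the exhaustive search
    and are rejected.
    """
    if max_len not in SUPPORTED_LENGTHS:
        raise ValueError(f"max_len must be one of {SUPPORTED_LENGTHS}")
    out = CycleCensus(squares=count_squares(graph))
    if max_len >= 6:
        out.hexagons = count_longer_cycles(graph, 6)
    if max_len >= 8:
        out.octagons = count_longer_cycles(graph, 8)
    return out


def nodes_in_squares_fraction(cc: CycleCensus, giant: nx.Graph) -> tuple[float, int]:
    """Fraction and count of giant-component nodes lying on at least one square."""
    if giant.number_of_nodes() == 0:
        raise ValueError("empty giant component")
    members = cc.nodes_in_squares & set(giant.nodes)
    return len(members) / giant.number_of_nodes(), len(members)


def assert_no_odd_cycles(graph: nx.Graph) -> dict:
    """Check the parity argument: biallelic-site networks must be bipartite.

    Returns a small report; raises ``AssertionError`` on violation, which for
    a network built from a biallelic matrix indicates a construction bug.
    """
    ok = nx.is_bipartite(graph)
    report = {"bipartite": ok, "n_nodes": graph.number_of_nodes()}
    if not ok:
        raise AssertionError("odd-length cycle found in a biallelic-site network")
    return report
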