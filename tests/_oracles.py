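"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — quadratic scans, exhaustive subset
enumeration, direct combinatorial summation — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def hamming1_pairs(sequences):
    """All index pairs of sequences at Hamming distance exactly 1 (quadratic)."""
    pairs = set()
    for i, a in enumerate(sequences):
        for j in range(i + 1, len(sequences)):
            b = sequences[j]
            if len(a) != len(b):
                raise ValueError("ragged pool")
            if sum(x != y for x, y in zip(a, b)) == 1:
                pairs.add((i, j))
    return pairs


def induced_cycles(graph, k):
    """Node sets of induced (chordless) k-cycles, by exhaustive subset search."""
    nodes = list(graph.nodes)
    adj = {u: set(graph.neighbors(u)) for u in nodes}
    found = set()
    for subset in combinations(nodes, k):
        sub = set(subset)
        degs = [len(adj[u] & sub) for u in subset]
        if any(d != 2 for d in degs):
            continue
        n_edges = sum(degs) // 2
        if n_edges != k:
            continue
        # all degree 2 with k edges: either one k-cycle or several smaller
        # disjoint cycles; walk to check connectivity
        start = subset[0]
        seen = {start}
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for v in adj[u] & sub:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        if len(seen) == k:
            found.add(frozenset(subset))
    return found


def union_find_components(nodes, edges):
    """Connected components by a standalone union-find."""
    parent = {u: u for u in nodes}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps = {}
    for u in nodes:
        comps.setdefault(find(u), set()).add(u)
    return sorted(comps.values(), key=lambda c: (-len(c), sorted(map(repr, c))))


def mwu_exact_two_sided_p(sample_a, sample_b):
    """Exact two-sided Mann–Whitney p by full enumeration of group labelings.

    Feasible for total n <= 12.  Two-sided p doubles the smaller tail
    probability of U (capped at 1), the classic exact convention.
    """
    a = list(sample_a)
    b = list(sample_b)
    pooled = a + b
    n, m = len(a), len(b)

    def u_stat(first_idx):
        first = [pooled[i] for i in first_idx]
        second = [pooled[i] for i in range(n + m) if i not in set(first_idx)]
        u = 0.0
        for x in first:
            for y in second:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_stat(tuple(range(n)))
    us = [u_stat(idx) for idx in combinations(range(n + m), n)]
    total = len(us)
    p_low = sum(1 for u in us if u <= u_obs) / total
    p_high = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(p_low, p_high))


def fisher_exact_two_sided_p(table):
    """Exact two-sided Fisher p by enumerating all tables with fixed margins.

    Two-sided by summing probabilities of tables no more likely than the
    observed one (the standard convention).
    """
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):  # x = top-left cell
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = prob(a)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12)))


def hypergeom_upper_tail(k, set1, set2, universe):
    """P(X >= k) for overlap of two fixed-size sets, by direct summation."""
    hi = min(set1, set2)
    total = comb(universe, set2)
    return sum(
        comb(set1, x) * comb(universe - set1, set2 - x) for x in range(k, hi + 1)
    ) / total


def pearson_r(xs, ys):
    """Plain-formula Pearson correlation."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / (sxx * syy) ** 0.5
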