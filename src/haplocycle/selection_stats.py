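"""Downstream selection diagnostics for genes with excess squares.

Given a protein-level haplotype network and its square census, these
routines probe possible evolutionary causes of the squares:

* positive selection — edges lying on squares should carry fewer synonymous
  changes than edges outside squares if the convergent amino-acid changes
  were driven rather than drifting (zero-synonymous contingency via Fisher's
  exact test; mean synonymous load via Mann–Whitney U, BH-corrected across
  genes), plus hypergeometric overlap with externally curated
  positive-selection gene sets and contiguous-window calling on supplied
  selection-scan statistics (e.g. XP-CLR window scores);
* balancing selection — elevated heterozygosity at nonsynonymous sites,
  correlated against square counts across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cyclecensus import CycleCensus
from .hapnet import mann_whitney
from .nullmodels_mutation import bh_fdr


class StatsError(ValueError):
    pass


@dataclass
class EdgeSquareLabeling:
    """Giant-component edges split by square membership, with mean_syn."""

    gene: str
    inside: list[tuple]  # edges (u, v)
    outside: list[tuple]
    mean_syn: dict[tuple, float]

    @property
    def n_inside(self) -> int:
        return len(self.inside)

    @property
    def n_outside(self) -> int:
        return len(self.outside)


def label_edges(giant: nx.Graph, census: CycleCensus) -> EdgeSquareLabeling:
    """Mark each giant edge as inside (on >= 1 square) or outside.

    An edge is inside iff its endpoints are consecutive corners of some
    enumerated square; for an elementary square those are exactly the
    endpoint pairs that are both in the square's node set and adjacent.
    """
    square_edges: set[frozenset] = set()
    for sq in census.squares:
        members = list(sq)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                if giant.has_edge(u, v):
                    square_edges.add(frozenset((u, v)))
    inside, outside = [], []
    mean_syn = {}
    for u, v in giant.edges:
        edge = (u, v)
        mean_syn[edge] = float(giant.edges[u, v].get("mean_syn", 0.0))
        (inside if frozenset(edge) in square_edges else outside).append(edge)
    return EdgeSquareLabeling(
        gene=giant.graph.get("gene", ""), inside=inside, outside=outside,
        mean_syn=mean_syn,
    )


def compare_zero_syn_fraction(labeling: EdgeSquareLabeling) -> dict:
    """Fisher's exact test: zero-synonymous edges inside vs outside squares."""
    if not labeling.inside or not labeling.outside:
        return {"p": None, "table": None, "degenerate": True}
    table = np.array(
        [
            [
                sum(1 for e in labeling.inside if labeling.mean_syn[e] == 0),
                sum(1 for e in labeling.inside if labeling.mean_syn[e] > 0),
            ],
            [
                sum(1 for e in labeling.outside if labeling.mean_syn[e] == 0),
                sum(1 for e in labeling.outside if labeling.mean_syn[e] > 0),
            ],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return {"p": None, "table": table, "degenerate": True}
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"p": float(p), "table": table, "degenerate": False}


def compare_mean_syn(labeling: EdgeSquareLabeling) -> dict:
    """Mann–Whitney U on per-edge mean synonymous changes, inside vs outside.

    Also reports the inside/outside ratio of means; a ratio below 1 means
    edges on squares carry fewer synonymous changes.
    """
    if not labeling.inside or not labeling.outside:
        return {"p": None, "U": None, "ratio": None, "degenerate": True}
    inside_vals = [labeling.mean_syn[e] for e in labeling.inside]
    outside_vals = [labeling.mean_syn[e] for e in labeling.outside]
    u, p = mann_whitney(inside_vals, outside_vals)
    mean_out = float(np.mean(outside_vals))
    mean_in = float(np.mean(inside_vals))
    ratio = mean_in / mean_out if mean_out > 0 else (None if mean_in == 0 else np.inf)
    return {"p": p, "U": u, "ratio": ratio, "degenerate": False}


def mean_syn_panel(labelings: list[EdgeSquareLabeling], alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene inside/outside comparison with BH correction across genes.

    Genes lacking inside or outside edges are excluded (and logged via the
    ``degenerate`` column of the returned frame).
    """
    rows = []
    for lab in labelings:
        res = compare_mean_syn(lab)
        rows.append(
            {
                "gene": lab.gene,
                "n_inside": lab.n_inside,
                "n_outside": lab.n_outside,
                "p": res["p"],
                "ratio": res["ratio"],
                "degenerate": res["degenerate"],
            }
        )
    df = pd.DataFrame(rows)
    ok = ~df["degenerate"]
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = bh_fdr(df.loc[ok, "p"])
    df["significant"] = df["q"] <= alpha
    return df


def heterozygosity(genotypes: np.ndarray) -> float:
    """Mean fraction of heterozygous individuals over nonsynonymous sites.

    ``genotypes`` holds per-individual allele sums (0/1/2), shape (N, S),
    restricted to sites with a nonsynonymous change; heterozygotes are the
    rows with value 1.
    """
    geno = np.asarray(genotypes)
    if geno.ndim != 2 or geno.shape[1] == 0:
        raise StatsError("need a (individuals x sites) matrix with >= 1 site")
    het_frac = (geno == 1).mean(axis=0)
    return float(het_frac.mean())


def correlate_het_squares(het_values, square_counts) -> dict:
    """Pearson correlation of per-gene heterozygosity with square counts."""
    x = np.asarray(het_values, dtype=float)
    y = np.asarray(square_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "p": None, "degenerate": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "degenerate": False}


def hypergeometric_overlap(k_hits: int, set1_size: int, set2_size: int, universe: int) -> float:
    """Upper-tail P(X >= k) for the overlap of two gene sets in a universe."""
    if not (0 <= k_hits <= min(set1_size, set2_size) <= universe):
        raise StatsError("inconsistent overlap counts")
    if max(set1_size, set2_size) > universe:
        raise StatsError("set larger than universe")
    return float(stats.hypergeom.sf(k_hits - 1, universe, set1_size, set2_size))


def call_windows(
    windows: pd.DataFrame,
    genes: pd.DataFrame,
    alpha: float = 0.01,
    min_contiguous: int = 2,
    contiguous: bool = True,
) -> pd.DataFrame:
    """Call genes under a selection scan from externally supplied window scores.

    ``windows``: columns (contig, start, end, pair, statistic); 0-based
    half-open, non-overlapping per population-pair track, sorted per track.
    ``genes``: columns (gene, contig, start, end).

    Windows with statistic 0 carry no information and are excluded before
    ranking; the top ``alpha`` quantile of the remaining windows in each
    track is significant.  With ``contiguous=True`` (the conservative
    default) a gene is called in a track only if a run of at least
    ``min_contiguous`` genomically abutting significant windows overlaps it;
    otherwise ``min_contiguous`` overlapping significant windows suffice
    regardless of adjacency.
    """
    for col in ("contig", "start", "end", "pair", "statistic"):
        if col not in windows.columns:
            raise StatsError(f"window table lacks column {col!r}")
    calls = []
    for pair, track in windows.groupby("pair"):
        track = track.reset_index(drop=True)
        for contig, sub in track.groupby("contig"):
            if not sub["start"].is_monotonic_increasing:
                raise StatsError(f"unsorted windows on {contig} for pair {pair}")
        scored = track[track["statistic"] != 0].reset_index(drop=True)
        if scored.empty:
            continue
        # rank-ordered significance: the top floor(alpha * n) windows of the
        # track; a plain quantile cutoff misbehaves under heavy ties
        n_sig = int(np.floor(alpha * len(scored)))
        order = np.argsort(-scored["statistic"].to_numpy(), kind="mergesort")
        flags = np.zeros(len(scored), dtype=bool)
        flags[order[:n_sig]] = True
        scored = scored.assign(significant=flags)
        sig = scored[scored["significant"]]
        if contiguous:
            runs = _significant_runs(scored, min_contiguous)
        else:
            runs = [[row] for row in sig.itertuples()]
        for _, gene in genes.iterrows():
            hit = False
            if contiguous:
                for run in runs:
                    if any(
                        w.contig == gene["contig"]
                        and w.start < gene["end"]
                        and gene["start"] < w.end
                        for w in run
                    ):
                        hit = True
                        break
            else:
                n_overlap = sum(
                    1
                    for w in sig.itertuples()
                    if w.contig == gene["contig"]
                    and w.start < gene["end"]
                    and gene["start"] < w.end
                )
                hit = n_overlap >= min_contiguous
            if hit:
                calls.append({"gene": gene["gene"], "pair": pair})
    return pd.DataFrame(calls, columns=["gene", "pair"])


def _significant_runs(scored: pd.DataFrame, min_len: int) -> list[list]:
    """Maximal runs of >= min_len abutting significant windows, per contig."""
    runs: list[list] = []
    for _, sub in scored.groupby("contig"):
        sub = sub.sort_values("start")
        current: list = []
        prev_end = None
        for row in sub.itertuples():
            if row.significant:
                if current and row.start != prev_end:
                    if len(current) >= min_len:
                        runs.append(current)
                    current = []
                current.append(row)
            else:
                if len(current) >= min_len:
                    runs.append(current)
                current = []
            prev_end = row.end
        if len(current) >= min_len:
            runs.append(current)
    return runs
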