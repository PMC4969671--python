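import networkx as nx
import numpy as np
import pandas as pd
import pytest
from _oracles import (
    fisher_exact_two_sided_p,
    hypergeom_upper_tail,
    mwu_exact_two_sided_p,
    pearson_r,
)

from haplocycle.cyclecensus import census
from haplocycle.selection_stats import (
    EdgeSquareLabeling,
    StatsError,
    call_windows,
    compare_mean_syn,
    compare_zero_syn_fraction,
    correlate_het_squares,
    heterozygosity,
    hypergeometric_overlap,
    label_edges,
    mean_syn_panel,
)


def labeling(inside_syn, outside_syn):
    inside = [("i", k) for k in range(len(inside_syn))]
    outside = [("o", k) for k in range(len(outside_syn))]
    mean_syn = {e: v for e, v in zip(inside, inside_syn)}
    mean_syn.update({e: v for e, v in zip(outside, outside_syn)})
    return EdgeSquareLabeling(
        gene="g", inside=inside, outside=outside, mean_syn=mean_syn
    )


class TestLabelEdges:
    def test_pure_square_all_inside(self):
        g = nx.cycle_graph(4)
        lab = label_edges(g, census(g))
        assert lab.n_inside == 4 and lab.n_outside == 0

    def test_square_with_pendant(self):
        g = nx.cycle_graph(4)
        g.add_edge(3, 9)
        lab = label_edges(g, census(g))
        assert lab.n_inside == 4 and lab.n_outside == 1

    def test_partition_covers_all_edges(self):
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        lab = label_edges(g, census(g))
        assert lab.n_inside + lab.n_outside == g.number_of_edges()

    @pytest.mark.parametrize("seed", range(4))
    def test_membership_matches_bruteforce(self, seed):
        from _oracles import induced_cycles

        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        lab = label_edges(g, census(g))
        squares = induced_cycles(g, 4)
        adj_pairs = set()
        for sq in squares:
            for u in sq:
                for v in sq:
                    if u < v and g.has_edge(u, v):
                        adj_pairs.add(frozenset((u, v)))
        assert {frozenset(e) for e in lab.inside} == adj_pairs


class TestFisherZeroSyn:
    def test_complete_separation_exact_p(self):
        lab = labeling(inside_syn=[0] * 5, outside_syn=[1] * 5)
        res = compare_zero_syn_fraction(lab)
        # table [[5,0],[0,5]]: two-sided p = 2/252
        assert res["p"] == pytest.approx(2 / 252)

    def test_identical_rows_p_one(self):
        lab = labeling(inside_syn=[0, 0, 1, 1], outside_syn=[0, 0, 1, 1])
        assert compare_zero_syn_fraction(lab)["p"] == pytest.approx(1.0)

    def test_degenerate_margins_flagged(self):
        lab = labeling(inside_syn=[1, 2], outside_syn=[3, 4])  # no zero edges
        assert compare_zero_syn_fraction(lab)["degenerate"]
        lab2 = labeling(inside_syn=[], outside_syn=[1])
        assert compare_zero_syn_fraction(lab2)["degenerate"]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        inside = list(rng.integers(0, 2, size=int(rng.integers(2, 7))))
        outside = list(rng.integers(0, 2, size=int(rng.integers(2, 7))))
        lab = labeling(inside, outside)
        res = compare_zero_syn_fraction(lab)
        if res["degenerate"]:
            pytest.skip("degenerate draw")
        table = res["table"]
        assert res["p"] == pytest.approx(
            fisher_exact_two_sided_p(table.tolist()), abs=1e-9
        )


class TestMeanSynComparison:
    def test_identical_distributions(self):
        lab = labeling(inside_syn=[1, 2, 3], outside_syn=[1, 2, 3])
        res = compare_mean_syn(lab)
        assert res["ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_inside_zero_outside_positive(self):
        inside = [0.0] * 4
        outside = [2.0] * 4
        res = compare_mean_syn(labeling(inside, outside))
        assert res["ratio"] == 0.0
        assert res["p"] == pytest.approx(
            mwu_exact_two_sided_p(inside, outside), abs=0.02
        )

    def test_undefined_ratio_flagged(self):
        res = compare_mean_syn(labeling([1.0], [0.0]))
        assert res["ratio"] == np.inf

    def test_panel_applies_shared_bh(self):
        labs = [
            labeling([0.0] * 6, [2.0] * 6),
            labeling([1.0, 2.0], [1.0, 2.0]),
            labeling([], [1.0]),  # degenerate, excluded
        ]
        df = mean_syn_panel(labs, alpha=0.5)
        assert df["degenerate"].tolist() == [False, False, True]
        from haplocycle.nullmodels_mutation import bh_fdr

        expected_q = bh_fdr(df.loc[~df["degenerate"], "p"])
        assert np.allclose(df.loc[~df["degenerate"], "q"], expected_q)


class TestHeterozygosity:
    def test_all_homozygous(self):
        assert heterozygosity(np.array([[0, 2], [2, 0]])) == 0.0

    def test_all_heterozygous(self):
        assert heterozygosity(np.ones((3, 4))) == 1.0

    def test_hand_counted_fixture(self):
        # site 1: 2 of 4 heterozygous; site 2: 1 of 4 -> mean 0.375
        geno = np.array([[1, 0], [1, 2], [0, 1], [2, 0]])
        assert heterozygosity(geno) == pytest.approx(0.375)

    def test_order_invariance(self, rng):
        geno = rng.integers(0, 3, size=(10, 6))
        shuffled = geno[rng.permutation(10)][:, rng.permutation(6)]
        assert heterozygosity(geno) == pytest.approx(heterozygosity(shuffled))

    def test_zero_sites_flagged(self):
        with pytest.raises(StatsError):
            heterozygosity(np.zeros((4, 0)))


class TestCorrelation:
    def test_perfect_correlation(self):
        res = correlate_het_squares([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert res["r"] == pytest.approx(1.0)

    def test_five_point_closed_form(self):
        x = [0.1, 0.3, 0.2, 0.5, 0.4]
        y = [3, 1, 4, 1, 5]
        res = correlate_het_squares(x, y)
        assert res["r"] == pytest.approx(pearson_r(x, y))

    def test_zero_variance_flagged(self):
        assert correlate_het_squares([0.1] * 5, [1, 2, 3, 4, 5])["degenerate"]

    def test_null_calibration(self):
        """Independent inputs give small r and roughly uniform p."""
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=300)
            y = rng.poisson(3, size=300)
            res = correlate_het_squares(x, y)
            assert abs(res["r"]) < 0.25
            pvals.append(res["p"])
        assert 0.05 < np.mean(pvals) < 0.95


class TestHypergeometricOverlap:
    def test_everything_overlaps(self):
        assert hypergeometric_overlap(5, 5, 5, 5) == pytest.approx(1.0)

    def test_zero_hits(self):
        assert hypergeometric_overlap(0, 5, 7, 30) == pytest.approx(1.0)

    def test_small_instance_matches_bruteforce(self):
        assert hypergeometric_overlap(3, 5, 5, 20) == pytest.approx(
            hypergeom_upper_tail(3, 5, 5, 20)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = int(rng.integers(10, 50))
        s1 = int(rng.integers(1, universe))
        s2 = int(rng.integers(1, universe))
        k = int(rng.integers(0, min(s1, s2) + 1))
        assert hypergeometric_overlap(k, s1, s2, universe) == pytest.approx(
            hypergeom_upper_tail(k, s1, s2, universe), rel=1e-9
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(StatsError):
            hypergeometric_overlap(6, 5, 5, 20)


def window_frame(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "pair", "statistic"])


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "contig", "start", "end"])


class TestCallWindows:
    @staticmethod
    def track(stats_list, pair="CEU-YRI"):
        return window_frame(
            [
                ("chr1", 2000 * i, 2000 * (i + 1), pair, s)
                for i, s in enumerate(stats_list)
            ]
        )

    def test_two_adjacent_significant_windows_call_gene(self):
        stats_list = [1.0] * 96 + [50.0, 60.0] + [1.0] * 2
        windows = self.track(stats_list)
        genes = gene_frame([("G", "chr1", 96 * 2000 + 100, 97 * 2000 + 100)])
        called = call_windows(windows, genes, alpha=0.02)
        assert called["gene"].tolist() == ["G"]

    def test_single_significant_window_not_called(self):
        stats_list = [1.0] * 98 + [50.0] + [1.0]
        windows = self.track(stats_list)
        genes = gene_frame([("G", "chr1", 98 * 2000, 99 * 2000)])
        assert call_windows(windows, genes, alpha=0.01).empty

    def test_overlap_count_reading_via_flag(self):
        # two significant but non-adjacent windows over one long gene
        stats_list = [1.0] * 100
        stats_list[10] = 50.0
        stats_list[14] = 60.0
        windows = self.track(stats_list)
        genes = gene_frame([("G", "chr1", 10 * 2000, 15 * 2000)])
        assert call_windows(windows, genes, alpha=0.02).empty
        called = call_windows(windows, genes, alpha=0.02, contiguous=False)
        assert called["gene"].tolist() == ["G"]

    def test_zero_statistic_windows_excluded_from_ranking(self):
        # 50 zero windows must not dilute the rank quantile
        stats_list = [0.0] * 50 + [1.0] * 47 + [9.0, 9.5] + [1.0]
        windows = self.track(stats_list)
        genes = gene_frame([("G", "chr1", 97 * 2000, 99 * 2000)])
        called = call_windows(windows, genes, alpha=0.05)
        assert called["gene"].tolist() == ["G"]

    def test_unsorted_windows_rejected(self):
        windows = window_frame(
            [
                ("chr1", 4000, 6000, "p", 1.0),
                ("chr1", 0, 2000, "p", 2.0),
            ]
        )
        with pytest.raises(StatsError, match="unsorted"):
            call_windows(windows, gene_frame([]), alpha=0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_scan(self, seed):
        """An independent re-scan (quantile cutoff + run detection written
        from scratch) agrees on which genes are called."""
        rng = np.random.default_rng(seed)
        stats_list = list(rng.exponential(size=200))
        windows = self.track(stats_list)
        genes = gene_frame(
            [(f"g{k}", "chr1", int(s), int(s) + 5000)
             for k, s in enumerate(rng.integers(0, 195 * 2000, size=30))]
        )
        called = set(call_windows(windows, genes, alpha=0.05)["gene"])

        k = int(np.floor(0.05 * len(stats_list)))
        cutoff = sorted(stats_list, reverse=True)[k - 1]
        sig = [s >= cutoff for s in stats_list]
        expected = set()
        for _, g in genes.iterrows():
            for i in range(len(sig) - 1):
                if sig[i] and sig[i + 1]:
                    run_lo, run_hi = 2000 * i, 2000 * (i + 2)
                    if run_lo < g["end"] and g["start"] < run_hi:
                        expected.add(g["gene"])
        assert called == expected
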