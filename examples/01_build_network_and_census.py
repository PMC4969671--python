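"""Build haplotype networks for a small synthetic cohort and census cycles.

Simulates two genes — one evolving tree-like, one with planted recurrent
evolution — builds their protein-level haplotype networks and prints the
topology summary plus the elementary-cycle census of each giant component.
"""

from haplocycle import pipeline
from haplocycle.cyclecensus import census, nodes_in_squares_fraction
from haplocycle.hapnet import build_network, giant, summarize
from haplocycle.synthetic_cohort import (
    CohortSpec,
    homoplastic_gene_spec,
    simulate_cohort,
    tree_gene_spec,
)

spec = CohortSpec(
    n_individuals=50,
    genes=[
        tree_gene_spec("TREELIKE"),
        homoplastic_gene_spec("HOMOPLASTIC", planted_squares=6,
                              n_nonsyn_sites=24, cds_length_nt=600),
    ],
    seed=11,
)
cohort = simulate_cohort(spec)

for name, matrix in pipeline.cohort_matrices(cohort).items():
    network = build_network(matrix, level="protein")
    summary = summarize(network)
    g = giant(network)
    cc = census(g, max_len=8)
    print(f"\n{name}: {summary.n_nodes} nodes, {summary.n_edges} edges, "
          f"{summary.n_components} components, giant {summary.giant_size} "
          f"({summary.giant_fraction:.2f} of nodes)")
    print(f"  giant cycles: {cc.n_squares} squares, {cc.n_hexagons} hexagons, "
          f"{cc.n_octagons} octagons")
    if cc.n_squares:
        frac, count = nodes_in_squares_fraction(cc, g)
        print(f"  {count} giant nodes ({frac:.0%}) lie on at least one square")

print(
    "\nSquares mark convergent amino-acid changes (homoplasy): the tree-like\n"
    "gene has none, the recurrent-evolution gene shows a dense square cluster."
)
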