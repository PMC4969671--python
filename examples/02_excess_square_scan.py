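"""Scan a cohort of genes for a significant excess of squares.

Simulates 20 genes of which 2 carry strong recurrent evolution, compares
each gene's observed giant-component square count with 200 degree-guided
mutation-null replicates (constrained variant), and reports the
BH-corrected calls.  Only the planted genes should be flagged.
"""

import numpy as np

from haplocycle import pipeline
from haplocycle.synthetic_cohort import demo_cohort_spec, simulate_cohort

cohort = simulate_cohort(demo_cohort_spec(n_genes=20, n_homoplastic=2, seed=7))
matrices = pipeline.cohort_matrices(cohort)
distributions, called = pipeline.excess_square_scan(
    matrices, variant="constrained", n_reps=200, seed=7, alpha=0.1
)

print(f"{'gene':>10} {'observed':>8} {'null mean':>9} {'null max':>8} "
      f"{'p':>7} {'q':>7}")
for d in sorted(distributions, key=lambda d: d.gene):
    if d.observed_squares == 0:
        continue
    counts = np.array(d.replicate_counts)
    q = f"{d.q_bh:.4f}" if d.q_bh is not None else "     -"
    print(f"{d.gene:>10} {d.observed_squares:>8} {counts.mean():>9.2f} "
          f"{counts.max():>8} {d.p_empirical:>7.4f} {q:>7}")

print(f"\ngenes called at q <= 0.1: {sorted(called)}")
truth = sorted(g.spec.name for g in cohort.genes if g.spec.planted_squares)
print(f"planted homoplastic genes: {truth}")
print("A called gene has more squares than every null replicate (empirical\n"
      "p = 1/200), i.e. its homoplasy cannot be explained by chance mutation.")
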