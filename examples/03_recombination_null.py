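"""Test whether recombination could explain a gene's square excess.

Builds one strongly homoplastic gene, then simulates 200 one-round diploid
populations with the mutation budget of the observed network and a
recombination budget anchored on the gene's synonymous diversity
(generations-to-ancestry S / (L * mu * Ne)).  Sensitivity presets raise the
effective population size ten-fold or double the crossover rate.
"""

import numpy as np

from haplocycle import pipeline
from haplocycle.cyclecensus import count_squares
from haplocycle.hapnet import build_network, giant
from haplocycle.nullmodels_recomb import (
    RecombParams,
    expected_recomb_per_pair,
    recomb_null_test,
)
from haplocycle.synthetic_cohort import CohortSpec, homoplastic_gene_spec, simulate_cohort

cohort = simulate_cohort(
    CohortSpec(n_individuals=100, genes=[homoplastic_gene_spec("HOM")], seed=3)
)
matrix = pipeline.cohort_matrices(cohort)["HOM"]
g = giant(build_network(matrix, level="protein"))
observed = len(count_squares(g))
n_sites = int((matrix.classes == "nonsynonymous").sum())

params = RecombParams(S=10, L=60_000)  # 10 synonymous sites, 60 kb gene
print(f"observed squares in giant: {observed}")
print(f"expected crossovers per sequence pair r = "
      f"{expected_recomb_per_pair(params):.3f}")

for preset in ("baseline", "Ne10x", "rho2x"):
    dist = recomb_null_test(
        g, params, observed, n_sites, n_reps=200, seed=3, gene="HOM",
        preset=preset,
    )
    counts = np.array(dist.replicate_counts)
    print(f"{preset:>9}: null mean {counts.mean():6.2f}, max {counts.max():3d}, "
          f"empirical p = {dist.p_empirical:.4f}")

print("\nThe observed count exceeding every replicate under all presets means\n"
      "recombination at plausible rates cannot account for the squares.")
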