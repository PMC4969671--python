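# Methods

This note records the models, conventions and numerical choices behind
`haplocycle`, and what the synthetic-data tests do and do not establish.

## Networks

A gene's sample of 2N phased haplotypes is reduced to its polymorphic sites
(after the ingest filters: FILTER = PASS, biallelic SNV, fully phased and
complete genotypes, minor allele frequency ≥ 0.01 computed over the 2N
haplotypes — haplotypes, not individuals, are the analysis unit). Nodes are
equivalence classes of identical site vectors; at the protein level only
nonsynonymous sites are active, so classes merge synonymous variation.
Edges join classes at Hamming distance exactly 1 over the active sites.
Adjacency is found by bucketing each vector once per site with that site
masked; two vectors share a bucket at site *i* iff they agree everywhere
else, which makes the procedure equivalent to the quadratic all-pairs scan
(property-tested against it) at near-linear cost.

Each protein-level edge carries `mean_syn`: the mean count of synonymous
differences over all member-haplotype pairs of its endpoints, stored as an
exact `Fraction` so that downstream rank statistics are immune to float
drift. The giant component is the largest component, ties broken by the
lexicographically smallest node-id set for determinism. Degree
assortativity is the Pearson correlation of endpoint degrees with both edge
orientations included; for regular graphs (zero degree variance) it is
reported as undefined (`None`) rather than NaN.

Mann–Whitney comparisons use the exact distribution when both samples have
≤ 20 tie-free observations and the tie-corrected normal approximation with
continuity correction otherwise.

## Cycle census

Networks built from biallelic sites are bipartite (each edge toggles one
site, a closed walk toggles every site an even number of times), so odd
cycles are impossible and the shortest cycle is the square. A cycle is
**elementary** when it is not decomposable into shorter ones; this is
operationalized as chordlessness — the subgraph induced by the cycle's
nodes contains exactly the cycle's edges. For squares and hexagons
chordlessness and "induces no shorter cycle" coincide; for octagons the
induced-edge-count check is equivalent because any extra induced edge is a
chord. Note that this is a *subgraph* notion, not a cycle-space one: a
3-dimensional hypercube contains four skew hexagons that are sums of faces
in the cycle space yet chordless, and they count as elementary here.

Squares are enumerated from common-neighbor pairs of non-adjacent node
pairs, hexagons and octagons by depth-first closed walks with
start-node-minimality pruning, deduplicated by node set (squares) or by
rotation/reflection-canonical sequence (6/8-cycles, with node-set counts
also available). Every census path is tested against exhaustive
induced-subgraph enumeration on random graphs. Lengths beyond eight are
rejected; the exhaustive walk becomes too costly there and longer cycles
are outside the analysis.

## Mutation-only null models

The null asks how many squares a network with the observed amount of
evolutionary change shows when every change is an independent random
mutation. One replicate regrows the observed giant component: a random node
receives a random root sequence; a breadth-first traversal then spends
**exactly one mutation per original edge** — when a node is processed, each
incident unprocessed edge produces one mutant of the node's assigned
sequence, credited to the neighbor; a neighbor reached again keeps its
first sequence, and the surplus mutant only joins the pool. The pool (root
+ |E| mutants) is merged by sequence identity and rebuilt into a distance-1
network whose squares are counted (the pool network is connected by
construction, so the whole network is in scope). A stricter
once-per-incident-edge-per-node reading (2|E| events) is available behind
`per_node_degree=True` for sensitivity analysis.

Two root/mutation variants bracket the constraints:

* **fulllength** — root is a uniform random nucleotide sequence over the
  gene's coding stretch (the union of all transcript CDS coverage); a
  mutation picks a random transcript, a random site in it and a random
  different base, rejection-sampling until the change is nonsynonymous in
  that transcript. Pool adjacency is nucleotide Hamming distance 1.
* **constrained** — root is a random binary vector with one position per
  observed nonsynonymous polymorphic site; a mutation toggles one uniformly
  chosen position. This respects the biallelic, few-sites structure of real
  data and produces far more chance squares, making it the conservative
  null (the conservatism ordering is asserted in the acceptance suite).

Empirical p is `max(#{replicates ≥ observed}, 1) / n_reps` — the floor
1/n_reps encodes that n_reps replicates cannot resolve smaller tail
probabilities. FDR control is Benjamini–Hochberg (via statsmodels),
applied only to genes with at least one square: a square-free gene cannot
show an excess and would only dilute the correction. Replicates are seeded
counter-style per (gene, replicate index) with CRC32 gene tags, so any
replicate is reproducible in isolation and results are independent of
execution order.

## Recombination null

Squares can also arise when crossover between two lineages recreates a
haplotype. One replicate simulates a single round over a diploid
population of `ceil(|V|/2)` individuals, all initially homozygous for one
random binary sequence over the gene's nonsynonymous sites:

1. **Mutation.** With budget |E| (the giant's edge count), each haplotype
   receives `allocate(M)` single-site toggles, `M = |E| / n_haplotypes`,
   where `allocate` returns ⌊x⌋+1 with probability x−⌊x⌋ (unbiased
   integerisation), so the expected total equals |E|.
2. **Recombination.** Each individual's pair undergoes `allocate(r)`
   reciprocal suffix exchanges at a breakpoint uniform on 1..L−1 (so both
   products are genuinely recombinant; the same breakpoint twice restores
   the originals). The per-pair expectation is
   `r = ρ·10⁻⁸·L·G / sample_size` with `G = S/(L·μ·N_e)` generations to
   common ancestry; 1 cM = 1 % crossover probability fixes the unit
   conversion. The generations formula is implemented exactly as stated
   and kept behind one function: placing N_e in the denominator is
   dimensionally unusual for a coalescent expectation, and isolating it
   allows alternative calibrations to be swapped in. S counts synonymous
   polymorphic *sites*, not change events.
3. **Reproduction.** Individuals are paired at random (an odd leftover
   pairs with a random partner); each pair produces two offspring, each
   sampling one haplotype per parent with replacement. The network built
   from the offspring haplotypes is censused.

Defaults: μ = 1.1 × 10⁻⁸, N_e = 10,000, ρ = 0.952 cM/Mb, sample size
1,092 pairs; presets `Ne10x` (N_e = 100,000) and `rho2x` (1.90 cM/Mb)
change only their own field. The `shared_synonymous_fraction` diagnostic
reports, per edge, the fraction of its synonymous changes that also occur
on another edge — pervasive sharing would mean S overstates the gene's age
and hence the recombination budget.

## Selection diagnostics

Edges are inside a square iff their endpoints are consecutive corners of
an enumerated square. The zero-synonymous contingency (inside/outside ×
zero/nonzero `mean_syn`) uses Fisher's exact test; mean `mean_syn` values
are compared by Mann–Whitney with BH correction across genes, alongside
the inside/outside ratio of means (ratio < 1: fewer synonymous changes on
square edges, a hint of driven rather than drifting convergence). Genes
lacking inside or outside edges are excluded and flagged. Gene-level
heterozygosity is the mean over nonsynonymous sites of the fraction of
heterozygous individuals; its correlation with square counts (Pearson,
t-based p) probes balancing selection. Set overlaps use the upper-tail
hypergeometric probability with the universe size an explicit argument
(never hard-coded, since the appropriate gene universe depends on the
annotation in use).

Selection-scan calling consumes externally computed per-window statistics
(e.g. cross-population composite likelihood ratios over 2 kb windows).
Zero-valued windows carry no information and are removed before ranking;
the top ⌊α·n⌋ windows of a population-pair track are significant (a rank
rule — an interpolated quantile misbehaves under heavy ties). The default,
conservative criterion calls a gene only when a run of at least two
genomically abutting significant windows overlaps it; a flag switches to
the laxer ≥ k overlapping-significant-windows reading.

## Synthetic cohorts

The generator emulates what the pipeline assumes about real panels: phased
diploid individuals, biallelic SNPs at MAF ≥ 0.01, synonymous and
nonsynonymous coding sites that are classified by actually translating the
synthetic CDS (annotation is internally consistent by construction, with
frame-aligned overlapping transcripts), and haplotypes related by a
genealogy. The genealogy is a random binary branching of the 2N
haplotypes, not a calibrated coalescent: the analysis consumes only
haplotype sets, so clade structure suffices. In **tree** mode each site's
derived allele marks exactly one clade — a perfect phylogeny — which
guarantees square-free networks and gives the excess-square scan a clean
negative control. In **recurrent** mode a quarter of the sites receive the
union of two disjoint clades (true recurrent mutation), and
`plant_square_motif` installs explicit square motifs: the four states
{00, 01, 10, 11} at a nonsynonymous site pair on a shared background.
Successive plantings chain off the previous square's far corner, producing
one connected ladder-like square cluster — the shape recurrent evolution
along a genealogy produces — rather than a single high-degree hub, which a
degree-guided null would largely reproduce by chance. Planted quartet rows
are protected from later edits; if planting or recombination pushes a site
below the MAF floor, alleles in unprotected rows are flipped back above
it.

Reference study conditions (`demo_cohort_spec`): 100 diploid individuals,
50 genes of which 5 are homoplastic. Tree-like genes have 12
nonsynonymous + 6 synonymous sites on a 300 nt CDS; homoplastic genes have
60 nonsynonymous + 10 synonymous sites on a 1,200 nt CDS with 12 planted
squares — giants of ~35 nodes carrying a dozen squares, the regime (tens
of squares, giants of tens to hundreds of nodes) in which real genes show
a detectable excess, scaled to desk size. Site frequencies are drawn at
MAF 0.05–0.5.

What the synthetic data does **not** emulate: realistic human demography
and linkage maps, selection acting during the simulation, genotyping
error, or the empirical site-frequency spectrum. Passing tests therefore
establish the correctness and calibration of the machinery — filters,
network construction, censuses, null-model mechanics, recovery of planted
homoplasy with zero false positives — not the genome-wide prevalence of
square excesses in any real cohort, which requires the full phased panel
as input.

Determinism: one seed per cohort; per-gene streams are spawned with fixed
keys, so a gene is reproducible without simulating its predecessors, and
fixed seeds give byte-identical VCF/annotation/truth output.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; VCF and the consequence
  table are 1-based. Allele code 0 is always REF.
* Multiallelic records are dropped (with a logged count), not split;
  records with any missing genotype are dropped; a record lacking a GT
  field altogether is a malformed input and raises.
* A change nonsynonymous in ≥ 1 overlapping transcript is classified
  nonsynonymous.
* Rejection sampling in the full-length mutator is capped (10⁵ draws)
  to surface degenerate gene models instead of hanging.
* The problem sizes in the test suite and acceptance script (cohorts of
  50 genes, 100–200 mutation-null replicates, 100–400 oracle graphs) are
  chosen so the full pipeline — generator through FDR — runs end-to-end
  in minutes on one core while keeping the planted-truth margins wide
  (observed squares ≥ 12 vs null maxima ≤ 9 across probed seeds).

## Known limitations

* The exhaustive cycle walk is exponential in cycle length; the census
  stops at octagons.
* The empirical p cannot fall below 1/n_reps; no importance sampling is
  provided for smaller tails.
* The recombination null runs a single mutate/recombine/reproduce round,
  following the procedure it models, not an iterated forward simulation.
* `giant`-based analyses ignore smaller components by design; both
  whole-network and giant-only square counts are reported by the census
  layer so the difference is visible.
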