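# Methods

## Network proximity statistic

The proximity of a candidate module to a disease gene set is the doubly
averaged shortest-path distance `D = (1/|S|) Σ_s (1/|T|) Σ_t d_st` on an
undirected, unweighted interactome. The module *S* is the candidate protein
plus its first neighbors; *T* is the disease gene set. `d_ss = 0`
contributes when a gene belongs to both sets. Distances are undefined
across components, so all computation is restricted to the largest
connected component (ties between equal components broken toward the
lexicographically smallest member). Gene symbols are compared exactly and
case-sensitively; symbols absent from the graph are dropped and counted,
never silently aliased.

For fixed *T* the per-node mean distance to *T* is precomputed with one BFS
per disease gene, after which any source set is scored in O(|S|) lookups;
this is what makes N-fold randomization cheap (N·|S| lookups instead of
N·|S| BFS runs).

### Degree-preserving null

Nodes are partitioned into degree bins by greedy low-to-high merging of
unique degree values until each bin holds at least `min_bin_size` genes
(default 100 for genome-scale interactomes; the synthetic analyses use
25–50 for their 500–2,000-node graphs so that bins stay informative); an
undersized trailing remainder merges into the previous bin. A null replicate
replaces the whole module with one uniform draw per member from that
member's bin, without replacement within the replicate; original module
genes remain eligible. *T* is never randomized.

The empirical p-value is the strict fraction `p_emp = #(D_r < D)/N`; ties
count as "not less". Its granularity is 1/N, reported as the detection
threshold (0.004 at the default N = 250) and rendered `< 1/N` when
`p_emp = 0`. The conservative variant `(count+1)/(N+1)` is stored alongside
but never drives masking; matrix cells are masked when `p_emp > 0.05`
(strictly greater). A z-score against the null is reported for convenience
and is undefined when the null distribution is degenerate (all replicates
identical). One master seed drives the whole matrix; each cell uses an RNG
substream derived from CRC32 hashes of its (candidate, disease) labels, so
results are independent of evaluation order.

### What the null does and does not control

The null matches degree only. Two second-order effects are real properties
of first-neighbor modules and are *not* removed by design:

* **Hub centrality.** Neighbors of the very highest-degree hubs are more
  central than bin-mates of equal degree, so a top-hub module is closer to
  *any* gene set than its degree-matched nulls. Synthetic planting
  experiments therefore use a moderate-degree candidate
  (`synth.pick_candidate`, target degree 10) so that significance reflects
  the planted proximity rather than candidate centrality.
* **Module clustering.** Even at moderate degree, a connected first-neighbor
  module differs topologically from a scattered degree-matched set, which
  shifts its p-values off exact uniformity under a uniform-T null; the
  direction and size depend on the graph. Calibration is therefore verified
  where it is mathematically guaranteed: when the scored set is itself drawn
  from the randomization distribution, observed and null distances are
  exchangeable, and p-values must be uniform. Because distinct sets can tie
  exactly on the averaged distance and the strict convention counts ties as
  "not less" (slightly conservative), the exact uniformity statement holds
  for the tie-randomized value `(count_less + U)/(N+1)`, `U` uniform on
  `{0..count_eq}`; the test suite checks that, over 200 fully independent
  (module, disease) pairs on fresh 500-node graphs at N = 100, with a KS
  test at the 0.01 level, and that the strict `p_emp` never exceeds it on
  average.

## Pulldown interactor calling

Input is a post-search, FDR-filtered peptide table (experiment, condition
∈ {S, AS, B}, protein, peptide, uniqueness flag, MS1 AUC). Spectrum
processing, database search and protein grouping happen upstream; the
uniqueness flag is taken as given. Per (experiment, condition, protein):
rows of one peptide sequence are summed first (redundant observations of a
single peptide species, so rollup is invariant to row order and row
splitting), proteins with fewer than two distinct unique peptides are
dropped, and abundance is the arithmetic mean of the top-3 peptide AUCs.
The mean (rather than sum) keeps 2- and 3-peptide proteins on one scale and
matches common top-N label-free practice; a `stat="sum"` switch exists.

Enrichment requires both S/AS > 2 and S/B > 2, strictly — a ratio of
exactly 2.0 fails. A protein quantified in sense but absent (or zero) in a
control gets an infinite ratio: absence from the control is maximal
evidence of sense-specific binding. A pseudo-count floor for the
denominator is available (`floor=`) for users who prefer bounded ratios.
Both filters apply within each experiment; the final set intersects all
experiments (`at_least_k` relaxation available). Proteins absent from the
sense condition are never candidates.

## Paired expression screen

Expression values are linear-scale; log2 is taken after adding an offset
(default 1.0) only when zeros are present. Per transcript the paired
differences `d_i = log2(LPS_i) − log2(control_i)` over donors give
`mean(d)` and residual variance s² (df = n−1). Variances are moderated,
`s̃² = (d0·s0² + (n−1)·s²)/(d0 + n − 1)`, with the prior `(d0, s0²)` fitted
across transcripts by method of moments on log s²: the excess of
`var(log s²)` over the pure chi-square noise `ψ'((n−1)/2)` identifies d0
via a trigamma inversion (Newton), and the mean of log s² then identifies
s0². When the observed spread is no wider than chi-square noise, d0 = ∞ and
all variances pool. The statistic `t = mean(d)/(s̃/√n)` is referred to a t
distribution with `n − 1 + d0` degrees of freedom. This is a deliberately
simplified, fully specified moderated test in the empirical-Bayes
linear-model tradition; it is not a reimplementation of any specific
package, and hit lists on real data may differ slightly from pipelines that
use a different prior fit.

P-values are BH-adjusted (step-up, via statsmodels, cross-checked in the
tests against a hand-written oracle). Hits satisfy `q < 0.05` (strict) and
linear fold change `2^mean(d) ≥ 2` (boundary included), screening
up-regulation by default (`direction="both"` uses `max(FC, 1/FC)`).
Fold change is `2^(mean log2 difference)`, not a ratio of linear means.

Row Z-scores standardize each transcript across samples with the sample
(n−1) standard deviation; constant rows are returned as zeros and flagged.

Positional classification uses 0-based half-open intervals (GFF3 input is
converted on read): no coding-gene overlap → intergenic; same-strand
overlap touching any coding exon → exon-sense overlapping; same-strand
overlap confined to introns → intron-sense overlapping; opposite-strand
overlap only → antisense. Same-strand classes take precedence when both
strands overlap.

## Synthetic data

Generators are pure functions of their parameters and seed. Defaults are
chosen once to emulate the study designs the analyses assume:

* **Interactome**: preferential attachment (m = 3) for heavy-tailed
  degrees; Erdős–Rényi and configuration models available. The largest
  connected component is returned.
* **Disease planting**: genes drawn without replacement with weight
  `exp(−closeness · d(gene, module))`; closeness 0 is the uniform null,
  closeness 2 with 20 genes is the standard recovery setting.
* **Pulldown**: 200 proteins with 2–8 unique peptides, log-normal base AUCs
  (log-mean 13, σ 1.2) shared across conditions, per-observation log2 noise
  sd 0.2; 3 planted interactors at 4-fold sense enrichment (three is the
  number of interactors such experiments typically confirm); 5
  single-peptide decoys at 100-fold enrichment that the two-peptide rule
  must always exclude; a few non-unique peptide rows that must be ignored.
* **Expression**: 1,000 transcripts × 4 donors, baseline log2 intensity
  Normal(8, 1.5), per-(transcript, donor) effect sd 0.3 (cancels in the
  paired differences), i.i.d. noise sd 0.25, planted transcripts gaining
  log2 effect 2.0 in LPS samples.
* **Annotation**: one toy chromosome with 7 intergenic, 2 antisense, 1
  intron-sense and 1 exon-sense lncRNA over two-exon coding genes — the
  composition of a typical LPS-screen hit list.

What the generators do not emulate: real interactome topology beyond degree
heavy-tails (no community structure or literature bias), MS instrument
noise physics, peptide detectability or missingness patterns, and
microarray probe effects or normalization artifacts. Passing tests
demonstrate the statistics behave correctly under their stated assumptions,
not that those assumptions hold for any particular real dataset.

## Problem sizes and numerics

The test and acceptance runs use 500–2,000-node graphs, N = 100–250
randomizations, 100-replicate operating-characteristic loops, and 1,000
small graphs for brute-force oracle comparison — sizes at which every
property is measurable in seconds while leaving the statistics
non-trivial. Degenerate cases are defined explicitly: zero-variance null
distributions yield an undefined z-score (`ptp == 0`, robust to float
rounding of identical values), constant expression rows are flagged rather
than divided by zero, and an all-zero-variance screen falls back to p = 1
for zero differences.
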