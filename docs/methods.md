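# Methods

`clonoscope` implements the bespoke statistics of a joint CRISPR-perturbation +
lineage-barcoding single-cell experiment: clone calling from barcode reads,
clonal fate-composition and lineage-coupling statistics with resampling nulls,
Poisson compositional regression, a balanced logistic IN/PN fate classifier,
and ChIP-peak promoter/enhancer annotation. This note records the models, the
parameters that matter, and the design choices made where the design was open.

## Clone calling from barcode reads

A lineage barcode is a 37-bp synthetic oligonucleotide in which random
stretches are bridged by fixed bases (`BarcodeLayout`; default
8N–TGCA–9N–GATC–8N–CTAG, configurable because real library builds differ).
Reads carry the cassette between constant 5'/3' anchors; extraction scans the
first `max_anchor_offset` positions for the 5' anchor within
`anchor_mismatch_tol` substitutions (default 1), takes the following 37 bases,
and verifies the 3' anchor.

Filtering keeps barcodes whose **mean** Phred over the 37 bases is ≥ 30
(`min` mode available; the protocol specifies only "a quality score of 30 or
higher", so the statistic is a documented choice). UMIs collapse PCR-jackpot
duplicates to one molecule per (cell, barcode, UMI).

Sequencing errors are absorbed by single-linkage clustering: clusters are
connected components of the graph joining barcode pairs at Hamming distance
≤ d (default d = 3). Single linkage was chosen over centroid clustering
because it gives "cluster distance" an exact graph semantics with a
brute-force oracle, and because a library with pairwise separation
≥ 2d + 1 = 7 (the generator's default) provably cannot merge two true
barcodes. Cluster ids are the lexicographically smallest member, making the
mapping input-order invariant.

Cells become clones as connected components of the bipartite cell ↔
barcode-cluster graph within each batch: cells sharing any cluster are one
clone, and a cell carrying two clusters merges them. Multi-barcode handling is
our documented choice (the underlying protocol paper is not restated here).
Clone ids are scoped per batch so identical library barcodes electroporated
into different embryos are kept distinct (collision guard). `min_umi`
(default 1) drops weakly supported cell–cluster pairs; dropped cells are
listed in the QC report, never silently discarded.

## Clonal intersections and sizes

Cluster annotations are merged into broad classes (mitotic / PN / IN, with an
optional MGE/CGE sub-split of INs) through a total `ClassMap`; an unmapped
annotation is an error. Each clone is characterized by the exact set of
classes its cells occupy — an {IN, PN} clone counts under {IN, PN}, not under
{IN} — and per-arm proportions divide by the total clone count of that arm, so
proportions sum to 1 per arm. "Multicell" means clone size ≥ 2. Batches are
pooled by default; per-batch means are also emitted because the pooling
convention of published UpSet panels is typically unstated.

## Lineage coupling

For states i, j the observed matrix counts clones with ≥ 1 cell in both:
O_ij = #{clones present in i and j}, with the diagonal O_ii = #{clones present
in i} (a strict mode excluding the diagonal from the marginals is provided).
The expectation under no coupling is the contingency-table independence
reading

    E_ij = (Σ_k O_ik)(Σ_k O_kj) / Σ_kl O_kl ,

the unique marginal-product form that conserves the grand total and maps a
uniform O onto itself. Stability comes from resampling: 1,000 trials each
recompute O/E on a random 25% of clones without replacement; the score is the
median ratio over a pair's valid trials (trials with E = 0 for that pair are
excluded and counted). The empirical p counts trials on the wrong side of 1
for the pair's coupling direction, with a pseudo-count, p = (k+1)/(n_valid+1),
so p is never 0; trials at exactly 1 count as wrong-side for both directions,
since a ratio of 1 is by definition coupling at random expectation.
Benjamini–Hochberg runs over the off-diagonal pairs.

**Known bias.** With the incidence diagonal, a fully independent assignment of
states to clones at per-clone presence probability p gives off-diagonal
expectation ratio k·p/(1 + (k−1)p) for k equally likely states — below 1
unless presence is high. The subsampling p-value measures *direction
consistency*, so it will flag this structural offset as negative coupling when
states are sparse and few. Interpretation should therefore compare pairs
against each other, and calibration checks in this package use well-sampled
clones (12–25 cells over 3 states, per-state presence ≥ 0.99), where the
offset is negligible: there the null is calibrated (scores 0.98–1.02, q > 0.05
in 20/20 seeds) and a pair co-occurring at 3× the independence rate at
presence 0.3 is detected in 20/20 seeds.

## Compositional Poisson regression

Per cell type, counts per (batch, arm) follow

    log E[count] = β0 + β_arm + β_batch + log(total cells in batch × arm),

a Poisson GLM whose exposure offset makes β_arm the log ratio of the cell
type's *proportion* between arms, immune to arm-level capture differences
(the cited helper's offset is not restated in the paper; without one,
capture-depth differences confound composition). Wald p-values (fast;
single-parameter hypotheses on moderate counts) are BH-corrected across cell
types. A cell type with zero cells in one arm has no finite MLE (separation)
and is flagged `unstable` with NaN effect rather than being fit on
pseudo-data. The companion `log_ratio_composition` reports
log10((prop_perturbed + pseudo)/(prop_control + pseudo)) pooled over batches.
Module-score effects use OLS, score ~ arm + batch + n_genes, per module and
non-control arm, Bonferroni-corrected across module × arm tests; constant
scores are flagged degenerate (effect 0, p 1).

## IN/PN fate classifier

Raw counts are depth-normalized to the median cell total, log1p-transformed,
restricted to the 3,000 most variable genes (variance of the normalized
values, ties broken by gene id), class-balanced by downsampling the majority
class, split two-thirds train / one-third validation (stratified), and
standardized per gene on the training cells. The classifier is L1-penalized
logistic regression with the penalty chosen by 3-fold cross-validation over 8
candidate strengths on the training split (lasso is the default of the
standard binomial elastic-net solvers this mirrors); accuracy is reported on
the held-out third. The balancing and split use one globally shuffled order,
so swapping the class labels provably mirrors the model (coefficients negate).
Gene fate scores are the sigmoid of the signed coefficient — 0.5 means
uninformative, > 0.5 PN-predictive, < 0.5 IN-predictive — reproducing the
published [0, 1] coefficient scale while raw coefficients remain available.

## Peak annotation

All coordinates are BED-style 0-based half-open. Peak anchors are summits when
present (the summit is the binding-site estimate), else midpoints. Nearest-TSS
distances are signed by the gene's strand (negative = upstream); ties break
toward the lexicographically smallest TSS id. Promoter assignment uses the
half-open window [TSS − w, TSS + w) with w = 5,000 bp by default: the source
text says both "within 5 kb of a TSS" and "~5 kb region around a TSS" (which
could mean ±2.5 kb), so the wider reading is the default and w is
configurable. Overlap classification is any-overlap (≥ 1 bp) and a-site
centric, so "shared / total a-sites" fractions are well defined under
one-to-many overlaps. Enrichment on the 3×2 (site class × enhancer overlap)
table is Pearson's Chi² without continuity correction (dof = 2). Target genes
are the union of promoter-assigned genes and genes linked to any overlapped
enhancer; the global list is deduplicated and sorted, and adding an enhancer
link can only grow it.

## Synthetic data generator

The generator emulates the statistical structure of the motivating
experiment; its defaults are the study conditions used throughout the tests.

- Two arms ("gLacZ" control, "gMeis2" perturbed), 2 batches, 150 progenitor
  clones per batch per arm; clone sizes from a decreasing law
  {1: 0.45, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05} (sparse electroporation:
  singletons dominate, mean ≈ 2 recovered cells).
- Control class probabilities mitotic 0.20, PN 0.50, IN-MGE 0.15, IN-CGE 0.15
  (PN-rich LGE-proximal sampling); the perturbed arm moves δ = 0.15 of PN mass
  to the IN classes, split equally, acting on whole newly generated clones —
  the clone-level reading of fate switching. δ is validated against
  0 ≤ δ ≤ P(PN).
- Reads: 20 per cell, 5 UMIs per cell pool (jackpotting by construction),
  per-base substitution error 0.005 on the barcode (substitutions only by
  default — keeps the fixed-length Hamming model exact), Phred ~ N(36, 4)
  clipped to [2, 41].
- Expression: 3,000 genes, gamma–Poisson counts (dispersion 1/10), 50
  informative genes at |log2FC| = 2 between PN and IN split symmetrically
  around a lognormal base mean; mitotic cells sit at base.
- Determinism: one root seed; each component draws from
  `default_rng([seed, stream])` with a fixed stream counter per component, so
  reruns are bitwise identical and components can be regenerated
  independently.

Dedicated state-level generators serve the coupling statistics:
`simulate_multistate_clones` (cells iid over states — the no-coupling null)
and `simulate_clone_states` (per-clone Bernoulli presence with an exact-
marginal coupled-pair mixture, so a (A, B, factor) entry co-occurs at exactly
factor × the independence rate).

Not emulated: ambient RNA, doublets, cell-cycle structure, indel errors
(optional mode deliberately omitted from defaults), cell-barcode whitelists,
alignment artifacts. Passing tests therefore demonstrate correctness of the
statistics under clean clonal structure, not robustness to those artifacts.

## Numerical choices

- Probability vectors validated to sum to 1 within 1e-12.
- Expected matrices computed in double precision; the oracle agreement
  tolerance is 1e-12 on 5×5 count matrices.
- Median coupling scores use only a pair's valid trials; a pair with zero
  valid trials reports NaN with n_valid_trials = 0.
- Library generation is rejection sampling with an explicit rejection budget
  (default 10,000 consecutive failures) — unsatisfiable requests fail loudly.
- Clustering ids, clone ids, gene tie-breaks, and intersection labels are all
  lexicographic, so every table is reproducible and order-invariant.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: 100–200
oracle instances per interval/matrix operation, 20 seeds × 1,000 resampling
trials for coupling calibration and power, 200 null simulations for type-I
error, 50 seeds for effect-sign recovery, and one ~2,000-cell × 3,000-gene
classifier fit. These sizes give the binomial assertions stated in the tests
comfortable margins while keeping a full run in well under five minutes.
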