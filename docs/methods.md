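# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `isocorde`.

## Normalization

Isoform-level quantification of full-length single-cell libraries shows a
strong length bias, which the pipeline removes with

    y_ij = c_ij / ( (1e-6 · Σ_i c_ij) · sqrt(1e-3 · l_i) )

where c_ij are estimated counts, l_i the isoform's effective length in
bases, and the sum runs over all isoforms in the matrix. An isoform of
length 1000 nt reduces exactly to counts per million; the square root keeps
the correction mild for long isoforms. The library size is taken *before*
feature filtering (the full library is the depth of the cell); this is a
deliberate choice — the alternative (post-filter library) rescales all cells
by a near-constant factor and barely changes correlations, but the
convention must be fixed for reproducibility. Zero-length or missing
lengths are a hard error rather than a silent fallback.

## Percentile correlation

Cells of the same type are treated as replicate draws from the type's
expression distribution. For each isoform and each of the K cell types we
compute p+1 quantiles at probabilities 0, 1/p, …, 1 (linear interpolation
between order statistics — the default estimator in scientific software;
the data do not determine a better choice and the estimator must be pinned).
With the default p = 10 each type contributes 11 values spanning the type
minimum to maximum; the percentile correlation of two isoforms is the
Pearson correlation of their concatenated K·(p+1) vectors. It is invariant
to permuting cells within a type (only per-type multisets matter) and to
per-isoform positive affine rescaling (Pearson invariance).

Degenerate cases: a zero-variance profile (isoform constant everywhere)
would leave Pearson undefined; its correlations are set to 0 (with a
warning) rather than NA so clustering distances stay defined. `p = 1`
yields the two-point min/max summary; the one-value-per-type "median only"
mode is exposed separately (`summary="median_only"`) because collapsing a
type to its median demonstrably disrupts the correlation distribution
(see the stability paragraph under Limitations).

The four comparison metrics are computed on the same normalized matrix used
for the percentile profiles, for comparability (the choice of input is
configurable): Pearson and Spearman per cell; zero-inflated Kendall as
Pimentel's τ* = p11²·τ11 + 2(p00·p11 − p01·p10) with τ11 the classical
tau-b over cells where both isoforms are positive; and the proportionality
measure ρ = 2·cov(log x̃, log ỹ) / (var log x̃ + var log ỹ) with pseudocount
1 on the values before the log (zeros retained). With pseudocount the ρ of
exactly proportional vectors is slightly below 1; for count magnitudes in
the tens it exceeds 0.99.

## Clustering

Correlations are mapped to distances by d = 1 − r for r > 0 and d = 1
otherwise: negative correlations are floored because the method targets
positive co-expression only, and nothing is ever merged on anticorrelation.
Trees are average-linkage (scipy).

**Dynamic cut.** The hybrid tree-cut contract is implemented directly: the
tree is first cut at 0.99 × the maximum merge height; components smaller
than the minimum cluster size are left unassigned (the PAM-like forced
reassignment stage is intentionally not provided — the pipeline always
disables it). Each remaining component is then split recursively at its top
merge whenever (a) both sub-branches hold at least `min_cluster_size`
leaves and (b) the relative height gap (branch height − taller child
height)/branch height exceeds a threshold that decreases with `deep_split`:
0.25, 0.15, 0.10, 0.05, 0 for deep_split = 0…4. Because a split permitted
at some deep_split is permitted at every larger one, the number of clusters
is non-decreasing in deep_split, and no emitted cluster can be smaller than
the minimum size. Over-splitting at deep_split = 4 is by design: the
refinement stages (and, in the benchmark, merging to a fixed cluster count)
reunite shards, mirroring the many-small-clusters-then-merge behaviour of
the published pipeline settings.

**Refinement.** Metatranscripts are the mean of member profiles after
min-max scaling each member to [0, 1], so highly expressed isoforms do not
dominate; correlation of a candidate isoform with a metatranscript is plain
Pearson and therefore insensitive to the candidate's own scale. The QC
filter (entry composition, single pass — iterative re-evaluation would make
the result order-dependent) moves a member to the unclustered group when it
has ≥ 3 within-cluster partners with r < 0.85 (first pass) or ≥ 10 partners
with r < 0.7 (second pass). Expansion assigns an unclustered isoform to the
maximally correlated cluster among those with r ≥ 0.9; ties resolve to the
highest correlation and then the lowest cluster label (all tie-breaks in
the package resolve to the lowest label). Merging clusters uses the
metatranscript correlation distance with a constant-height cut at 0.1
(manual merge lists are accepted as an override); the final merge after
recursive assignment defaults to the same height. Recursive assignment
lowers the threshold 0.9 → 0.8 → 0.7, recomputing metatranscripts after
every change, and finally force-assigns any stragglers by maximum
correlation, so it terminates with an empty unclustered set.

## Differential expression

Each isoform is tested for any between-type difference with an NB GLM (log
link): full model with K − 1 type dummies versus intercept only,
likelihood-ratio χ² with K − 1 df. The dispersion is a per-isoform
within-type method-of-moments estimate (cell-number weighted, floored at
1e-8); a fixed θ can be supplied. A per-observation weight vector is
accepted so externally estimated zero-inflation weights can be injected —
weight estimation itself is not part of the package. The response is raw
counts (the NB likelihood requires counts); the normalized values feed only
correlation and clustering. Under a matched NB null (240 cells, 4 types,
1000 features) the empirical size at α = 0.05 is ≈ 0.047.

The consensus procedure downsamples over-represented cell types (without
replacement, per-run seed), re-applies the detection filter (≥ 25% non-zero
cells in at least one type — zeros grow more abundant after downsampling),
tests, and repeats R = 50 times; multiple test engines can be configured
and their per-run DE sets are unioned. The consensus keeps isoforms
significant (BH FDR < 0.05 within each run) in ≥ ⌈0.5·R⌉ runs (inclusive).
Agreement is summarized as mean ± sd of the Jaccard index over all C(R,2)
run pairs; two empty DE sets have Jaccard 1 (they agree perfectly).

## coDIU model

For a candidate gene pair (≥ 2 shared clusters; one representative isoform
per gene per shared cluster, chosen as the highest-mean-expression isoform
when a gene has several in one cluster) the isoform count vectors are
stacked into a response z of length Σ_g I_g·N (4N for two genes × two
clusters) and modelled with a fixed-dispersion NB GLM (log link, θ = 10,
configurable; no offset by default — a log-library offset is available).
The design contains gene, cluster and cell-type main effects, the
gene × cluster interaction, and the two tested interactions. Type-II
likelihood-ratio tests drop one interaction at a time while keeping all
main effects and the other interaction; degrees of freedom are
(K − 1)(C − 1) for cluster × type and K − 1 for gene × type. Pairs with
more than two shared clusters enter with C − 1 cluster dummies. The two
interaction p-value families are BH-adjusted separately; a pair is positive
when cluster × type FDR < 0.05 *and* gene × type FDR > 0.05, and a gene is
called coDIU when positive in at least one pair. Non-converging fits are
flagged and excluded from the BH families.

The cluster-level network has clusters as nodes and, as edge weights, the
number of distinct coDIU genes whose positive pairs share both clusters.
The cell-type co-usage summary needs a notion of where a cluster "peaks":
a cluster is taken to peak in the cell types whose per-type metatranscript
mean exceeds the across-type mean + 1 sd (falling back to the single
highest type). This is a heuristic — the mapping from clusters to peak
types is not uniquely determined by the model — and is documented as such.

## Synthetic data generator

The generator defines the study conditions used throughout the tests and
the acceptance script.

**Base counts** are gamma-Poisson: per-feature baseline mean ~
Gamma(shape 2, scale 5); per-(feature, type) multiplicative effect ~
LogNormal(0, 1.5), giving every cell type its own expression ranking of the
features; per-cell library factor ~ LogNormal(0, 0.2); NB dispersion 0.3;
3% of features boosted 5× as high-expression outliers. Defaults: 1000
cells split evenly over 8 types, 8000 features. Sparsity (≈ 12% zeros in
the base matrix, ≈ 43% in the module dataset) comes from the long lower
tail of the per-(feature, type) means; sequencing-protocol noise models
(capture efficiency, amplification, read depth) are deliberately out of
scope — the generator emulates expression structure, not a specific
protocol.

**Planted modules.** Fifteen binary peak profiles over the 8 types — five
modules peaking in 1 type, five in 2, five in 3 — are placed greedily on
the least-loaded types, with two constraints: no type peaks in more than 6
modules, and (a generator design choice) a new peak set shares at most one
type with every earlier one, because near-subset peak sets are
near-collinear profiles and would make the planted modules unidentifiable
in principle. Within each cell type, features are ranked by mean
expression; the top 1400 and bottom 1400 form high/low pools of per-type
count vectors. Each module receives 200 synthetic features whose per-type
blocks are drawn without replacement from the high pool in peaking types
and the low pool elsewhere (pools reshuffle and recycle with a warning when
exhausted — the low pools must serve more than 7 modules). Drawn vectors
are rank-matched within a module: the j-th synthetic feature receives the
j-th strongest drawn vector in every type, so one feature's peak
magnitudes are mutually consistent; without this, the wide dynamic range of
the pools makes multi-peak members mutually dissimilar and the refinement
filter removes the majority of them. Because vectors are moved between
features, never altered, the per-type count structure of the base
simulation is preserved exactly.

**Refinement** computes each module's median profile over cells (median
across members, per cell, once on entry) and drops members whose cell-level
Pearson correlation with it is below 0.75. Under the defaults ≥ 98% of
members survive per module. Determinism: the base simulation and the module
construction take seeds derived from one user seed; every pipeline stage is
deterministic given its inputs.

**What the generator does not emulate.** Modules are built from permuted
real(istic) count vectors, so within-type marginals are faithful, but
cross-feature dependence within a type is destroyed except through the
planted structure; there is no doublet/ambient contamination, no
batch/protocol effects, and no gene structure linking isoforms (each
synthetic feature is its own gene — coDIU recovery is therefore exercised
on purpose-built constructions, not on the module dataset). Passing tests
on these data show the pipeline recovers strong, cleanly planted
cell-type-level co-expression; they do not certify performance on subtler
real-data structure.

## Benchmark harness

For each metric the harness clusters the simulated features with the
automated variant (dynamic cut at min size 10, deep split 4, no QC, no
re-assignment; metatranscript merging cut by *cluster count* to exactly the
simulated module count — the fixed count replaces a manual height choice
and makes metrics comparable), then reports: the fraction of within-cluster
pairwise metric values above 0.8 (singletons report NaN), the per-module
Jaccard between each simulated module and its best-matching calculated
cluster (matched by metatranscript correlation, ties to the lowest label,
many-to-one allowed; computed before expansion, so unclustered features
count against agreement), and the unclustered percentage before and after
a single expansion pass at r ≥ 0.9 (the benchmark uses one pass, not the
recursive schedule; expansion is percentile-based for every metric since
metatranscripts live in profile space). Intra/inter-module distribution
overlap is quantified by the overlapping coefficient (shared histogram
mass, 100 bins on [−1, 1]).

At the default effect sizes all five metrics separate the planted modules
almost perfectly, so the cross-metric comparison is reported as ranking
properties (percentile ≥ rank-based metrics) rather than as exact values.

## Problem sizes in the test suite

The suite exercises the full default conditions (1000 cells, 8000 base
features, 15 × 200 modules) for the headline checks, and scaled-down
versions of the same construction (240–400 cells, 20–40 features per
module) for properties that require many model fits or O(n²·N) metrics
(null calibrations: 1000 features; coDIU null: 500 pairs; five-metric
comparison: 40 features per module). These sizes are the package's own
choices for routine validation; all thresholds are unchanged from the
defaults above.

## Known limitations

* The p-count stability of percentile correlations is asymmetric in the
  data's sparsity: on the default simulation the mean absolute difference
  between p = 4 and p = 100 correlations is ≈ 0.057, concentrated entirely
  in near-zero inter-module pairs whose summaries are dominated by the
  block maximum (pairs with r > 0.9 move by < 0.01). Median-only
  summarization is twice as disruptive (≈ 0.11). Clustering at p = 10 is
  unaffected.
* The dynamic cut is a contract-faithful re-implementation, not a port of
  the published hybrid algorithm; per-branch decisions use the relative
  height gap rather than the original core-scatter criteria. The PAM stage
  is not implemented.
* coDIU fits assume a common fixed θ across isoforms and cells; strongly
  misspecified dispersion inflates or deflates both interaction tests
  together.
* The cell-type peak heuristic (mean + 1 sd) for the co-usage summary is a
  convention, not an inference.
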