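# isocorde

Isoform co-expression networks and co-differential isoform usage (coDIU)
from single-cell RNA-seq counts.

## The problem

Alternative splicing gives most genes several transcript isoforms, and cell
types differ not only in which genes they express but in *which isoform of a
gene* they use. Detecting coordinated isoform choices across genes from
single-cell data is hard: isoform-level counts are sparse and bursty, so
per-cell correlation metrics (Pearson, Spearman, zero-inflated Kendall,
proportionality) under-estimate co-expression. `isocorde` implements a
cell-type-aware pipeline for this problem:

1. **Percentile correlation.** Within each of the K cell types, an isoform's
   expression across that type's cells is summarized by p+1 quantiles
   (default p = 10, i.e. 11 values from the type minimum to maximum).
   Pearson correlation between isoforms is computed over the concatenated
   K·(p+1) summary vectors instead of over cells — treating cells of a type
   as replicates drawn from the type's expression distribution.
2. **Semi-automated clustering.** Correlations become distances
   (d = 1 − r for r > 0, else 1), average-linkage trees are cut with an
   adaptive per-branch dynamic procedure (minimum cluster size, unassigned
   leaves allowed), and clusters are refined: correlation QC, metatranscript
   (mean of min-max-scaled member profiles) expansion at r ≥ 0.9, profile
   merging at height 0.1, and recursive assignment at thresholds
   0.9 → 0.8 → 0.7.
3. **DIU / coDIU.** A gene shows differential isoform usage when ≥ 2 of its
   isoforms land in different clusters. Two genes show *co*-differential
   isoform usage when their isoforms share ≥ 2 clusters and a stacked
   negative-binomial GLM (log link, θ = 10) on the 4N-long response confirms
   a significant cluster × cell-type interaction with a non-significant
   gene × cell-type interaction (type-II likelihood-ratio tests, BH per
   interaction family).

Multi-group differential expression uses an NB GLM likelihood-ratio test
(χ², K − 1 df) with a downsampling consensus to balance cell-type sizes, and
a built-in simulator plants known co-expression modules (15 modules × 200
synthetic features over 8 cell types by default) to validate every stage.

## Worked example

```python
import numpy as np
from isocorde import simulate_dataset, evaluate_metric

# scaled-down study conditions: 8 cell types, 400 cells, 15 planted modules
ds = simulate_dataset(n_cells=400, n_features=2000, per_module=40,
                      top_n=280, seed=3)
print(f"{ds.matrix.n_isoforms} synthetic features in "
      f"{len(set(ds.modules.values()))} modules")

report = evaluate_metric(ds, "percentile")
print(f"clusters: {report.n_clusters}")
print(f"mean simulated-vs-calculated Jaccard: {report.jaccard_mean:.3f}")
print(f"unclustered before/after expansion: "
      f"{report.pct_unclustered_before:.1f}% / {report.pct_unclustered_after:.1f}%")
```

prints

```
597 synthetic features in 15 modules
clusters: 15
mean simulated-vs-calculated Jaccard: 1.000
unclustered before/after expansion: 0.0% / 0.0%
```

i.e. the refinement filter kept 597 of the 600 planted features, the
automated clustering forced to the simulated module count recovered the 15
planted modules essentially perfectly, and one metatranscript-expansion pass
assigned every feature to a cluster.

The same stages are available from the shell:

```
isocorde simulate --cells 1000 --features 8000 --seed 7 --out sim/
isocorde preprocess --counts sim/ --min-detect 0.25 --out pre/
isocorde correlate --counts pre/ --metric percentile --p 10 --out corr.tsv
isocorde cluster --counts pre/ --min-size 20 --out clusters/
isocorde codiu --counts pre/ --assignment clusters/assignment.tsv --out codiu/
isocorde run --config config.yaml --out results/
```

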