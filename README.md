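# methylsubtypes

Feature selection and multi-class classification of cancer subtypes from
Illumina 450K DNA-methylation beta values, with a synthetic-cohort generator
so the entire pipeline is testable without any download.

## The problem

Breast tumors split into intrinsic subtypes (basal, Her2, LumA, LumB) with
distinct methylation patterns, but a 450K array measures ~450,000 CpG probes
for a few hundred patients, and cohorts are heavily imbalanced (LumA
typically dominates). Finding a *small* panel of subtype-discriminative
probes requires aggressive, multi-stage feature selection plus careful
handling of class imbalance. This package implements that analysis as a
reusable pipeline of scikit-learn-style estimators:

1. **Maximum-relevance filter** — each probe *y* is scored by the mutual
   information with the subtype label *x*,

   *I(x, y) = Σ p(x, y) log₂ [p(x, y) / (p(x) p(y))]*,

   estimated by the plug-in formula after discretizing beta values into
   three states at mean ± σ. Probes with more than a threshold (default 0.2
   bits) are retained (`RelevanceFilter`, `mr_filter`).
2. **Monte Carlo Feature Selection (MCFS)** — grow *p·t* entropy decision
   trees over *p* bootstrap sets × *t* random projections of *m* features and
   rank each feature *g* by its relative importance

   *RI_g = Σ_τ (wAcc_τ)ᵘ Σ_{n_g(τ)} IG(n_g(τ)) · (no. in n_g(τ) / no. in τ)ᵛ*,

   where wAcc is the tree's macro-averaged per-class recall on held-out
   (out-of-bag) samples, IG the information gain of a node that splits on
   *g*, and u = v = 1 (`MCFSRanker`, `ri_scores`).
3. **SMOTE balancing** — every minority class is topped up to the majority
   size with convex combinations *z = x + r (y − x)* of a sample and one of
   its k nearest same-class neighbors (`SmoteBalancer`, `balance`).
4. **Incremental feature selection (IFS)** — nested top-k prefixes of the
   ranked list (k = 10, 20, 30, …) are each evaluated by stratified 10-fold
   cross-validation of a one-vs-rest polynomial-kernel SVM (or random
   forest); the prefix with the best multi-class Matthews correlation
   coefficient,

   *MCC = cov(X, Y) / √(cov(X, X) cov(Y, Y))*

   over the prediction/truth indicator matrices, is the optimum feature set
   (`ifs`, `multiclass_mcc`).
5. **Enrichment** — optimum probes map to genes through a 450K-style
   annotation and gene sets are tested by the exact hypergeometric upper
   tail with Benjamini–Hochberg FDR (`enrich`).

A generator (`generate_dataset`) emulates such a cohort: beta values from
Beta distributions, the study's class imbalance (34/37/120/63), a planted
set of informative probes with class-shifted means, and an optional
`lum_proximity` flag that places the two luminal classes close together.
It returns the ground truth, so feature-recovery is directly testable.

## Worked example

Run the full pipeline on a synthetic cohort with confusable luminal
subtypes (config `{seed: 1, lum_proximity: true}`):

```
$ methylsubtypes run-all --config demo.yaml --out demo/
optimum k=50  MCC=0.7512  accuracy=0.8000  significant terms=1
```

`demo/ifs.tsv` holds the IFS curve — performance rises with the number of
features and plateaus once the informative probes are exhausted:

```
 k  accuracy      mcc
10  0.627083 0.540038
20  0.714583 0.640817
30  0.745833 0.681067
40  0.772917 0.714747
50  0.800000 0.751163
59  0.802083 0.751023
```

`demo/confusion_best.tsv` (rows = true class, after balancing to 120 per
class) shows the luminal classes absorbing nearly all of the error — 69 of
120 LumA samples are called LumB — exactly the failure mode the
`lum_proximity` flag plants:

```
           basal  her2  lumA  lumB
basal        120     0     0     0
her2           4   106    10     0
lumA           0     8    43    69
lumB           0     1     4   115
```

Per-class sensitivities were basal 1.000, her2 0.883, lumA 0.358,
lumB 0.958; the one planted gene-set term came out significant
(FDR < 0.05). Without the proximity flag (plain `--seed 1`) the same
pipeline reaches MCC 1.000 at k = 20 of 97 retained probes. Rerun either
command with the same seed and the artifact directory is byte-identical.
A `run-all --exclude-class lumB` mode repeats the whole sweep on the three
remaining subtypes.

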