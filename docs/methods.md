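# Methods

## Pipeline overview

The package classifies tumor samples into intrinsic subtypes from 450K
methylation beta values and extracts a compact discriminative probe panel.
Stages run in a fixed order: relevance filter → MCFS ranking → SMOTE
balancing → incremental feature selection (IFS) under cross-validation →
gene-set enrichment. The filter runs *before* MCFS so the Monte Carlo stage
ranks only probes that carry label information; each stage persists its
artifact so any stage can also be run standalone from the CLI.

## Mutual-information relevance (stage 1)

The relevance score of a probe is the plug-in mutual information, in bits,
between the subtype label and the probe's discretized beta values. The
estimator is fully specified by two conventions that the score's magnitude
depends on, both configurable:

- **Discretization**: three states at mean ± w·σ per probe, w = 1 (the mRMR
  program's convention). A constant probe lands entirely in the middle state
  and scores exactly 0.
- **Log base 2**, so the retention threshold (default 0.2, strict `>`) is in
  bits.

Because any such score is estimator-dependent, the retained-probe *count* on
a given dataset is meaningful only relative to these conventions. The
plug-in estimate has a positive bias of roughly
(|states|−1)(|classes|−1)/(2·n·ln 2) ≈ 0.017 bits at n = 254 samples, which
is why a null probe does not score exactly zero; the default threshold sits
well above this floor. Ties in the retained ordering break lexicographically
by probe id.

## Monte Carlo Feature Selection (stage 2)

RI_g sums, over all p·t trees, each tree's contribution
(wAcc)ᵘ · IG(node) · (n_node/n_root)ᵛ for every node splitting on g.
Choices:

- **Trees**: CART-style binary splits on single features, entropy criterion
  (IG in bits), split thresholds at midpoints between sorted distinct
  values; growth stops on pure nodes, a `min_leaf` floor (default 2), or no
  positive-gain split. Trees are scorers, not predictors, so there is no
  pruning. The trees are grown by scikit-learn's
  `DecisionTreeClassifier(criterion="entropy")`; per-node gain, sample
  counts and class counts are extracted from the fitted tree into the
  package's own node structure, on which the RI accumulation operates (a
  brute-force split-search oracle in the tests confirms the extracted
  splits and gains).
- **Held-out evaluation**: wAcc is the macro-averaged per-class recall on
  the bootstrap's out-of-bag samples — the zero-extra-data choice. A
  `holdout="split"` alternative (bootstrap split 2:1 into train/eval, as the
  reference MCFS implementation does) is available in the config.
- **Defaults** p = 20, t = 50, m = ⌈0.05·M⌉, u = v = 1. p·t = 1000 trees
  rank a few-hundred-probe panel in seconds on one core; stability of the
  ranking grows with p·t (checked as a property test via Spearman
  correlation between independent runs).

Exponents u = v = 1 weight every split by the full tree accuracy and the
node's sample fraction; features never chosen by any split have RI exactly 0.

## SMOTE (stage 3)

Balancing happens **after** the relevance filter, so nearest-neighbor
distances (Euclidean) are computed over the retained probes — distances over
all 450K dimensions would be dominated by uninformative noise. Neighbors are
searched within the class only; k (default 5) is capped at class size − 1,
and a class of one sample is an error. Synthetic samples are convex
combinations of same-class points, hence stay within [0,1] and within the
class's bounding box; originals are never modified and are flagged.

Two evaluation modes exist because oversampling-then-cross-validating leaks
synthetic copies of test information into training folds:

- **default**: balance the full dataset once, before CV. The per-class
  metrics are then computed on the augmented cohort; a companion confusion
  matrix restricted to the original samples is emitted alongside
  (`confusion_best_original.tsv`), so both readings are always available.
- **`leak_free: true`**: balance inside each training fold only; test folds
  contain only original samples. This is the statistically sound estimate
  and the recommended mode for new analyses.

## Classifier evaluation (stage 4)

- **One-vs-rest SVM**, polynomial kernel (default degree 1, C = 1): one
  binary SVC per class; a sample gets the class with the highest binary
  score. The default per-class score is the uncalibrated decision value;
  `score_mode: probability` switches to Platt-calibrated probabilities
  (sigmoid calibration with an internal CV). On well-separated binary
  margins the argmax of the two coincides; the decision route avoids the
  calibration's extra cost and randomness, which is why it is the default.
  Exact score ties break toward the class with more training samples, then
  lexicographically.
- **Random forest** alternative (default 100 trees, seeded).
- **Cross-validation** is stratified 10-fold (plain label-blind folds would
  often leave a minority class absent from a fold at these class sizes);
  every sample is predicted exactly once and one confusion matrix is
  accumulated over folds. A class smaller than the fold count is an error.
- **Metrics**: per-class sensitivity TP/(TP+FN) and specificity
  TN/(TN+FP), overall accuracy, and the multi-class MCC computed from the
  column-centered indicator-matrix covariances. MCC is defined as 0 when
  either covariance is degenerate (e.g. a constant prediction). This
  statistic is algebraically the R_K correlation; the test suite checks it
  against scikit-learn's independent confusion-matrix implementation.
- **IFS** sweeps k = step, 2·step, … (step 10) up to the ranked-list length,
  including a final partial prefix; `max_k` caps the sweep. The optimum is
  the max-MCC prefix, ties resolved toward the smaller k (parsimony).

## Enrichment (stage 5)

Optimum probes map to the union of their annotated gene symbols
(semicolon-split, deduplicated; unannotated probes contribute nothing). Each
term is tested by the exact hypergeometric upper tail P(X ≥ k) within a
finite universe; p-values are BH-adjusted and significance is FDR < 0.05
strictly. The default universe is the set of genes annotated on the
*analyzed* (relevance-retained) probe set, not the whole genome — the test
should condition on what was measured and screened; pass an explicit
universe to override.

## Synthetic cohort generator

The generator emulates the structure of a four-subtype 450K cohort:

- **Class sizes** default to 34 basal / 37 Her2 / 120 LumA / 63 LumB
  (the imbalance of the motivating cohort; Σ = 254).
- **Beta values** are drawn per probe from Beta(α, β) parameterized by
  (mean, concentration), respecting the [0,1] support. Noise probes share
  one distribution across classes (baseline mean ~ U(0.15, 0.85)).
- **Informative probes** (default 100 of 2000) add equally spaced per-class
  offsets spanning ±effect/2 (default effect 0.35) to the baseline,
  clipped into [0.02, 0.98], with the class→offset assignment permuted per
  probe so no class is systematically hyper-methylated.
- **Dispersion** (concentration α+β) defaults to 10, i.e. a within-class
  s.d. of ≈0.15 at mean 0.5. This matches the within-subtype heterogeneity
  of *variable* CpGs in tumor cohorts and keeps few-feature classifiers
  imperfect, the regime the real analysis operates in; at concentrations
  several-fold higher the synthetic task becomes trivially separable and no
  longer exercises the feature-selection trade-offs.
- **`lum_proximity`** places the lumB offset at 0.3 of the inter-class
  spacing from lumA's, reproducing the luminal-vs-luminal confusability seen
  in practice (under this flag the lowest per-class sensitivity lands on a
  luminal class — asserted as a rank property in the tests).

What the generator does **not** emulate: probe-probe spatial correlation
along the genome, probe-type (Infinium I/II) effects, batch effects, missing
values, and real CpG identifiers beyond the `cg`+digits format. Passing
recovery tests on this generator therefore demonstrates correctness of the
selection machinery under the assumed statistical structure, not performance
on real arrays.

The matching annotation generator assigns each probe 0–2 gene symbols (with
occasional duplicates, as in the real manifest) and parallel region tags;
the gene-set generator can plant one term overlapping a given hit list at a
configurable rate so enrichment recovery is testable.

## Determinism and problem sizes

All stage RNGs derive from one master seed via `SeedSequence.spawn`, and the
run manifest contains no timestamps or absolute paths, so two `run-all`
invocations with the same config are byte-identical. Numeric artifacts are
serialized with `repr`, making write→read round-trips lossless.

Default problem sizes (2000 probes, 254 samples, 1000 MCFS trees, IFS over
~100 retained probes under 10-fold CV) complete in a few seconds on one
core; the recovery simulations in the test suite (500 probes × 10 seeds,
1000 trees each) run in about a minute. These sizes were chosen as the
smallest at which the planted-recovery statistics are stable.

## Known limitations

- The relevance threshold's meaning is tied to the MI estimator conventions
  above; comparing retained counts across estimators is not meaningful.
- The default of balancing before cross-validation
  optimistically biases the reported metrics (synthetic near-copies of test
  points appear in training folds); use `leak_free: true` for honest
  estimates.
- No missing-value support: the loader rejects non-numeric cells rather than
  imputing.
- Real-data mode expects a GEO-style series-matrix TSV with labels in a
  characteristics row and a GPL13534-style annotation CSV; IDAT parsing and
  intensity normalization are out of scope.
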