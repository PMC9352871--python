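# Methods

## Problem setting

Radiomics tables are small-n / large-d: a few dozen patients, several
hundred correlated real-valued features (intensity, texture, histogram,
volumetric, wavelet families) extracted from segmented MRI, and a binary
phenotype label — here the motivating case is MGMT promoter methylation
status in glioma (positive class = methylated). Most features are noise or
near-duplicates of one another; a classifier trained on all of them
overfits badly at these sample sizes. `gaselect` selects a small predictive
subset with a two-stage procedure and quantifies how well that subset
classifies.

## Stage 1 — gain-importance pre-filter

A single gradient-boosted tree ensemble (XGBoost) is fitted to the full
table and each feature is scored by its **gain**: the total loss reduction
it contributes across all splits, as reported by XGBoost's
`get_score(importance_type="gain")`. Features that never enter a split have
gain exactly 0.

Boosting hyperparameters (defaults, all configurable): logistic binary
objective, tree booster, learning rate (eta) 0.3, gamma 0, max depth 6,
L2 penalty (lambda) 1, 100 boosting rounds, single-threaded for
determinism. One historical parameter listing for this configuration also
shows `binary = "hinge"`, which contradicts the logistic objective and is
not an XGBoost parameter name; this package uses `binary:logistic` and
records the discrepancy here rather than guessing an interpretation.

The default selection policy is **nonzero_gain** — keep every feature with
gain > 0, optionally capped at the top 40 — so the stage-1 count is an
emergent property of the fit rather than a fixed k. A `top_k` policy is
available. The importance fit is a single fit on all samples; a
CV-aggregated importance is a possible extension but not implemented.

## Stage 2 — genetic-algorithm wrapper

Each individual ("GA-chromosome") is a bit vector over the stage-1
candidates; bit i = 1 includes feature i. Defaults (all in `GAConfig`):

| parameter        | default | meaning |
|------------------|---------|---------|
| population x     | 100     | chromosomes per generation |
| crossover rate   | 0.8     | probability a mating pair recombines |
| mutation rate    | 0.05    | per-bit flip probability |
| generations      | 5000    | fixed run length (no early stop by default) |
| elites           | 2       | top chromosomes copied unchanged |

One generation: evaluate fitness for every member; copy the `n_elites`
highest-fitness members unchanged (ties broken by fewer selected features —
parsimony — then by member index); fill the remaining slots with offspring
from roulette-wheel parent selection

    p_i = ACC-bar_i / sum_k ACC-bar_k ,

single- or double-point crossover (a fair coin decides which, per pair; cut
points uniform over interior positions, distinct for the double cross), and
independent per-bit mutation. Parents are drawn with replacement from the
full population, elites included. If the offspring count is odd the last
pair contributes one child. An all-zero fitness vector (possible only in
degenerate inputs) falls back to uniform selection probabilities.

Design choices where the procedure was genuinely open:

* **Mutation semantics** — per-bit independent flips at rate 0.05. A
  single-point per-chromosome mode exists behind `mutation_mode`.
* **Fitness of the all-zero chromosome** is defined as 0 (no features, no
  model), which keeps the degenerate mask out of the gene pool.
* **Trajectory convention** — the initial population counts as generation
  0 and is evaluated before the first replacement, so a run of G
  generations yields G + 1 trajectory points and `best_generation` is the
  first generation at which the final best fitness appeared. Evolution
  always continues to the configured horizon; an optional patience-based
  early stop exists but is off by default.

## Fitness

Fitness of a chromosome is the mean accuracy of a classifier under
`n_repeats` × stratified `n_folds`-fold cross-validation on the masked
columns. Classifiers: random forest with 100 trees (`rf`), RBF-kernel SVM
(`svm`), XGBoost with library defaults (`xgb`). Inside the GA the default
is 2 repeats of 5-fold CV; the final evaluation protocol uses 20 repeats.

Two deliberate choices:

* **Frozen folds.** Fold assignment is drawn once per GA run from
  `fold_seed` and reused for every chromosome. Fitness is then a pure
  function of the mask: the memoization cache is sound and elitism makes
  the per-generation best fitness exactly non-decreasing. Re-drawing folds
  per evaluation would make fitness comparisons noisy and the trajectory
  non-monotone.
* **Scaling.** Features are standardized (train-fold statistics only)
  inside the SVM pipeline, because RBF kernels are scale-sensitive; tree
  models receive raw features. Whether the original study standardized is
  unknown; this is this package's choice, documented as such.

No class weighting is applied (the intended cohorts are near-balanced) and
the inner classifiers are not tuned. Note the protocol — like the study
design it follows — evaluates the selected subset by CV on the same table
the subset was selected on; that estimate carries wrapper selection bias,
which is why the package also provides frozen-subset transfer to an
independent cohort, and why the null-data control below matters.

## Evaluation protocol

`repeated_cv_evaluate` runs 20 independent stratified 5-fold CVs (distinct
fold seeds derived from one seed). Within a repeat every sample is
predicted exactly once; confusion counts are pooled over the five folds,
and then over repeats:

    sensitivity = TP/(TP+FN),  specificity = TN/(TN+FP),
    accuracy    = (TP+TN)/(TP+TN+FP+FN).

Because each repeat scores all n samples once, the pooled ratios equal the
mean of the per-repeat ratios exactly, and the identity
`acc = (sens·P + spec·N)/(P+N)` holds on every report. Pooling within a
repeat (rather than averaging per-fold ratios) avoids undefined ratios in
small folds at n ≈ 50.

AUC is the rank (Mann–Whitney) form — probability a random positive
outscores a random negative, ties counted ½ — computed per repeat on pooled
scores (class-1 probability for rf/xgb, decision margin for svm) and
averaged. The 20 per-repeat accuracies are the samples compared across
classifier variants with the two-sample Kolmogorov–Smirnov test
(asymptotic p-value by default, exact behind a flag).

Transfer evaluation applies a frozen subset to a second cohort: names are
intersected (missing ones dropped and counted), and the classifier is
retrained within the target's CV folds — no re-selection.

## Synthetic cohorts

The generator emulates the radiomics table shape: `n_informative` features
share an equicorrelated latent factor (within-block correlation `rho`,
default 0.3) and get a standardized class-1 mean shift `delta` (default
1.2; each marginal has unit variance, so one feature's theoretical
two-class AUC is Φ(delta/√2)); `n_redundant` features are noisy linear
copies of informative ones (correlation ≈ 0.89 with their source),
mimicking the strong collinearity of radiomics families; the rest are
independent standard normals. Class counts are fixed at
`round(n·balance)` and shuffled, so small cohorts always contain both
classes. A `design_seed` separates the cohort *design* (names, column
order, redundant wiring) from the sample draw, so two specs sharing a
design model independent cohorts measured by the same extraction pipeline —
the transfer scenario. Feature names are radiomics-flavored but carry no
role information; ground truth is returned separately.

What the generator does **not** emulate: heavy inter-family correlation
structure of real extractions beyond one block, batch/scanner effects,
non-Gaussian marginals (a standardized-t option exists behind
`heavy_tailed`), and label noise. Passing the planted-recovery tests
therefore shows the machinery finds signal it is possible to find, not that
real radiomics cohorts contain such signal.

## Scaled demonstration sizes

The full study configuration (100 chromosomes × 5000 generations × repeated
5-fold CV) is a multi-day search. The package's own end-to-end checks and
`scripts/acceptance.py` use scaled conditions chosen a priori:

* planted-signal recovery: n = 80, 60 features, 8 informative, delta = 1.2;
  GA with population 24, 60 generations, RF fitness under 1 × 3-fold CV;
* null control: delta = 0, 200 features, pipeline with population 16, 30
  generations, RF fitness, scored on an independent n = 200 cohort;
* elitism-monotonicity runs use the SVM fitness (cheapest of the three);
* determinism check: population 12, 12 generations, SVM fitness.

The single CV repeat inside the scaled GA runs is the documented
cost-control knob of `FitnessSpec`; the evaluation protocol stays at 20
repeats everywhere.

## Numerical and degenerate-input conventions

* All randomness flows from one master seed through named `SeedSequence`
  substreams (init / selection / crossover / mutation / folds /
  classifier), so components are independently reproducible and any seed
  passed to scikit-learn stays below 2³¹.
* Samples are sorted by id before fold assignment, making every result
  invariant to input row order.
* Gain ties in the stage-1 ranking break lexicographically by feature name;
  zero-gain features sort last.
* Rows with missing values are dropped at load time (never imputed) with a
  logged count; a single-class label column is an error.
* A chromosome whose classifier fit fails receives fitness 0 with a
  warning.
* Selection probabilities on an all-zero fitness vector fall back to
  uniform with a warning.

## Limitations

* The CV-on-selection-table estimate is optimistically biased by
  construction (no nested CV, matching the protocol it implements); the
  transfer path and null control are the honest counterweights.
* Roulette selection with accuracies in [0.5, 1] exerts weak selection
  pressure (probability ratios near 1); elitism does most of the work at
  small population sizes.
* The stage-1 filter is a single fit; its retained set varies with the
  boosting seed on weak signals.
* Runtime is dominated by classifier fits: one GA run costs roughly
  population × generations × repeats × folds fits, minus cache hits.
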