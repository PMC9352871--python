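# gaselect

Two-stage feature selection for radiomics-style tables: a gradient-boosted
gain-importance pre-filter followed by a genetic-algorithm (GA) wrapper
whose fitness is the cross-validated accuracy of a pluggable classifier.

## Who this is for

Quantitative-imaging and biomarker researchers who have a small cohort
(tens of patients), a large extracted feature table (hundreds of
correlated radiomics features — intensity, texture, histogram, wavelet
families) and a binary phenotype label — the motivating application is
predicting MGMT promoter methylation status in glioma from MRI radiomics —
and who need a small, predictive feature subset plus an honest evaluation
of how well it classifies, including on a second cohort.

## The method

**Stage 1 (filter).** An XGBoost model (logistic objective, tree booster,
eta 0.3, max depth 6, lambda 1) is fitted once to the full table; features
are ranked by their *gain* — the total loss reduction contributed across
all tree splits — and features with zero gain are discarded.

**Stage 2 (wrapper).** A GA searches the subsets of the surviving
candidates. Each chromosome is a bit mask over the candidates; its fitness
is the mean accuracy ACC̄ of a classifier (random forest with 100 trees,
RBF-SVM, or XGBoost) under repeated stratified 5-fold cross-validation on
the masked columns. Generations evolve by fitness-proportional
(roulette-wheel) parent selection

```
p_i = ACC̄_i / Σ_k ACC̄_k
```

single- or double-point crossover (rate 0.8), per-bit mutation
(rate 0.05), and replacement with two elites copied unchanged — defaults:
population 100, 5000 generations.

**Evaluation.** The selected subset is scored by 20 × stratified 5-fold CV
(sensitivity, specificity, accuracy from pooled confusion counts; rank-form
AUC), classifier variants are compared by a two-sample Kolmogorov–Smirnov
test on the 20 per-repeat accuracies, and a frozen subset can be
transferred to a second cohort (e.g. high-grade → low-grade glioma) without
re-selection.

A synthetic-cohort generator with planted informative features makes every
stage testable with known ground truth. See `docs/methods.md` for the full
model description, design decisions and limitations.

## Worked example

```python
import gaselect as g

# synthetic cohort: 60 patients, 120 features, 8 informative (+6 redundant)
spec = g.SyntheticSpec(n_samples=60, n_features=120, n_informative=8,
                       n_redundant=6, effect_size=1.5, seed=7)
table, truth = g.generate(spec)

model = g.GAFeatureSelector(
    table,
    ga_config=g.GAConfig(population_size=20, n_generations=15, master_seed=1),
    fitness_spec=g.FitnessSpec("rf", n_folds=5, n_repeats=1),
)
results = model.fit()
print(results.summary())
report = results.evaluate(n_repeats=20, seed=0)
print(f"sensitivity {report.sensitivity:.3f}  specificity {report.specificity:.3f}  "
      f"accuracy {report.accuracy:.3f}  AUC {report.auc:.3f}")
```

prints

```
                Two-stage GA feature selection
==============================================================
No. samples:                60
No. features (input):       120
Class counts (neg/pos):     30/30
Stage-1 policy:             nonzero_gain (cap 40)
Stage-1 candidates:         12
Fitness classifier:         rf (1x5-fold CV)
Population / generations:   20 / 15
Crossover / mutation rate:  0.8 / 0.05
Master seed:                1
--------------------------------------------------------------
Best fitness (ACC-bar):     1.0000  at generation 15
Selected features:          3
--------------------------------------------------------------
  MORPH_T2_F0037
  MORPH_T2_F0092
  TEXTURE_NGTDM_FLAIR_F0027
==============================================================
sensitivity 0.940  specificity 0.963  accuracy 0.952  AUC 0.995
```

The stage-1 filter kept 12 of 120 features; the GA settled on 3 of them.
The best fitness of 1.0 is the GA's own (selection-biased) CV accuracy on
the training table; the 20-repeat evaluation below it is the reported
metric set. Note both are computed on the cohort the subset was selected
from — for an unbiased estimate, transfer the frozen subset to an
independent cohort with `results.transfer(other_table)`.

## Command line

```bash
gaselect simulate --seed 4 --out synth.csv --truth truth.txt
gaselect select-stage1 --input synth.csv --label-column label --out stage1.txt
gaselect select-ga --input synth.csv --label-column label \
    --candidates stage1.txt --classifier rf --pop 100 --gens 5000 --seed 1 --out run/
gaselect run --input table.csv --label-column MGMT --positive-label methylated \
    --transfer lgg.csv --seed 1 --out run/      # full pipeline + transfer
gaselect compare runA/manifest.json runB/manifest.json   # KS test
```

Each run writes a JSON manifest (config, seeds, stage-1 ranking, GA
trajectory, evaluation reports) sufficient to reproduce it bit-identically.

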