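# nivstack

Prediction of noninvasive-ventilation (NIV) failure for ICU patients,
implemented as a reusable, fully testable pipeline:

* **`nivstack.cohort`** — seeded synthetic ICU cohort generator: static
  fields, paired physiological measurements before NIV (`H0_*`) and after
  one hour (`H1_*`), class-imbalanced binary outcome (`niv_failure`),
  configurable effect sizes, missingness, outliers, and far-isolated
  minority points for oversampler testing.
* **`nivstack.preprocess`** — train-fitted cleaning chain: 3-sigma outlier
  masking, median imputation, z-score standardization, one-hot encoding
  with rare-category collapse into `Others`, and the 80/20 split.
* **`nivstack.features`** — three feature families with provenance tags:
  per-pair temporal mean/difference (`manual`), clinician formulas and
  pairwise products (`expert` / `cross`), and autoencoder latents
  (`deep`); variance + Pearson feature selection.
* **`nivstack.lstm_autoencoder`** — an LSTM encoder/decoder over the two
  time points, written directly in numpy (analytic backprop + Adam,
  verified against finite differences); the latent code becomes the deep
  feature block.
* **`nivstack.oversample`** — the hard-instance cluster oversampler: an
  RBF-SVM probe collects misclassified minority rows, isolated points are
  removed, the remainder is k-means clustered, and synthetic minority
  rows are drawn on centroid-to-member segments until class balance.
  Baselines (random, classic/borderline/SVM k-NN interpolation) share the
  same signature.
* **`nivstack.stack`** — three base learners (logistic regression, random
  forest, categorical-aware gradient-boosted trees) stacked through a
  logistic meta learner trained on out-of-fold probabilities.
* **`nivstack.metrics` / `nivstack.benchmarks`** — accuracy, precision,
  recall, F1, rank-based ROC-AUC; oversampler and classifier comparison
  harnesses.
* **`nivstack.explain`** — exactly additive per-feature attributions:
  closed-form linear explanations for logistic regression, a seeded
  permutation explainer for tree models and the stack; global mean-|phi|
  rankings.
* **`nivstack.pipeline` / `nivstack.cli`** — config-driven orchestration
  with a single global seed fanned out per stage.

## CLI

```bash
# generate a synthetic cohort CSV
nivstack simulate --n-patients 2495 --seed 1 --out cohort.csv

# full pipeline: simulate -> preprocess -> features -> oversample ->
# stack -> evaluate -> explain; artifacts land in the output directory
nivstack train --config config.yaml --seed 1 --out-dir run/

# comparison tables
nivstack benchmark-oversamplers --config config.yaml --seed 1
nivstack benchmark-classifiers --config config.yaml --seed 1
```

Minimal `config.yaml`:

```yaml
cohort: {n_patients: 1000, failure_rate: 0.3}
autoencoder: {latent_dim: 8, hidden_units: 32, epochs: 200}
stack: {n_folds: 5}
oversampler: modified_smote
use_deep: true
out_dir: run
```

Stage toggles (`use_manual`, `use_expert`, `use_crosses`, `use_deep`)
reproduce the feature-ablation arms; `oversampler` swaps the rebalancing
method.

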