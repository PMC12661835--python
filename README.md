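# tabaug

**Does synthetic-data augmentation help small tabular health datasets — and
why?**

Clinical prediction models are routinely trained on datasets that are far
too small for stable machine learning.  One remedy is *augmentation*:
fit a generative model to the available records, simulate n′ additional
rows, and train on the concatenation of n = n₀ + n′ rows.  `tabaug` is a
tested framework for quantifying when this works for mixed-type tabular
data with a binary outcome, for whom the gain is real, and whether it is
driven by added data **diversity** rather than by sample size alone.

The package provides:

* a schema-typed tabular data model (CSV + YAML sidecar) with
  outcome-stratified splitting and smoothed target encoding;
* three augmentation generators behind one fit/sample contract —
  bootstrap resampling (the "more rows, no new diversity" control),
  sequential decision-tree synthesis, and a Bayesian network learned by
  hill-climb BIC search — plus a subprocess adapter for external deep
  synthesizers;
* a LightGBM prognostic workload with leakage-safe tuning and rank-based
  ROC-AUC evaluation;
* eight dataset-complexity characteristics (degrees of freedom, imbalance
  factor, standardized entropy, mutual-information CV, Gower-distance
  class separability, baseline ROC-AUC, n₀, predictor count);
* a diversity statistic built on an extended isolation forest: both the
  base and augmented datasets are scored by oblique-split isolation trees
  trained on the base only, scores become contamination curves over the
  threshold grid τ = 0.01…1.00, and

      diversity = (1/100) Σⱼ 1(xⱼ ≥ 0) · xⱼ(2 − xⱼ),

  with xⱼ the augmented-minus-base contamination-rate difference;
* the two study engines: a population-scale grid (40 base sizes × 10
  geometric series × 30 synthetic sizes n′ = [b^(i+4)], b ~ N(1.5, 0.005))
  and a nested 5-fold cross-validated case study with exact sign-flip
  permutation tests;
* a random-intercept logistic model (Gauss–Hermite marginal likelihood,
  validated against `lme4::glmer`) of which dataset characteristics
  predict augmentation benefit;
* a latent-Gaussian-copula population simulator with `simple` and
  `complex` presets spanning the studied complexity range, so the entire
  pipeline runs without any restricted data.

## Worked example

```python
from tabaug import *
from tabaug.workload import FAST_SETTINGS
from tabaug.grid import draw_base

pop = generate_population(preset_population("complex", n_rows=20_000, seed=7))
pair = split_population(pop, train_fraction=0.7, seed=7)

base = draw_base(pair.train, n0=100, seed=1)
baseline = evaluate_auc(train_workload(base, FAST_SETTINGS), pair.test)

model = fit_generator("bayes_net", base, seed=1)
aug = augment(base, model, n_prime=300, seed=1)
augmented = evaluate_auc(train_workload(aug, FAST_SETTINGS), pair.test)

div = dataset_diversity(base, aug, seed=1)
boot = augment(base, fit_generator("bootstrap", base, seed=1), 300, seed=1)
div_boot = dataset_diversity(base, boot, seed=1)

print(f"baseline ROC-AUC (n0=100):        {baseline:.4f}")
print(f"augmented ROC-AUC (n' = 300):     {augmented:.4f}")
print(f"relative improvement:             {relative_improvement(baseline, augmented):.2f}%")
print(f"diversity (Bayesian network):     {div.diversity:.4f}")
print(f"diversity (bootstrap control):    {div_boot.diversity:.4f}")
```

prints

```
baseline ROC-AUC (n0=100):        0.5595
augmented ROC-AUC (n' = 300):     0.6306
relative improvement:             12.71%
diversity (Bayesian network):     0.0338
diversity (bootstrap control):    0.0009
```

A base sample of only 100 rows from a complex population (high-cardinality
categoricals, prevalence 0.15) gives a weak classifier.  Augmenting it with
300 Bayesian-network records lifts held-out ROC-AUC by 0.07 — while
bootstrap resampling, which adds rows but essentially no new support,
leaves diversity near zero.  That contrast (generative diversity ≫
bootstrap diversity, and AUC gains tracking it) is the mechanism the
package is built to measure.

## Command line

```bash
tabaug make-population --preset complex --n-rows 20000 --seed 7 --out pop.csv
tabaug diversity --base base.csv --augmented aug.csv --schema pop.schema.yaml --seed 1
tabaug paired-test --table results.csv --column-a augmented_auc --column-b baseline_auc
tabaug part1 --config part1.yaml --out-dir out/   # grid + benefit model
tabaug part2 --config part2.yaml --out-dir out/   # nested-CV case studies
```

Every run writes a `manifest.json` of seeds and config hash; reruns with
the same manifest are byte-identical.

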