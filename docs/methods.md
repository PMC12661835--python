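# Methods

`tabaug` evaluates data augmentation for small tabular health datasets: how
much does concatenating synthetic records to a small training set (size
n₀) improve the held-out ROC-AUC of a gradient-boosted tree classifier, and
is any improvement attributable to added data *diversity* rather than to
sample size alone?  This note documents the models, the defaults and their
rationale, the numerical choices, and what the synthetic study conditions
do and do not show about real data.

## The augmentation design

A population dataset is split once, 70%:30%, stratified by the binary
outcome; the test partition is fixed for an entire run.  From the training
partition, outcome-stratified base samples of size n₀ are drawn without
replacement over a 40-point grid (20–100 by 10, 150–1,000 by 50,
2,000–10,000 by 1,000, 20,000–50,000 by 10,000).  Each base sample fits a
generative model, which then produces synthetic records in geometric series:
a growth factor b ~ N(1.5, 0.005) is drawn once per series and element i is
n′ = [b^(i+4)] (nearest integer, halves away from zero), for i = 1..30 —
roughly 8 to 10⁶ records — with 10 series per configuration.  The augmented
training set is the base rows followed by the n′ synthetic rows, so
n = n₀ + n′.  At full scale this yields 40 × 10 × 30 = 12,000 augmented
datasets per generator per population (300 per n₀).  Whether b should vary
per element rather than per series is genuinely open; we draw once per
series so each ladder is internally coherent, and expose `b_per_element`
as a switch.

Cells whose augmented data degenerate (for example a single synthetic
outcome class at tiny n′) are recorded with a `failed` flag rather than
silently dropped.

## Generators

* **Bootstrap** — whole-row resampling with replacement.  This is the
  control condition: it increases sample size while adding (nearly) no new
  support, so any ROC-AUC gap between bootstrap and model-based augmentation
  isolates the contribution of diversity.
* **Sequential decision trees (SEQ)** — variables are synthesized in schema
  order; the first from its empirical marginal, each later variable from a
  CART tree (classification for categoricals, regression for numerics)
  fitted on the preceding variables.  Sampling routes the synthesized
  prefix to a leaf and draws from the leaf's class frequencies or its pool
  of observed numeric values, so no value outside the observed support is
  invented.  Defaults: `min_leaf=5`, `max_depth=12` — small trees that
  resist overfitting at the base sizes studied here.  The variable order is
  configurable; schema order is the default because no principled ordering
  is available without extra assumptions.
* **Bayesian network (BN)** — numerics are discretized into 5
  equal-frequency bins; structure is learned by greedy hill climbing
  (add/remove/reverse arc moves from an empty graph) maximizing the
  decomposable BIC under a `max_parents=3` limit; conditional probability
  tables are posterior means under a symmetric Dirichlet prior with
  strength 1, so rows sum to one and unseen parent configurations fall back
  to uniform.  Sampling is ancestral in topological order, with numerics
  back-transformed by a uniform draw within the sampled bin.
* **Adapter** — deep tabular synthesizers (CTGAN/TVAE-class models) are
  supported only through a subprocess contract over CSV files; their
  training loops are deliberately out of scope.

## The workload

LightGBM binary classification.  Categorical predictors are embedded by
smoothed target encoding fitted on the training rows only:
level → (count·level_mean + s·global_mean)/(count + s) with smoothing
s = 10 (the shrinkage keeps rare high-cardinality levels near the global
rate).  Unseen levels map to the global mean.  Hyperparameters are chosen
by seeded random search over a conventional space (learning rate 0.01–0.3
log-uniform; 8–128 leaves; depth 3–12; min child samples 5–50; feature/row
subsampling 0.6–1.0; L1/L2 10⁻⁸–10 log-uniform), scored by stratified
inner-CV ROC-AUC, default budget 30 configurations, then refit on the full
training data.  A reduced budget (`FAST_SETTINGS`: 5 trials, 3 folds, 60
boosting rounds) is used for smoke runs and most tests; the mechanism
experiments reported by the acceptance script use it too, with base size
n₀ = 100 and n′ ∈ {100, 300, 1000} on a 20,000-row population — sizes
chosen so a full run is a desk-scale computation while leaving the
qualitative behaviour of the full design intact.  ROC-AUC is computed
rank-based with ties counted ½, i.e. the Mann–Whitney U statistic scaled
by n₊·n₋ (asserted against `scipy.stats.mannwhitneyu` in the tests).

## Complexity characteristics

Eight quantities describe each base dataset: n₀; total degrees of freedom
(1 per numeric, k−1 per k-level categorical); the imbalance factor
max(p/(1−p), (1−p)/p) of outcome prevalence p; mean standardized entropy
of the predictors (Shannon entropy over level frequencies divided by
log k, defined as 0 for a single-level variable); the coefficient of
variation (sample SD / mean) of plug-in mutual information over all
predictor pairs; a class-separability ratio; the baseline ROC-AUC; and the
predictor count.  Numerics are discretized into 10 equal-frequency bins
for entropy and MI — the grain is configuration, not ground truth, and MI
uses natural log (the normalization cancels the base).

Separability is the ratio of mean intraclass to mean interclass
nearest-neighbour Gower distance (numeric contributions |a−b|/range,
categorical 0/1 mismatch, missing contributions omitted from the mean;
a zero-range numeric contributes 0).  Ratio-of-means is the default
aggregation because per-record ratios are undefined on duplicate records;
mean-of-ratios is available as an option.  Datasets beyond 2,000 rows are
stratified-subsampled before the O(n²) distance matrix.

## Diversity

An extended isolation forest — isolation trees with random *oblique*
hyperplane splits (standard-normal normal vector over all encoded
dimensions, intercept uniform within the node's projection range), grown on
ψ-subsamples to depth ⌈log₂ ψ⌉ — is fitted on the base dataset only.
Records are encoded without the outcome (min-max scaled numerics,
level-frequency categoricals) so outcome labels cannot leak into the
diversity measurement.  Scores use the classic normalization
s = 2^(−E[h]/c(ψ)), placing them in (0, 1) so the fixed threshold grid
τ = 0.01, …, 1.00 is meaningful.  Defaults n_trees = 200 and
ψ = min(256, n) follow standard isolation-forest practice.

Both the base and the full augmented dataset are scored; each score vector
becomes a contamination curve (share of records with score ≥ τ), and with
x_j the augmented-minus-base rate difference at threshold j,

    diversity = (1/100) Σ_j 1(x_j ≥ 0) · x_j (2 − x_j).

The statistic is 0 when augmentation adds no outlying structure and 1 at
the maximum; negative differences contribute nothing; the weight x(2−x) is
increasing on [0, 1], so larger positive shifts in the contamination curve
always raise the score.

## Case studies and inference

Small datasets are evaluated with a stratified nested 5-fold outer loop:
every generator is fitted on each training partition only, augmented
training sets over the geometric n′ ladder are scored on the held-out
fold, and fold-averaged ROC-AUC selects the best (generator, n′_max) pair
— smallest n′ on ties, since the cheaper augmentation is preferable.  The
baseline is the fold average of the un-augmented workload.  A bootstrap
rerun at exactly n′_max provides the resampling control, and diversity is
fold-averaged the same way.

Across datasets, paired comparisons use a one-tailed exact sign-flip
permutation test of the mean difference: all 2ⁿ sign assignments of the
absolute differences are enumerated (n ≤ 20) and the p-value is the share
with mean ≥ the observed mean, ties counting as extreme — on the bundled
seven-dataset benchmark table this yields 1/128 ≈ 0.0078 for augmented vs
baseline AUC and 2/128 ≈ 0.016 for augmented vs resampled.  Beyond 20
pairs the test falls back to Monte-Carlo sign flips with the resampling
count reported.

## The benefit model

Per {dataset, n₀, generator} cell, benefit = 1 when the best
mean-over-series augmented AUC across the n′ ladder exceeds the baseline.
The mean-over-series form damps Monte-Carlo noise from single runs;
`any_run` and `overall_mean` variants are exposed because the aggregation
rule is genuinely open.  The benefit indicator is then modelled by a
logistic regression with the eight characteristics as fixed effects and a
random intercept per dataset.  The marginal likelihood is maximized
directly with the cluster integral evaluated by 25-node Gauss–Hermite
quadrature and an analytic gradient; Wald standard errors come from the
numerically differentiated observed information.  The fit agrees with
R's `lme4::glmer` (nAGQ = 25) to within 0.05 on fixed effects in the test
suite, and 95% Wald CIs cover known simulated coefficients at ≥ 0.9 over
100 replicates.  Odds ratios are exp(estimate) with exponentiated Wald
CIs; a standardized variant (covariates centered and unit-scaled,
zero-variance columns dropped with a warning) makes estimates comparable
across characteristics.  Extreme estimates or unstable standard errors
raise a quasi-separation warning rather than failing silently.

## The synthetic populations

Real populations of the kind this framework targets are access-restricted,
so the study conditions are emulated by a latent Gaussian copula: a
multivariate normal draw with configurable (exchangeable or full)
correlation supplies dependence; numerics are latent coordinates;
categoricals slice their latent coordinate into k levels at
equal-probability or Zipf-weighted quantiles; the outcome is logistic in
per-predictor effects, with categorical levels carrying evenly spaced
scores in [−1, 1] so cardinality refines rather than inflates the signal;
the intercept is calibrated by bisection so expected prevalence hits the
target within 10⁻³.  Two presets bracket the studied complexity range: a
claims-like **simple** population (6 predictors, max cardinality 5,
prevalence 0.3) and an adverse-event-report-like **complex** population
(7 predictors including Zipf-imbalanced categoricals with 50–120 levels,
prevalence 0.15).  Coefficients were set so large-sample baseline ROC-AUC
falls in the middle of the 0.5–0.9 range seen in clinical prediction work.

What the copula does *not* emulate: real missing-data mechanisms,
nonlinear or interaction-driven outcome surfaces, measurement error,
temporal structure, and the idiosyncratic level distributions of real
registries.  Passing tests on these populations therefore demonstrate
that the pipeline's mechanics and the qualitative augmentation mechanism
(small-n₀ gains on complex data; generative diversity exceeding bootstrap
diversity) behave as designed — not that any particular real dataset will
see the same effect sizes.

## Known limitations

* The SEQ and BN samplers only emit observed categorical levels and
  observed (or binned) numeric values; they cannot extrapolate beyond the
  base support.
* The BN hill climb is greedy and can stop at a local BIC optimum;
  restarts are not implemented.
* The permutation test's exact mode is capped at 20 pairs by memory/time;
  the Monte-Carlo fallback is clearly flagged in its result.
* The GLMM uses non-adaptive Gauss–Hermite quadrature; for very large
  cluster sizes with extreme intercept variance, adaptive quadrature would
  be more accurate.
* Deep generative baselines are adapter-only; no training code ships with
  the package.
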