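# Methods

This note records the modelling assumptions, parameter defaults and design
choices behind `myodx`, and what the synthetic cohorts do and do not
establish about behaviour on real data.

## Scales and score representation

Five scales are built in: Mercuri-style ordinal scales 0–4, 0–5, 1–4, the
0–4 variant with 2a/2b subcategories, and the continuous Dixon fat fraction
(FF).  Discrete scores are held internally in *rank space* (0-based ordinal
rank, fractional after averaging), which makes side- and group-averaging
well defined for non-numeric levels; the 2a/2b subcategories are ordered
2a < 2b between 1 and 3.  Normalization maps rank r of k levels to
100·r/(k−1).  The mapping is linear over ranks by default: ordinal Mercuri
grades carry no calibrated fat-fraction anchors, so any non-linear
quantization would be an extra assumption; per-scale custom mappings can be
added by registering a `FatScale`.

Fat-fraction values pass through unchanged.  Equal-width bins over [0, 100]
(k levels → k bins) are used when the synthetic generator quantizes a
continuous fat fraction onto a discrete scale; the round-trip error is at
most one normalized bin width, 100/(k−1).

## Harmonization pipeline

Order of operations: align to the target muscle list (merge/expand) → reduce
sides → normalize scales → KNN-impute missing muscles → leave-one-out
rescale → assemble extra features.  Imputation runs *before* rescaling so
the leave-one-out mean is always computed on complete vectors; rescaling
partially observed vectors would make relative scores incomparable across
missingness patterns.  The alternative order is available via
`CohortHarmonizer(impute_before_rescale=False)`.

Specific choices:

* **Merging with a missing member yields a missing group score** rather
  than the mean of the observed members, to avoid silently biasing group
  scores; missingness is handled downstream by imputation.
* **Asymmetry** is |L − R| after normalization (signed differences would
  depend on arbitrary side labelling); the per-patient summary uses the
  population (n-denominator) standard deviation.  Non-bilateral records get
  missing asymmetry features, imputed like any other block-missing feature;
  if an entire training cohort lacks bilateral data the asymmetry columns
  are structurally unobservable and are neutralized to 0.
* **Age scaling** is a min–max map onto [−100, 100] learned from training
  data only and persisted with the model; out-of-range ages are clipped.
* **`mean_involvement`** is the mean of the (imputed) normalized absolute
  scores over the modelled muscle set — the disease-stage signal removed
  from the individual features, kept as one explicit column.
* **KNN imputation** uses k = 5 neighbours, nan-aware Euclidean distance
  rescaled by feature coverage, uniform donor weights.  k is a conventional
  default, exposed as `imputer_k`.  The imputer, like every other fitted
  component, is refit per training fold inside cross-validation.

The leave-one-out rescaling is exactly shift-invariant: adding a constant
to all of a patient's normalized scores changes only `mean_involvement`.
This is what removes scorer/protocol offsets and, with them, most of the
scale information.

## Augmentation

The modified SMOTE-NC oversamples every class, including the majority, to
`ceil(augment_factor × max original class count)`; `augment_factor = 1`
(default) balances classes without inflating the majority.  A per-class
multiplier was considered and rejected because it would not balance
classes.  Interpolation uses k = 5 same-class neighbours (shrunk for small
classes), the SMOTE-NC categorical convention (majority value among
neighbours, median-of-stds distance penalty), and `sex` as the only
categorical feature; `scale` and `source` are metadata and never model
features.  Classes with a single training member are refused — there is
nothing to interpolate — so cohorts must provide at least two patients per
class per training partition.

## Training protocol

Nested, patient-grouped, stratified cross-validation: 10 outer × 5 inner
folds by default (`StratifiedGroupKFold`, grouping by patient so
longitudinal repeats never straddle a train/test boundary).  The TPE
sampler (authored in-package: univariate Parzen mixtures over good/bad
trial splits at the γ = 0.25 quantile, 30 random startup points, 60 trials
per fold, objective = mean inner-fold balanced accuracy) proposes
hyperparameters; combinations scoring strictly above the linear-interpolated
90th percentile of a fold's trials are refit on the full outer training
partition as ensemble members (≤ 6 of 60 trials; ties at the threshold fall
back to the top `round(n/10)` by score; zero finite trials is an error).
Members are refit rather than reusing inner-fold fits to maximize member
quality.  Default search space: depth 2–10, learning rate 1e−3–0.5 (log),
50–500 trees, subsample/colsample 0.5–1, min-child-weight 1–20, L1/L2
1e−8–10 (log).  These are conventional ranges for boosted trees on small
tabular data, not a published space.

All stochastic stages (fold shuffling, TPE, SMOTE, tree construction) draw
child seeds from one root seed via `numpy.random.SeedSequence`, so a run is
reproducible bit for bit.

Prediction averages raw margins across members and applies the
max-subtracted softmax; ranking ties are broken by fixed class order.  A
deployment bundle can pool the qualifying trials of all outer folds into
one refit ensemble (`--pool-folds`, default) or keep the first fold's.

## Explanations

SHAP values are tree-SHAP on raw margins (XGBoost's native
`pred_contribs`/`pred_interactions`), averaged over members exactly as the
margins are, so local accuracy holds for the ensemble (residuals < 1e−4 in
tests; interaction row-sums recover SHAP values within 1e−3).  Per-disease
summaries average |SHAP| over *all* samples toward that class by default
(the class-only view is a flag); clustering is agglomerative with average
linkage on Euclidean distances, rows and columns independently, leaf order
deterministic.  Interaction summaries zero the diagonal before clustering
so main effects do not swamp the colour scale.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
per-disease muscle-involvement prototypes (weights in [0, 1]), a disease
stage s ~ Beta(2, 2) (mid-stage mass; real pooled cohorts span early to
late stages), continuous fat = clip(100·s·prototype + N(0, 8), 0, 100),
Gaussian left/right asymmetry (sd 5 normalized units; one deliberately
asymmetric disease uses sd 15 to exercise the asymmetry features),
source-specific scales, side modes, scoring offsets and missing-muscle
blocks, truncated-normal ages with disease-specific means, longitudinal
repeats (p = 0.15) that advance the stage, and 4:1 class imbalance.

* **Default design** (pipeline recovery): eight diseases with distinct
  hallmark-muscle prototypes over five sources, one per scale.  Sources do
  not recruit diseases whose hallmark region they cannot image (the
  thigh-only source contributes no distal myopathies), mirroring how real
  multi-study pools are assembled.  400 patients by default.
* **Confounded design** (leakage demonstration): each disease is observed
  through exactly one source, so scale is confounded with diagnosis.
  Diseases come in weight-permuted pairs of four involvement families, the
  two members of a pair bound to *different* scales — no single muscle
  identifies a scale through the disease.  Each scale except 0–4 has one
  marker muscle its sources never score; these deterministic missing
  blocks are the channel a shallow probe reads pre-harmonization.

What the synthetic tests show: the pipeline recovers planted patterns
(out-of-fold balanced accuracy ≥ 0.8, weighted top-3 ≥ 0.95 at desk scale)
and harmonization removes directly recoverable scale information (a depth-3
tree probe: ~1.0 accuracy before, ≤ 0.6 after, where the residual is the
irreducible disease→scale association of the confounded design).  What
they do not show: performance on real scored MRI, where patterns overlap
more, scorers disagree, and stage distributions are not Beta; absolute
accuracy numbers on synthetic cohorts say nothing about clinical accuracy.

## Problem sizes

Tests and the acceptance script use a scaled-down protocol chosen as a
deliberate desk-scale design point: 400-patient cohorts, 5 outer × 3 inner
folds, 10 TPE trials (5 startup) and a reduced tree space (depth 2–6,
50–200 trees).  The full 10 × 5 / 60-trial protocol is the library default
for real use.

## Known limitations

* Ordinal→0–100 mapping is linear per rank; if a scale's grades are known
  to be non-linear in fat fraction, supply a custom mapping.
* Fractional scores on the labelled 2a/2b scale cannot be written back to
  CSV (they arise only after averaging, which is an internal
  representation).
* KNN imputation is non-iterative; model-based imputation is out of scope.
* The TPE sampler models hyperparameters independently (univariate
  mixtures); parameter correlations are not exploited.
* No significance testing between classifiers; baseline comparisons are
  descriptive.
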