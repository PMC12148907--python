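# Methods

This note documents the models and procedures implemented in `attenurank`,
the assumptions behind them, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The cohort simulator

Real athlete-monitoring datasets of this kind are restricted, so the
package ships a generator (`attenurank.cohort`) whose output has the same
schema and summary structure a Gaelic-football monitoring study would
produce: 41 athletes by default; anthropometrics with the published cohort
moments (age 23.3 ± 4.2 y, height 178.3 ± 7.91 cm, body mass
80.64 ± 9.47 kg, Σ7 skinfolds 81.3 ± 28.0 mm, body fat 14.3 ± 5.2%);
baseline neuromuscular tests, strength 1RMs and VO₂max; four GPS running
metrics split by half; and pre/post-match panels for PR, CK, CMJ, DJ, DJCT
and RSI. Moments for the non-anthropometric variables are not published
for this cohort; the defaults in `DEFAULT_MOMENTS` are set once from
sport-science norms for senior male team-sport athletes (e.g. CMJ
38 ± 5.5 cm, VO₂max 55 ± 4 ml/kg/min, match distance 8.5 ± 0.9 km,
~12 sprints > 20 km/h) and are user-overridable; they are documented as
assumptions, not facts about the original cohort.

**Generative structure.** A deliberately minimal two-factor model:

* latent fitness F ~ N(0,1) loads on the fitness-related columns
  (loadings 0.4–0.6, negative for body fat, contact time and age);
* latent attenuation A = −ρ·F + √(1−ρ²)·ε with ρ =
  `correlation_strength` (default 0.6): fitter athletes attenuate less;
* the second-half decline fraction of each GPS metric and the
  pre-to-post-match decrement of each response panel are affine in
  `attenuation_effect · A` plus noise scaled by `noise_sd`, clipped to
  plausible ranges. With `noise_sd = 0` the relations are exact and
  recomputable from the stored latent draws (a test oracle).

A single shared factor is the simplest structure that makes the
median-split labels learnable from the input columns while remaining
parameter-recoverable; it deliberately does not model the real cohort's
full joint distribution, positional differences, or recovery dynamics at
half-time/24 h/48 h (those time points exist in the schema design but are
not generated by default). Consistency constraints are built in: RSI =
jump height / contact time up to measurement noise, match totals are the
exact sum of halves, PR is a latent normal thresholded into the 1–5 Likert
grid, CK is log-normal with a post-match multiplicative rise.

Draws are clipped post-hoc to physiological ranges (clipped fractions are
logged); ranges were chosen wide enough that all configured moments stay
recoverable within 3 standard errors / 10% relative error at n ≥ 1000.
Consequence of the design worth knowing: the planted signal reaches the
input columns only through F, so at the default ρ = 0.6 and noise level the
classification problem is genuinely hard (near-chance on an 11-row test
split); the test suite's learnability and control checks use explicit
strong-signal conditions (ρ = 0.9, effect 2.0, noise 0.3).

**Normality gate.** `normality_check` runs Shapiro–Wilk per continuous
column; constant columns return `"degenerate"` rather than pass/fail
because the statistic is undefined at zero variance. CK fails by
construction (log-normal), as it typically does in practice.

## 2. The ranking system

All scaling is **cohort-wise min–max on severity**. For intra-match
declines severity is −(second − first); for pre/post differences severity
is oriented per variable (decrease-worse for PR, CMJ, DJ, RSI;
increase-worse for CK and DJCT — both worsen by rising). The orientation
map is configuration: the Likert questionnaire's direction in particular
is an assumption (default: higher PR = better wellbeing). Choices made
where the construction was open:

* the min–max reference is the cohort itself (no historical norms);
* "pre-existing rankings" are the min–max-scaled severity of the pre/post
  difference, mirroring the decline normalization and keeping the adjusted
  ranking (their exact product) in [0, 1];
* degenerate constant inputs map everyone to 0.5 — all athletes sit at the
  median and the split deterministically yields all-Group-0;
* second-half improvements stay on the linear scale (an improver anchors
  severity 0); `clip_improvements=True` floors them instead so one outlier
  cannot stretch the scale.
* the median is the standard mid-point of the central order statistics;
  group 1 is strictly-above-median, so tie-free cohorts split within one.

Every run emits a JSON ledger (scaling bounds, medians, group counts) so
any label can be audited back to raw data.

## 3. The tabular VAE

Implemented from first principles in NumPy (`attenurank.tvae`): at this
scale (tens-to-thousands of rows, a few hundred transformed dimensions)
dense linear algebra is fast, and the explicit backward pass is verified
against central-difference gradients in the test suite.

* **Transforms.** Continuous columns: per-column Gaussian mixture with the
  component count selected by BIC over k = 1..10 (a unimodal column gets
  exactly one mode; a clearly bimodal one gets two); values encode as
  offsets (x−μₖ)/(4σₖ) clipped to ±0.99 plus a one-hot mode indicator,
  with the mode sampled from its posterior. Categoricals are one-hot.
  Rounding precision is inferred as the maximum number of decimals
  observed (capped at 8).
* **Architecture/training defaults** (all overridable): 128-dim diagonal
  Gaussian latent, compress/decompress dims (128, 128), Adam at 1e-3 with
  weight decay (`l2scale`) 1e-3, batch 500, 500 epochs, reconstruction
  weighting factor 2 (applied to the reconstruction term only, not the
  KL). With a 41-row table and batch 500, each epoch is one full-batch
  step. Log-variances are clamped to ±20 (gradient zeroed where clamped);
  the learned output scales σ_d are clamped to [0.01, 1] after each step.
  Training is a pure function of the seed; non-finite loss raises with the
  epoch index.
* **Sampling.** Latents from N(0, I); continuous offsets are drawn from
  the decoder's Gaussian output (tanh mean + learned σ_d noise) — sampling
  the output model rather than its mean, which matters for marginal
  fidelity; mode indicators decode by argmax, categoricals are sampled
  from the softmax probabilities (hence never leave the training category
  set). Enforcement order is round-then-clip so rounding can never push a
  value outside the observed training envelope; a column trained on a
  constant is reproduced exactly.
* The pipeline trains one model jointly over the 14 inputs and the 6
  binary group labels (so the synthetic pool carries its own labels);
  `inputs_only=True` synthesizes features alone.

## 4. Fidelity scoring

All metrics are symmetric, live on [0, 1], and score 1 iff the compared
summaries are identical; each is cross-checked against an independent
brute-force implementation to 1e-12 in the tests. Choices:

* Hellinger distances for continuous columns use 20 shared equal-width
  bins over the pooled range (configurable); 20 bins is stable around
  n ≈ 200. Binning follows the standard histogram convention
  (lower-closed bins, last bin closed).
* The dataset-level Hellinger value is the unweighted mean over columns;
  pair-trend and shape aggregates are unweighted means; the overall score
  is the mean of the two aggregates.
* Correlation similarity uses Pearson ρ; zero-variance columns raise
  rather than returning a conventional value, and `quality_report` skips
  such pairs (they carry no trend information).
* Likert/binary columns are treated as categorical throughout (TV
  complement / contingency similarity).
* Tiers on the shape score: high > 0.85, moderate 0.80–0.85, lower < 0.80.

## 5. Two-phase evaluation

* Grids (defaults): random forest — estimators {50, 100, 200}, depth
  {None, 10, 20, 30}; XGBoost — estimators {50, 100, 200}, learning rate
  {0.01, 0.1, 0.2}, depth {3, 6, 9}; AdaBoost — estimators {50, 100, 200},
  learning rate {0.01, 0.1, 1.0}, depth-1 stumps; linear SVM — C
  {0.01, 0.1, 1, 10}, max iterations {1000, 2000}, with standardized
  features (the other families operate on raw features).
* Selection inside a family: stratified 5-fold CV accuracy (grid order
  breaks exact ties). Across families: CV accuracy, then test F1, then a
  fixed simplicity order (linear SVM < AdaBoost < random forest <
  XGBoost). Precision/recall/F1 are class-macro by default
  (`weighted` available).
* Phase 1 proportions are **relative to the real training split**:
  p = 100% appends as many synthetic rows as there are real training rows
  (the only base that keeps p meaningful against a ~30-row split). Rows
  are drawn without replacement from the pool with a seeded generator;
  p = 0 reduces exactly to the benchmark. Phase 2 trains on a seeded
  permutation prefix covering p ∈ {40..100}% of the pool and evaluates on
  every real row; below ~40% of a 200-row pool, training is too unstable
  to interpret.
* Labels for synthetic rows default to the jointly synthesized group
  columns; recomputing them through the ranking module is possible when
  the synthesized table carries the temporal panels.
* Effect size: 100·(acc − acc_bench)/acc_bench, reported to one decimal;
  undefined at zero benchmark accuracy.
* One master seed fans out to split/fold/grid/sampling child seeds via
  SHA-256 (`attenurank._seeds.child_seed`), so every table is exactly
  reproducible and stages are independently re-runnable.
* Every result row stores its train/test row indices; `audit_leakage`
  verifies train/test disjointness (and the absence of real rows in
  pure-synthetic training) after any run.

## 6. Problem sizes in the test suite

The suite exercises the full stack at sizes chosen to keep runs
comfortable on one CPU while remaining statistically meaningful: moment
recovery at n = 10,000; ranking ledger and planted-signal checks at
n = 1,000; same-distribution fidelity calibration on two disjoint
1,000-row halves; TVAE constraint scans over 10,000 samples from a
41-row-trained model; mixture-recovery at 2,000 rows; and the
evaluation-harness controls over 10 seeds with reduced grids (the controls
test the harness, not grid breadth). Examples use reduced grids and sweeps
for the same reason; the full experiment is a configuration change, not a
code change.

## 7. Known limitations

* The simulator is a stand-in, not a replica: passing tests show the
  pipeline behaves correctly on data *with this structure*, not that the
  original study's data-dependent scores (fidelity percentages, per-target
  accuracies) are reproduced — those depend on the restricted dataset.
* The single-factor correlation structure understates the block structure
  real monitoring data exhibits (e.g. jump metrics inter-correlate beyond
  one factor).
* VAE fidelity at n = 41 is intrinsically noisy; a few continuous columns
  land in the "lower" tier at that size, mirroring the general difficulty
  of synthesizing small tabular samples.
* Binary labels only (no graded attenuation classes); no recovery-timeline
  modeling; no privacy/disclosure metrics for the synthetic data.
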