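# Methods

## Overview

`luminet` implements a neural-network-driven biomarker discovery pipeline
for binary phenotypes in transcriptomic data — the motivating application is
oestrogen-receptor (ER) status in breast cancer — followed by the clinical
statistics used to relate a candidate marker to patient outcome. The
pipeline has four computational stages: single-probe perceptron ranking,
leave-one-out interaction inference, signed network filtering, and cohort
association/survival analysis. A synthetic-data generator with planted
ground truth makes every stage testable without external downloads.

## The perceptron engine

The model is a multilayer perceptron with one hidden layer of two logistic
sigmoid units and a logistic sigmoid output:

    o(x) = σ( b_out + Σ_h w_out[h] · σ( b[h] + Σ_i W[i,h] · x_i ) )

Inputs are probe expression values rescaled per probe to [0, 1] (min → 0,
max → 1; a constant probe maps to 0.5). The per-sample loss is the squared
error (o − y)²; gradients therefore carry a factor 2 relative to the ½-loss
convention, which is equivalent up to a rescaled learning rate.

Training is online back-propagation with heavy-ball momentum
(v ← m·v − η·∇; w ← w + v), with defaults η = 0.1 and m = 0.5. Samples are
visited in a freshly shuffled order each epoch. Weights initialise uniform
in [−0.5, 0.5]. At momentum 0 the update is exactly plain stochastic
gradient descent (asserted against an independent replay in the tests).

**Monte-Carlo cross-validation (MCCV).** Each model run partitions the
samples at random into train/test/validation subsets in proportions
60/20/20 (test and validation sizes are ⌊0.2·n⌋, the remainder trains; 278
samples give 168/55/55). The train subset drives weight updates; the test
subset drives early stopping; the validation subset is never used during
training and its MSE is reported as a held-out figure.

**Early stopping.** After every epoch the test-subset MSE is evaluated.
Training stops at `max_epochs` (default 3000) or once `patience_epochs`
(default 1000) pass without a strictly lower test MSE; the patience window
resets on each improvement. The returned weights are the snapshot at the
best test MSE, not the final-epoch weights, and the stored
`best_test_mse` is exactly the MSE of those snapshot weights.

The inner loop is JIT-compiled (numba); all randomness derives from
explicit integer seeds, so training is bit-reproducible.

## Probe ranking

Each probe is used alone as the input of the perceptron predicting the 0/1
class label. Its score is the mean of the early-stopping best test MSEs
over `n_iterations` MCCV splits (default 50). Crucially, the *same* splits
— and, per split, the same weight initialisation — are shared by all
probes, so scores are directly comparable, identical probes score
identically, and the ranking is invariant to probe ordering. Probes sort
ascending by mean test MSE (lower = more predictive), ties broken
lexicographically by probe ID. `select_panel` takes the top k (default
100) for the network stage.

## Interaction inference

Over a panel of p probes, each probe in turn is the regression target of a
perceptron whose inputs are the remaining p − 1 probes (their scaled [0, 1]
values; the target likewise). For a trained model, the signed influence of
input i on the target is the first-order pathway product

    score_i = Σ_h W[i,h] · w_out[h],

positive read as stimulating, negative as inhibiting. This is the natural
signed summary for a two-hidden-unit sigmoid net and is sign-correct for
monotone dependencies; it is asserted on planted linear structure. Each
target is fitted `n_models` times (default 10), each on a fresh MCCV
split, and entry (i, j) of the interaction matrix is the arithmetic mean
of input i's score across the models for target j. A p-probe panel defines
exactly p·(p−1) directed entries — 9,900 for p = 100. Scores are *not*
renormalised across targets; magnitudes are comparable only within a run.

Inputs are presented in lexicographic probe-ID order and all per-target
randomness is keyed by the target's ID, making the matrix exactly
permutation-equivariant under panel relabelling.

## Network construction

The pair table (both directions of every pair) is filtered *within each
sign class*: the `n_positive` largest positive and `n_negative` most
negative weights are kept (defaults 100 + 100, a top-200 network); ties
break by (|weight| desc, source ID, target ID); a deficit in either sign
class keeps all of it and records a warning. Hubs are nodes with more than
five retained interactions (total degree ≥ 6, each kept edge counted
once). The ego interactome of a focal probe is its k strongest-|weight|
incident edges in either direction. Networks export to SIF
(`activates`/`inhibits`), GraphML (weight/sign attributes) and a
round-trippable edge TSV.

## Cohort statistics

* **H-score**: Σ(intensity × % cells) over staining intensities 0–3,
  range 0–300. Groups: negative (score 0), low (0 < score < 200), high
  (score ≥ 200, strong positivity); present/absent is score > 0. The
  0-boundary for "negative" is the usual immunohistochemistry convention.
* **Association screen**: per marker, a 2×2 (marker absent/present) ×
  (exposure absent/present) table tested with the uncorrected Pearson
  chi-square — no Yates correction, the convention under which the
  packaged reference tables' published statistics reproduce exactly
  (e.g. HER2 6.595 matches only the uncorrected statistic). Degenerate
  markers are reported with a note and skipped, not fatal.
* **Survival**: Kaplan–Meier product-limit curves per group; Mantel–Cox
  log-rank test (df = groups − 1); Cox proportional-hazards regression
  with Efron tie handling and Wald 95% CIs = exp(β ± 1.96·SE). All three
  are backed by lifelines and validated against hand-computed
  product-limit and O−E summation oracles plus parameter-recovery
  simulations.

### Packaged reference tables

The package ships the printed contingency counts of a ~1,000-patient
breast-cancer tissue-microarray cohort relating nuclear DACH1 expression
to 11 clinicopathological factors and 15 biomarkers. 25 of the 26 tables'
published chi-square statistics reproduce to ±0.01 from their own counts;
the "Tumour type" table's published statistic (57.194) is internally
inconsistent with its printed counts, which imply 57.017 — the count-derived
value is what the package computes and asserts.

## Synthetic data generator

**Expression.** Baseline probes are independent standard normals (a
log-intensity-like continuous scale; values are rescaled per probe to
[0, 1] before modelling). Informative probes add a mean shift of
`effect_size` pooled standard deviations to class-1 samples. Panel probes
follow a linear directed-acyclic structural model: edges are sampled
uniformly among forward pairs, coefficients have magnitude uniform in
`edge_coefficient_range` with random sign, and targets are
x_t = Σ coeff·x_s + N(0, noise_sd) (a `nonlinear` switch squashes sources
through tanh). Defaults (500 probes × 200 samples, 118 class-1, i.e. the
~59/41 class balance of a 278-sample ER study; 20 informative probes at
effect size 1.5; a 20-probe panel with 10 edges, |coeff| ∈ [0.5, 1.0],
noise 0.3) are a scaled-down stand-in for a 22,283-probe microarray; the
CLI's `--full-size` flag reproduces the full study shape.

**Cohort.** Exposure (the candidate marker; H-score 0 when absent) is
Bernoulli(1/2). Binary markers are drawn with
logit P(marker) = logit(baseline) + log(OR)·exposure. Event times are
exponential under proportional hazards with baseline median survival at
half the follow-up horizon (default 240 months, so ~50% baseline events
by end of follow-up — a long-follow-up breast-cancer-like regime);
censoring is uniform random on (0, follow-up) with probability
`censor_rate` (default 0.2) plus administrative censoring at follow-up end.

**What the generator does not emulate**: probe-level array artifacts,
normalisation pipelines, correlated biology beyond the planted structure,
informative censoring, or covariate-dependent hazards. Passing tests
demonstrate that the machinery recovers structure it is designed to
recover under clean conditions; they do not certify discovery performance
on real microarray or cohort data.

## Numerical and design choices

* Best-test-MSE snapshotting (not final-epoch weights) is used both for
  ranking scores and for the weights from which interaction scores are
  read.
* "Improvement" for early stopping means strictly lower test MSE; no
  tolerance band.
* Ranking defaults to 50 MCCV reiterations and the network stage to 10
  models per target; both are exposed as parameters.
* Chi-square tables must have positive margins; zero-margin tables raise a
  degenerate-table error (the association screen converts this to a note).
* Filtering drops exactly-zero weights (they carry no sign).
* Test-suite and demo runs use reduced training budgets (tens to a few
  hundred epochs, 2–5 resamples) — the package's demonstration scale; the
  classical settings (3000 epochs, patience 1000, 50 reiterations) remain
  the library defaults.

## Known limitations

* Interaction scores are first-order weight products: adequate for
  monotone dependencies, but a net exploiting strong non-monotone
  structure could receive a misleading sign.
* The inferred "directionality" is bookkeeping (input = source, output =
  target); no causal claim is made, and the matrix is near- but not
  exactly symmetric in information content.
* Magnitudes of interaction scores are run-relative; only within-run
  comparisons (filtering, ranking of edges) are meaningful.
* The survival stage assumes non-informative censoring and proportional
  hazards, matching the generator; violations are not modelled.
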