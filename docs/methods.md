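# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `seroprog`.

## Survival model and primitives

All survival machinery assumes right censoring that is independent of the
event process conditional on covariates, and proportional hazards where a
hazard ratio is reported.

**Harrell's C.** Over pairs (i, j) with `t_i < t_j` and `event_i = 1`, a
pair scores 1 if `risk_i > risk_j`, 0.5 on a risk tie, 0 otherwise; C is
the mean over such pairs. Pairs tied on time are not comparable under the
strict inequality (Harrell's original convention). Inputs with no
comparable pair (everything censored) raise rather than returning a
default. The implementation is vectorized but exactly equals an O(n²) pair
enumeration, which the tests enforce on randomized instances with ties.

**Nelson–Aalen.** Leaf estimator of the survival trees:
`H(t) = Σ_{t_k ≤ t} d_k / n_k` over distinct event times; censored-only
times contribute no increment. Leaves store H evaluated on the forest-wide
grid of training event times, and a leaf's *mortality* is the sum of H over
that grid — the canonical ensemble-mortality risk score. The score's scale
is arbitrary; only its ordering matters, and Harrell's C is invariant to
monotone transforms of it.

**Log-rank splitting.** Nodes split by the standardized two-group log-rank
statistic `(O − E)² / V` summed over the node's distinct event times, with
the hypergeometric variance term zeroed when fewer than two subjects are at
risk. Candidate thresholds are midpoints between consecutive distinct
values of the candidate protein; ties on the statistic resolve to the
lowest feature index, then the lowest threshold, making fits reproducible
bit-for-bit under a fixed seed. The search is implemented twice: a numpy
reference and a numba kernel that maintains O − E and V incrementally as
samples cross the threshold; the two agree to floating-point accuracy and
the compiled path is used when numba is importable.

**Forest.** Bootstrap resampling with out-of-bag (OOB) bookkeeping;
`max_features` candidates drawn without replacement per node; growth stops
at `min_samples_split` / `min_samples_leaf` or when no split has positive
variance. Degenerate parameterizations (e.g. `min_samples_split` larger
than the node) give single-leaf trees whose constant score yields C = 0.5
exactly — used as a null check in the tests.

**Permutation importance.** `mean over repeats of [C(original) −
C(column permuted)]`, evaluated either on supplied data with full-forest
predictions or on the training matrix with OOB predictions
(`use_oob=True`). Whether the original study scored importance on OOB or
held-out folds is not recoverable from its description, so both are
exposed; the pipeline uses OOB. A protein never used in any split has
importance exactly 0 by construction (permuting it cannot alter routing),
and such columns are skipped for speed.

## Preprocessing

Fixed order: sample exclusions → LOD filter → rescale/censor → kNN
imputation. The LOD filter removes proteins with a below-LOD fraction
strictly above 15% (computed over current samples), then samples strictly
above 15% (computed over retained proteins); the sentence order of the
source protocol fixes proteins-first, and whether rescaling preceded the
filters is not stated — filter-first is this package's choice. Rescaling
subtracts the per-protein LOD; values below `LOD − 2·SD(LOD)` become NA.
The meaning of "two standard deviations of the LOD" is ambiguous at the
source (SD across plates? across assays?), so `lod_sd` is a per-protein
input; its default 0 is the conservative reading under which *every*
below-LOD value becomes NA. kNN imputation (k = 5) replaces each NA with
the unweighted mean of the k nearest samples' observed values for that
protein, with distance the Euclidean over proteins observed in both
samples normalized by the shared-protein count (so sparsely observed
samples remain comparable), donors restricted to samples with the target
protein observed, and distance ties broken by sample order.

## Feature-selection cascade

Residualization regresses each protein on the eight-covariate design (age
continuous; categoricals dummy-coded against the first-listed reference
level; dummy columns for levels absent from the cohort are dropped). The
same design builder feeds the multivariable Cox models so the two cannot
drift. A rank-deficient design raises, naming a collinear column set.

The initial "random forest" screen's response variable is unspecified at
the source; this package treats the screen as an untuned survival-forest
pass (500 trees, √p features by default) with permutation importance,
avoiding any censoring-ignoring regression target. The ⌈25%⌉ lowest-median
proteins are dropped per endpoint, and the 20 highest-median retained
proteins go forward.

Tuning samples configurations uniformly from a four-parameter grid
(`n_estimators` 100–1000, `max_features` 2–10, `min_samples_leaf` 3–15,
`min_samples_split` 6–30 by default — source gives no ranges) and scores
each by repeated 5-fold CV on test-fold Harrell's C. RFE orders proteins by
descending median permutation importance and evaluates each top-k set by
repeated k-fold CV under the tuned parameters (re-tuning per k is
supported conceptually but reusing the tuned parameters is the default; the
source is ambiguous). Curve ties resolve to the smallest k (parsimony).

## Cox inference

Classical fits maximize the Efron-ties partial likelihood by
Newton–Raphson (via lifelines; Efron chosen because month-resolution times
produce heavy ties). Because NPX is log2-scaled, `exp(β)` is the HR per
doubling. Non-convergence and monotone likelihoods are flagged, not
silently reported, and flagged fits carry p = 1 into the q-value
computation. q-values are Benjamini–Hochberg step-up with the panel size
m = 92 as the family even when fewer fits converge — the family is the full
assayed panel. Evidence labels: significant P < 0.005, suggestive
0.005 ≤ P < 0.05, weak otherwise (boundaries belong to the weaker class).

Elastic-net Cox uses glmnet-style cyclic coordinate descent
(scikit-survival) on internally standardized columns, with mixing
α = 0.5 by default (the source names elastic nets without a mixing value)
and the penalty chosen by cross-validated Breslow partial-likelihood
deviance. Variable weights for ranking are |standardized coefficient| at
the selected penalty. A pure-ridge request (α = 0) is approximated with a
numerically tiny L1 share because the solver requires one; an all-zero
selected model is reported as such, not as an error.

## Clinicopathological associations

Markers are dichotomized at their median (ties to low, for determinism).
Two-level features use Fisher's exact test with the probability-mass
two-sided p; the reported OR is the cross-product ratio ad/bc with a
Woolf/Haldane interval. Features with ≥3 levels use logistic regression
with marker-high as the outcome and dummy-coded levels as predictors —
the source does not state the model's orientation; marker-as-outcome gives
per-level ORs against a reference of 1, matching the published table
layout. Reference levels are the first-listed category of each feature.
Quasi-separation is flagged on the affected rows.

## Synthetic-cohort generator

The generator emulates the *structure* the analysis assumes, not any real
cohort's distributions (the source reports no distributional facts about
NPX beyond the log2 scale):

- **NPX**: multivariate normal, mean 5, SD 1 NPX units, with block-diagonal
  correlation (default three blocks of 8/8/6 proteins at ρ = 0.5/0.5/0.3);
  optional covariate-linked shifts inject confounding.
- **LOD**: per-protein LOD at a configurable quantile of the protein's
  empirical distribution (default 5%), with a reported LOD-estimate SD
  (default 0.1 NPX). Below-LOD values are *recorded*, not truncated —
  truncation is a downstream preprocessing decision.
- **Covariates**: multinomial draws matching a first-line MBC cohort's
  frequencies (ECOG 0 ≈ 55%, visceral ≈ 59%, CTC ≥ 5 ≈ 51%, ...); age
  normal (65, 10) clipped to 40–90.
- **Outcomes**: Weibull proportional hazards, shape 1.2, OS scale 42 months
  (median OS ≈ 31 months at a null linear predictor, echoing first-line MBC
  survival), PFS scale 12 months. The linear predictor is
  Σ(per-doubling log-HR × centered log2 NPX) + Σ(covariate log-HRs) plus a
  shared Gaussian frailty (SD 0.5, OS/PFS correlation 0.5) so the two
  endpoints' marker sets overlap as they do in real cohorts.
- **Censoring**: independent exponential, rate solved by root-finding so
  the expected censored fraction matches the target; realized fractions
  land within ±5 points for n ≥ 500.
- **Availability**: a configurable fraction of samples is flagged
  unavailable, split 14:5:1 over lost-sample / QC-failure / low-volume
  reasons.

What passing tests on this generator shows: the pipeline recovers planted
per-doubling effects, controls the false-positive rate under the null, and
is deterministic. What it does not show: robustness to non-Gaussian NPX,
plate effects, informative censoring, or covariate-dependent missingness,
none of which the generator produces.

## Problem sizes and profiles

The full protocol (5-fold CV × 100 for tuning, 10-fold CV × 100, RFE at
100 repeats) is the documented `full` profile. The `desk` profile used in
tests and in `scripts/acceptance.py` reduces repeats (5-fold × 1–2, 10-fold
× 1–2, 3-fold RFE, 50–150-tree forests) and is the package's chosen scale
for desk-top verification; repeat counts are configuration values and are
recorded in each run's manifest. Acceptance-style checks use: oracle
equivalence at n ≤ 50 (hundreds of randomized instances), HR recovery at
n = 1500 over 10 seeds, null calibration with 92 proteins over 50 seeds
(25 in the script), and 5-planted-of-92 selection recovery at n = 300.

## Known limitations

- The RSF prediction score is ensemble mortality; other scores (e.g.
  survival probability at a horizon) are not exposed.
- No competing risks, time-varying covariates, tree pruning, or
  proportional-hazards diagnostics; separation in Cox/logistic fits is
  flagged, not repaired (no Firth correction).
- The published OS top-9 and PFS top-10 marker lists overlap in six
  proteins by exact set arithmetic (9 + 10 − 13); `report_overlap` returns
  exact cardinalities.
- Elastic-net tie-breaking near the selected penalty can reorder proteins
  with nearly equal |coefficients| across BLAS builds; rank tables should
  be read with that granularity in mind.
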