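# Methods

## Models and estimation

Two outcome families are supported on low-dimensional covariate subsets
Z = (z₁,…,z_k), k ≪ n.

**Logistic regression.** log{p/(1−p)} = β₀ + βᵀZ, fitted by Newton–Raphson
maximization of the Bernoulli log-likelihood.  The intercept is always
present and never tested or selected.

**Cox proportional hazards.** h(t | Z) = h₀(t) e^{βᵀZ}, fitted by
Newton–Raphson maximization of the partial log-likelihood with **Efron's
approximation** for tied event times (fixed, not configurable: ties occur
in real data, and Efron is the accurate mainstream default).  The model
has no intercept; the empty model is the valid starting point.

Both solvers run *batched*: an insertion scan stacks the C candidate
design matrices into a (C, n, d) array and iterates Newton steps on all
candidates simultaneously, with step halving, warm starts from the parent
model, and an active set that drops candidates as they converge.
Convergence is declared at relative log-likelihood change ≤ 1e−8 within
100 iterations.  Failures are explicit, never silent:

- perfect separation (logistic: fitted probabilities equal to the
  response) and monotone likelihood (Cox: unbounded linear predictor,
  detected as an eta-spread > 250) return `converged=False`;
- rank-deficient designs raise an error naming the offending columns
  (for Cox the check runs on column-centred X, since the partial
  likelihood ignores location);
- in a stepwise scan, a candidate whose augmented fit fails is simply
  ineligible at that step (p treated as 1), with a debug log entry.

**Significance.** Per-coefficient two-sided Wald tests z = β̂ⱼ/SEⱼ from the
observed-information covariance, the convention of standard stepwise
software; one joint fit yields every coefficient's p-value, which the
deletion sweep needs anyway.  −log₁₀ p values are computed on the log
scale (`norm.logsf`), so the p ≈ 1e−30 values produced by strong risk
scores do not underflow.

## Stepwise search

`forward_stepwise` inserts, among the candidates not in the model, the
one with the smallest Wald p-value *in the augmented joint model*
(marginal p-values would ignore the covariates already selected),
provided p < α_in; ties break to the lowest original feature index, so
results are deterministic and independent of candidate order.  After an
insertion the deletion sweep removes covariates with p > α_out one at a
time with refitting (one-at-a-time is the standard behaviour; a
remove-all-at-once variant would differ only in rare near-threshold
constellations).  The just-inserted covariate is protected while others
are deletable, but is itself removed if the deletions push its own
p-value above α_out — this keeps the output certificate unconditional:
every retained coefficient has p ≤ α_out.  Cycling is prevented by
(a) refusing to re-insert a feature just deleted from the identical
model state, (b) stopping if a model state repeats, and (c) a hard
`max_selected` cap (default 30).

Because the first scan of any block is univariate, its p-values do not
depend on block composition; they are computed once per dataset and
cached across all permutations.

## Repeated sieving

`repeated_sieving` partitions the features into contiguous blocks of
m₀ = 50 in permuted order and applies the stepwise search with
(α₁, α₂) = (0.01, 0.02) inside each block.  Design choices:

- the first permutation of each round is the identity (the original
  feature order is itself a legitimate partition; `identity_first=False`
  randomizes it);
- a remainder of m mod m₀ features forms a final smaller block —
  features are never dropped;
- each permutation consumes an independent child stream spawned from the
  master seed, so the pooled union is reproducible and permutations could
  be parallelized without changing output;
- if the pooled union exceeds `pool_cap` (default 1000) and rounds remain
  (`max_rounds`, default 2), the pool is sieved again with the same P and
  thresholds;
- the pool is passed to the final stepwise sorted by original feature
  index, making the final model deterministic given the pool.

The final model uses stricter thresholds: (α₃, α₄) = (0.0025, 0.005) for
binary outcomes and (0.0005, 0.001) for survival outcomes, the values
used throughout the study design.

## Evaluation metrics

Risk scores are r = β̂ᵀZ without intercept (both metrics below are
invariant to location shifts and to any strictly increasing transform).
AUC is the Mann–Whitney version (ties count ½) via scikit-learn.
Harrell's C is implemented directly as vectorized pair counting: a pair
is usable iff the shorter observed time carries an event; concordance
means the shorter-lived subject has the higher score; score ties count ½;
tied event times contribute usable pairs at ½; tied event/censored times
are unusable.  (lifelines' `concordance_index` scores tied times
differently; the definitions coincide on tie-free data, which is the
case for the continuous simulated times, and a tie-free cross-check
against lifelines is part of the test suite.)

## Synthetic data generator

The generator emulates a microarray-style cohort and is the basis of all
quantitative tests:

| parameter | default | meaning |
|---|---|---|
| n | 400 | subjects (split 50–50 into train/validation) |
| m | 10,000 | Gaussian features, unit variance |
| block_len | 20 | independent blocks; within-block equicorrelation ρ |
| rho | 0.2 | compound-symmetry correlation |
| m1 | 6 | true predictors, planted pairwise into m1/2 blocks |
| beta_magnitude | 2.0 / 0.7 | logistic / Cox coefficients, alternating sign |
| baseline_hazard | 0.1 | exponential event-time rate at Z = 0 |
| censor_target | 0.30 | target censoring fraction (0.10 or None supported) |

Features are drawn per block as L·e with L the Cholesky factor of the
20×20 compound-symmetry matrix (ρ ≥ 0 keeps it positive definite; the
config rejects ρ outside [0, 1)).  True features default to the first two
positions of the first m1/2 blocks for reproducibility; randomized
placement is available.  Binary outcomes are Bernoulli with logistic
probability and zero intercept; survival times are exponential with rate
h₀·e^{βᵀz} by inverse transform.

**Censoring calibration.** The accrual window a of the U(0, a) censoring
scheme is solved by Brent root-finding on the marginal censoring fraction
P(T > C).  Because βᵀz is exactly Gaussian under the block design, the
fraction is computed by integrating the uniform censoring time in closed
form — E[(1−e^{−λa})/(λa)] for U(0, a) and E[e^{−λa}(1−e^{−λb})/(λb)] for
U(a, a+b) — and Monte-Carlo averaging over 400,000 fixed-seed draws of
λ = h₀e^{βᵀz}.  The 30% level fixes a; lighter levels (10%) keep that a
and solve for the extra follow-up b.  Calibration is a property of the
DGP, not of a replicate, so it uses its own fixed seed and is cached;
achieved fractions are verified within ±0.01 on independent draws.

Features (covariates), outcome noise, and censoring use independent
streams spawned from the config seed, so two censoring levels run at the
same seed share covariates and latent event times — the paired design the
censoring-direction tests rely on.

**What the generator does not emulate:** non-Gaussian or heavy-tailed
expression distributions, batch effects, long-range correlation,
informative censoring, and non-proportional hazards.  Passing tests show
the pipeline recovers planted sparse signal under the stated Gaussian
block design; they do not certify performance on real microarray data,
which enters only through the generic CSV interface.

## Benchmark comparators

L1 (lasso) and L1+L2 (elastic net) penalized fits on training-standardized
features; coefficients are mapped back to the original scale so risk
scores apply to raw data.  Logistic comparators use scikit-learn's
`LogisticRegressionCV` (liblinear for L1, saga for elastic net) with
10-fold stratified CV minimizing the deviance (`neg_log_loss`), CV-minimum
rule.  Cox comparators use scikit-survival's Coxnet path with 10-fold CV
minimizing the Verweij–van Houwelingen partial-likelihood deviance
−2[ℓ(β̂₋k) − ℓ₋k(β̂₋k)], evaluated with this package's own partial
log-likelihood.  The elastic-net mixing weight is searched on the grid
{0.1, 0.5, 0.9} jointly with λ (a finer grid is a constructor argument;
the 3-point default keeps the saga path affordable).  The selected set is
the features with nonzero penalized coefficients.  An `oracle` method
(unpenalized joint fit on the planted truth) provides an internal upper
benchmark.

## Problem sizes used in the shipped runs

Full scale for the study grid is N = 100 replicates, P = 100 permutations
at m = 10,000 — hours of compute.  The shipped runs use desk scales,
chosen once as the package's own reduced designs:

- `scripts/acceptance.py`: all three arms at m = 10,000, N = 10
  replicates; P = 20 (binary) / 15 (survival) permutations;
- acceptance tests: binary arm at m = 1,000 (N = 4, P = 10); survival
  arms at m = 4,000 (N = 5, P = 8) paired across censoring levels on
  common random numbers; the pooled-candidate-size check runs one
  replicate at the full m = 10,000, P = 20.

At reduced m the selection task is easier (fewer noise features), so
desk-scale runs recover slightly more of the planted signal and higher
validation metrics than the full-scale design; order relations between
methods are unaffected, which is what the tests assert.

## Numerical and degenerate-input conventions

- Insertion requires p strictly below α_in, so α_in = 0 selects nothing.
- An empty candidate list is an error; an all-noise dataset yields an
  empty model with a warning, and its all-zero risk scores score AUC and
  C-index 0.5 (every pair tied) while the univariate-Cox significance of
  a constant score is undefined and reported as missing.
- Logistic fits with k ≥ n or collinear columns are refused rather than
  regularized; the sieve's block size exists precisely to keep k small.
- Survival times must be strictly positive; the event indicator is 0/1.
- Model artifacts are JSON text (feature ids as strings, coefficients,
  family, metadata) — portable and auditable; no binary serialization.

## Known limitations

- Wald-based selection shares the usual weaknesses near separation; the
  solver flags such fits, and the affected candidate is skipped rather
  than rescued (no Firth correction).
- The deletion sweep's one-at-a-time refitting is O(k) fits per
  insertion; with `max_selected` at its default this is negligible.
- Permutations are evaluated serially; the per-permutation RNG streams
  make a parallel implementation output-identical, but none is shipped.
- The two study arms share no variance-reduction machinery beyond seed
  pairing; small-N desk runs retain visible Monte-Carlo error.
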