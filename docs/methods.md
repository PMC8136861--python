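# Methods

## Decision model

A trial is a one-dimensional Wiener process with unit diffusion
coefficient, absorbing bounds at 0 (avoid) and *a* (approach), start
*z·a* and drift *v*; the response time adds a non-decision component
*ndt*.  Fixing the diffusion coefficient at 1 is the scaling
convention for all parameter magnitudes in this package, including the
default generating values.  No inter-trial variability parameters
(sv, sz, st) are included: the trial-level regressions themselves
carry the systematic trial-to-trial variation.

The first-passage density is evaluated with the standard small-time
and large-time series expansions (Navarro–Fuss style accuracy-driven
term counts).  The regime is chosen per evaluation by comparing the
number of terms each expansion needs for truncation error
`WFPT_ERR = 1e-7` (configurable); the upper-bound density is obtained
by the exact reflection v → −v, z → 1 − z.  The trial log-likelihood
is floored at log(1e-12) so samplers remain finite when a proposal
makes a trial's density underflow (e.g. rt ≤ ndt); floor triggers are
counted and reported in the fit diagnostics.

Analytic absorption probabilities,
P(approach) = (1 − e^{−2vza}) / (1 − e^{−2va}) (→ z as v → 0), serve
as an independent oracle for the simulator and likelihood.

## Trial-level regressions

Drift, threshold and starting point are identity-linked linear
functions of the design (see README for the three equations); ndt is a
subject-level constant.  Numerical/representation choices:

- **log(0)**: the log-reward regressor is 0 at zero-reward offers,
  whose offset is absorbed by the dReward dummy.
- **Conflict** is |reward − aversiveness| of the raw offer values,
  z-scored afterwards.
- **Standardization scope** is within subject by default (required for
  ROI betas, whose scale is subject/scanner-specific) and is exposed as
  `ModelSpec.z_scope = "pooled"` for pooled scaling.  Dummies are never
  standardized.  Standardization uses the population (ddof = 0) SD.
- **Admissibility**: a trial whose implied a ≤ 0 or z ∉ (0, 1) has zero
  posterior mass during estimation; during data generation it aborts
  with the offending trial indices.

## Priors and estimation

Intercept-type group means carry weakly informative priors in the
range typical of empirical two-choice RT studies: a ~ N(1.5, 0.75²) on
(0, ∞); ndt ~ N(0.4, 0.35²) on [0, ∞); v ~ N(0, 2²);
z ~ N(0.5, 0.25²) on (0, 1).  Group SDs are Half-Normal(1); slopes are
diffuse N(0, 10²).  All are configurable via `PriorConfig`; the exact
values are stand-ins for toolbox-default empirical priors and none of
the validation results are sensitive to them at the tested scales.

Sampling is adaptive Metropolis-within-Gibbs: componentwise Gaussian
random-walk proposals; scale parameters (group SDs) walk on the log
scale with the appropriate Jacobian.  Because tightly data-constrained
subject intercepts leave the centered sampler unable to move the
population SDs, each iteration additionally performs interweaving
moves per intercept family — a translation of the whole family
together with its group mean, and a rescaling around the mean together
with the group SD, i.e. updates with the subject effects held fixed on
the standardized (non-centered) scale.  Proposal scales adapt toward
their target acceptance rates in batches of 50 iterations during
burn-in only, so post-burn-in draws form a valid Markov chain.  Subject-level
likelihood contributions are cached so a subject-parameter update
costs one subject's trials and a group-slope update one pass over all
trials.  The kernel choice is deliberately unglamorous; correctness is
established by the recovery, null-recovery, shrinkage and
self-consistency oracles in the test suite rather than by the sampler
family.  Chains are initialized from data-informed heuristics (ndt at
0.8 × each subject's minimum RT) plus seed-controlled jitter; runs are
bit-reproducible given (data, spec, seed).

Two chain profiles are provided: the full protocol (5 chains × 5000
samples, 2500 burn-in) and a desk-scale `fast` profile (3 × 1500, 500
burn-in) used throughout the tests and the acceptance script; the
problem sizes quoted below were chosen so the whole validation surface
runs on a single ordinary CPU.

Grouping modes: `separate` (fit one group at a time with identical
priors, compare posteriors afterwards), `mixed` (one fit with a group
dummy and dummy-by-regressor interactions on all three regressions;
the ndt group contrast is absorbed by the subject-level population
rather than parameterized), and `single` (one pooled population; with
`subject_level_slopes=True` every coefficient becomes subject-level —
the classification variant, which exists so per-subject estimates are
not shrunk toward diagnosis-specific means).

Diagnostics: classic Gelman–Rubin R̂ (between/within-chain variance
ratio, threshold 1.1, non-fatal warning), initial-positive-sequence
effective sample size, and DIC = mean deviance + pD with
pD = mean deviance − deviance at the posterior means.  The model
ladder refits the same data under incrementally richer specifications
(linear → log reward, zero-offer dummies, conflict on threshold,
Pavlovian mapping on starting point, ROI regressors) and ranks by DIC.

## Synthetic data

The generator emulates the task: per subject 105 trials over 3 runs,
offers uniform over the 16 × 6 − 1 admissible cells (equal spacing on
[0, 5]; the sampling distribution over cells is not otherwise
constrained, and exact cell balance is impossible at 105 trials), and
a Pavlovian dummy balanced to within one trial.  ROI series are
within-subject z-scored Gaussian noise by default, with opt-in linear
coupling to the offers for regressor-recovery experiments.  Behavior
is simulated from the model itself, so true parameters are known.

Choices made where the emulated study reports none:

- **Between-subject SDs** apply to the four intercept-type parameters
  only (mirroring the estimation hierarchy) and default to a 0.4,
  v 0.6, z 0.05, ndt 0.2 — the order of spread implied by group-mean
  interval widths at ~24 subjects.
- **Simulation step**: trial simulation is Euler–Maruyama; dataset
  generation and posterior predictive replication default to
  dt = 2e-4 s. At dt = 1e-3 the boundary-overshoot bias of discrete
  stepping (≈ 0.58·√dt per bound) inflates recovered thresholds by
  ≈ 0.04 and drift slopes by one to two posterior SDs, which would
  contaminate recovery-based validation. Paths exceeding the 20 s cap
  are resampled (counted), and exhausted retries raise an error naming
  the parameter set.
- **Model-comparison effect sizes** for the ladder validation: conflict
  on threshold 0.182 (a typical healthy-control value) and a Pavlovian
  starting-point shift of 0.05 — large enough to be detectable at
  10 subjects yet within the plausible range for this task family.

What the generator does *not* emulate: BOLD dynamics or LS-S beta
estimation (trial betas are drawn directly), offer-sequence
autocorrelation, post-error slowing, lapses/contaminant RTs, missing
responses, or learning across runs.  Passing recovery tests therefore
demonstrates internal consistency of the pipeline under the model's
own assumptions, not robustness to the violations real data bring.

## Group comparison, PPC, reliability, classification

Posterior group differences pair equal-length pooled draw sequences
elementwise (the shorter resampled with replacement if needed); exact
ties count as half, so p(A>B) + p(B>A) = 1.  HDIs use the
sorted-window method.  The posterior predictive check redraws
parameter vectors from the stored posterior, simulates full datasets
on the observed designs, and compares approach proportions and signed
RTs (avoid decisions negative) in cells of the 6 aversiveness levels ×
6 equal-width reward bins (binning configurable); a cell is covered
when the observed proportion falls in the central 95% of replicated
proportions.  Behavioral group tests are hierarchical Bayesian
logistic (choice) and linear (RT) regressions with subject intercepts,
sampled by the same adaptive scheme.  Test-retest reliability is the
two-way mixed, consistency, single-measures ICC (via pingouin) on
per-subject posterior means.

Classification uses L2-regularized logistic regression with the
strength grid 10^{−3..3}. Within each stratified 30% holdout split the
strength with the best repeated stratified k-fold CV AUC on the
training portion is refit and scored on the held-out subjects; the
reported AUC averages over repeated holdout splits (a single fixed
split is available by setting `n_holdout_splits=1`).  Feature
standardization is fit on training folds only.  Feature importance is
the absolute mean coefficient, descending.  Follow-up transfer freezes
the baseline classifier; remitters (follow-up depression score ≤ 7)
can optionally be rescored as healthy.  The leave-one-subject-out
variant retrains once per follow-up subject with that subject fully
excluded.

## Known limitations

- The wfpt series is evaluated at fixed absolute accuracy (1e-7); for
  extremely small decision times the density underflows to the floor
  rather than to an error.
- Metropolis-within-Gibbs mixes more slowly than gradient-based
  samplers on strongly correlated posteriors; the effective sample
  size diagnostics should be consulted before interpreting tail
  quantities from short chains.
- DIC is reported because it is the conventional criterion for this
  model family; it shares the known weaknesses of plug-in deviance
  penalties (pD can be noisy at small effective sample sizes).
- The classifier defaults (100 × 10-fold CV) are meaningful for
  dozens of subjects; with very small cohorts the fold count is capped
  by the minority class size.
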