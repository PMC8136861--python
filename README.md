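# aacddm — drift-diffusion modeling of approach–avoidance conflict

`aacddm` is a Python package for decomposing approach–avoidance
conflict decisions with an affective drift-diffusion model (DDM) and
for turning the resulting parameters into computational phenotypes.
It is aimed at computational-psychiatry researchers analyzing tasks in
which a participant accepts or rejects a combined offer of reward and
aversiveness (here: 105 trials, 16 reward levels × 6 aversiveness
levels on [0, 5], with a trial-varying push/pull response mapping),
optionally with single-trial estimates of ROI activity (caudate, pACC,
nucleus accumbens, STN).

## Model

Each trial *t* is a Wiener diffusion with unit noise between an avoid
bound at 0 and an approach bound at *a*, starting at *z·a*, drifting at
*v*; choice and RT follow the Wiener first-passage-time (wfpt)
distribution,

    choice, rt_t ~ wfpt(a_t, ndt, z_t, v_t)

with trial-level parameters given by three linear regressions on
z-scored predictors:

    v_t = β0_v + β_rew·log(reward)_t + β_av·avers_t + β_cau·caudate_t + β_pacc·pACC_t
          + β_rew:cau·log(reward)_t·caudate_t + β_av:pacc·avers_t·pACC_t + β_dRew·dReward_t
    a_t = β0_a + β_stn·STN_t + β_conf·|reward−avers|_t + β_conf:stn·|reward−avers|_t·STN_t
    z_t = β0_z + β_pav·Pavlovian_t + β_nacc·NAcc_t + β_nacc:pav·NAcc_t·Pavlovian_t

`dReward` flags zero-reward offers (the log term is 0 there) and
`Pavlovian` flags trials whose response mapping is congruent with
approach (push to approach).  Estimation is hierarchical Bayesian:
intercept-type parameters (*a*, *v*, *z* intercepts and non-decision
time) are per subject with group-level normal populations; slopes are
group-level.  Inference runs an adaptive Metropolis-within-Gibbs
sampler against a numba-compiled wfpt likelihood; convergence is
checked with the Gelman–Rubin statistic (R̂ < 1.1) and model variants
are compared by DIC.  Group effects are posterior differences,
summarized by p(A > B) and 95% highest-density intervals.  A
cross-validated L2-regularized logistic classifier predicts clinical
status from per-subject posterior means obtained from a
single-population fit (preventing shrinkage leakage), and test-retest
reliability uses two-way intraclass correlations.

Because no task data ship with the package, `aacddm.synthetic`
generates complete datasets from the model itself at configurable
group parameters, so every stage is testable by parameter recovery.

## Worked example

Simulate a healthy-control-like and a depressed-like group (12
subjects each) at the package's default group means, fit each group
separately, and compare posteriors:

```python
from aacddm import synthetic, fit_groups, group_difference

groups = [
    synthetic.GroupSpec("HC", synthetic.HC_COEFFS),
    synthetic.GroupSpec("MDD", synthetic.MDD_COEFFS),
]
data = synthetic.generate_dataset(groups, n_subjects_per_group=12, seed=7)
fits = fit_groups(data.trials, n_chains=2, n_samples=1200, burn_in=400, seed=0)

for name in ("drift.reward", "start.intercept", "ndt.intercept"):
    comp = group_difference(fits["HC"][0].get(name), fits["MDD"][0].get(name))
    lo, hi = comp.hdi95
    print(f"{name:16s} HC {comp.mean_a:6.3f}  MDD {comp.mean_b:6.3f}  "
          f"diff HDI [{lo:+.3f}, {hi:+.3f}]  p(HC>MDD) = {comp.p_a_gt_b:.3f}")
```

Output:

```
drift.reward     HC  0.688  MDD  0.615  diff HDI [-0.009, +0.155]  p(HC>MDD) = 0.954
start.intercept  HC  0.513  MDD  0.538  diff HDI [-0.082, +0.020]  p(HC>MDD) = 0.153
ndt.intercept    HC  0.720  MDD  0.679  diff HDI [-0.163, +0.230]  p(HC>MDD) = 0.667
```

The reward-sensitivity difference built into the generating groups
(drift-reward 0.701 vs 0.577) is recovered with p(HC>MDD) = 0.95,
while the other parameters show no credible difference at this sample
size — the pattern the model is designed to detect.

A thin CLI wraps the same functions: `aacddm simulate`, `fit`,
`compare`, `ppc`, `icc`, `classify` (see `aacddm --help`).

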