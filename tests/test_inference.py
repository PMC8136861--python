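"""Tests of the hierarchical sampler, convergence diagnostics and DIC."""

import numpy as np
import pandas as pd
import pytest

from aacddm import FINAL_MODEL, ModelSpec, fit_model, fit_groups, run_model_ladder
from aacddm.ddm import DDMTrialParams, TrialOutcome, trial_loglik
from aacddm.design import CoefficientSet
from aacddm.inference import (
    PosteriorSamples,
    compute_rhat,
    dic_from_deviance,
    default_ladder,
    _rhat_1d,
)
from aacddm.posterior import group_difference, hdi
from aacddm.synthetic import HC_COEFFS, MDD_COEFFS, GroupSpec, generate_dataset


def _dummy_samples(draws_by_name, n_chains):
    any_draws = next(iter(draws_by_name.values()))
    return PosteriorSamples(
        group_draws=draws_by_name,
        subject_draws={},
        subject_ids=[],
        subject_groups=[],
        spec=FINAL_MODEL,
        n_chains=n_chains,
        n_samples=any_draws.shape[1],
        burn_in=0,
        seed=0,
        deviance=np.zeros_like(any_draws),
    )


class TestRhat:
    def test_identical_chains_formula(self):
        """Chains that are exact copies give sqrt((n-1)/n), just below 1."""
        n = 400
        chain = np.random.default_rng(0).standard_normal(n)
        draws = np.stack([chain, chain, chain])
        samples = _dummy_samples({"x": draws}, 3)
        rhat = compute_rhat(samples)["x"]
        assert rhat == pytest.approx(np.sqrt((n - 1) / n), rel=1e-12)

    def test_null_distribution_near_one(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((4, 1000))
        assert _rhat_1d(draws) < 1.05

    def test_gross_nonconvergence_detected(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((2, 1000))
        draws[1] += 5.0  # means shifted by 5 within-chain SDs
        assert _rhat_1d(draws) > 1.1

    def test_single_chain_rejected(self):
        samples = _dummy_samples({"x": np.zeros((1, 100))}, 1)
        with pytest.raises(ValueError, match="2 chains"):
            compute_rhat(samples)


class TestDIC:
    def test_degenerate_posterior(self):
        """All draws identical: pD = 0 and DIC is the deviance at that point."""
        dev = np.full(500, 123.4)
        dic, pd_eff = dic_from_deviance(dev, 123.4)
        assert pd_eff == pytest.approx(0.0)
        assert dic == pytest.approx(123.4)

    def test_conjugate_normal_mean_closed_form(self):
        """Normal-mean model with known variance: pD = n * s^2 / sigma^2 and
        DIC = D(posterior mean) + 2 pD, matched by Monte Carlo."""
        rng = np.random.default_rng(3)
        sigma, n = 1.0, 40
        x = rng.normal(0.3, sigma, size=n)
        post_mean, post_sd = x.mean(), sigma / np.sqrt(n)  # flat prior
        theta = rng.normal(post_mean, post_sd, size=200_000)
        dev = np.array([((x - t) ** 2).sum() / sigma**2 for t in theta[:50_000]])
        dev_at_mean = ((x - post_mean) ** 2).sum() / sigma**2
        dic, pd_eff = dic_from_deviance(dev, dev_at_mean)
        expected_pd = n * post_sd**2 / sigma**2  # = 1 effective parameter
        assert pd_eff == pytest.approx(expected_pd, abs=0.05)
        assert dic == pytest.approx(dev_at_mean + 2 * expected_pd, abs=0.1)

    def test_nonfinite_deviance_rejected(self):
        with pytest.raises(Exception, match="deviance"):
            dic_from_deviance(np.array([np.inf, 1.0]), 1.0)


NULL_COEFFS = CoefficientSet.from_partial(
    threshold={"intercept": 2.244},
    ndt={"intercept": 0.737},
    drift={"intercept": 0.4},
    start={"intercept": 0.536},
)

BEHAVIORAL = ModelSpec(name="behavioral", roi=False)


@pytest.fixture(scope="module")
def null_slope_fit():
    ds = generate_dataset([GroupSpec("G", NULL_COEFFS)], 8, seed=21)
    samples, diag = fit_model(ds.trials, spec=BEHAVIORAL, n_chains=2, n_samples=800, burn_in=300, seed=2)
    return samples, diag


class TestFit:
    def test_determinism_identical_seeds(self):
        ds = generate_dataset([GroupSpec("G", NULL_COEFFS)], 3, seed=22)
        kw = dict(spec=BEHAVIORAL, n_chains=2, n_samples=250, burn_in=100, seed=5)
        s1, _ = fit_model(ds.trials, **kw)
        s2, _ = fit_model(ds.trials, **kw)
        for name in s1.group_draws:
            np.testing.assert_array_equal(s1.group_draws[name], s2.group_draws[name])

    def test_null_slopes_recovered(self, null_slope_fit):
        """Data simulated with all slopes 0: every slope's 95% HDI contains 0."""
        samples, _ = null_slope_fit
        for name in ("drift.reward", "drift.aversiveness", "drift.d_reward", "threshold.conflict", "start.pavlovian"):
            lo, hi = hdi(samples.get(name))
            assert lo <= 0.0 <= hi, name

    def test_constrained_draws_admissible(self, null_slope_fit):
        samples, _ = null_slope_fit
        assert (np.asarray(samples.subject_draws["subject.a"]) > 0).all()
        z = np.asarray(samples.subject_draws["subject.z"])
        assert ((z > 0) & (z < 1)).all()
        assert (np.asarray(samples.subject_draws["subject.ndt"]) >= 0).all()

    def test_shrinkage_toward_group_mean(self, null_slope_fit):
        """Subject drift-intercept posterior means lie between the subject's
        own maximum-likelihood value and the group mean (partial pooling)."""
        samples, _ = null_slope_fit
        ds = generate_dataset([GroupSpec("G", NULL_COEFFS)], 8, seed=21)
        post = samples.subject_means()
        group_mean = samples.get("drift.intercept").mean()
        grid = np.linspace(-1.5, 2.5, 41)
        n_between = 0
        n_informative = 0
        for sid, row in post.iterrows():
            sub = ds.trials[ds.trials["subject_id"] == sid]
            outcomes = [TrialOutcome(int(c), float(r)) for c, r in zip(sub["choice"], sub["rt"])]
            lls = [
                sum(
                    trial_loglik(o, DDMTrialParams(v=v, a=row["subject.a"], z=row["subject.z"], ndt=row["subject.ndt"]))
                    for o in outcomes
                )
                for v in grid
            ]
            mle = grid[int(np.argmax(lls))]
            if abs(mle - group_mean) < 0.15:
                continue  # too close to distinguish pooling direction
            n_informative += 1
            lo, hi = sorted((mle, group_mean))
            if lo - 0.05 <= row["subject.v"] <= hi + 0.05:
                n_between += 1
        assert n_informative >= 3
        assert n_between / n_informative >= 0.75

    def test_validation_errors(self):
        ds = generate_dataset([GroupSpec("G", NULL_COEFFS)], 2, seed=23)
        with pytest.raises(ValueError, match="exceed burn_in"):
            fit_model(ds.trials, n_samples=100, burn_in=100)
        two = generate_dataset([GroupSpec("A", NULL_COEFFS), GroupSpec("B", NULL_COEFFS)], 2, seed=24)
        with pytest.raises(ValueError, match="fit_groups"):
            fit_model(two.trials, spec=BEHAVIORAL, n_chains=2, n_samples=200, burn_in=50)


def test_separate_and_mixed_grouping_agree_on_direction():
    """Separate-group fits and the mixed-effect (group dummy) fit agree on
    the sign and rough size of the drift-reward group difference."""
    hc = GroupSpec("HC", HC_COEFFS, subject_sd={"a": 0.2, "v": 0.3, "z": 0.03, "ndt": 0.1})
    mdd_coeffs = HC_COEFFS.with_intercepts(2.244, 0.665, 0.536, 0.737)
    mdd_coeffs = CoefficientSet(
        threshold=mdd_coeffs.threshold,
        ndt=mdd_coeffs.ndt,
        drift={**mdd_coeffs.drift, "reward": 0.3},
        start=mdd_coeffs.start,
    )
    mdd = GroupSpec("MDD", mdd_coeffs, subject_sd=hc.subject_sd)
    ds = generate_dataset([hc, mdd], 8, seed=25)
    fits = fit_groups(ds.trials, spec=BEHAVIORAL, n_chains=2, n_samples=700, burn_in=300, seed=6)
    sep = group_difference(fits["HC"][0].get("drift.reward"), fits["MDD"][0].get("drift.reward"))
    mixed, _ = fit_model(
        ds.trials,
        spec=BEHAVIORAL.replace(grouping="mixed"),
        n_chains=2,
        n_samples=700,
        burn_in=300,
        seed=7,
    )
    mixed_diff = mixed.get("drift.reward:group")  # HC dummy (alphabetically first)
    sep_mean = sep.diff_draws.mean()
    assert sep_mean > 0 and mixed_diff.mean() > 0
    assert mixed_diff.mean() == pytest.approx(sep_mean, abs=0.25)


def test_ladder_single_member_and_default_shape():
    ds = generate_dataset([GroupSpec("G", NULL_COEFFS)], 3, seed=26)
    table = run_model_ladder(
        ds.trials, [BEHAVIORAL], n_chains=2, n_samples=250, burn_in=100, seed=8
    )
    assert list(table["model"]) == ["behavioral"]
    assert bool(table.loc[0, "best"])
    names = [s.name for s in default_ladder()]
    assert names[0] == "linear-reward" and names[-1] == "final"


def test_ladder_annotates_failures():
    ds = generate_dataset([GroupSpec("G", NULL_COEFFS)], 3, seed=27)
    bad = BEHAVIORAL.replace(name="broken", grouping="nonsense")
    table = run_model_ladder(ds.trials, [bad], n_chains=2, n_samples=250, burn_in=100, seed=9)
    assert table.loc[0, "error"] != ""
    assert np.isnan(table.loc[0, "dic"])
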