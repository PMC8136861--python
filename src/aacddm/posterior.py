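"""Posterior group comparison, predictive checking and reliability.

Group effects are tested in the Bayesian fashion: the posterior
distribution of the difference between two groups' draws, summarized by
p(A > B) (the proportion of difference draws above 0, ties counted as
half) and the 95% highest density interval.  Posterior predictive
checks simulate full datasets from posterior parameter draws on the
observed trial designs and compare choice proportions and signed RT
distributions (avoid decisions carry negative sign) across binned
reward x aversiveness offers.  Test-retest reliability of per-subject
parameter means uses the two-way mixed, consistency, single-measures
intraclass correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import simulate_trials
from .inference import PosteriorSamples, _prepare_arrays

__all__ = [
    "GroupComparison",
    "PPCReport",
    "group_difference",
    "hdi",
    "posterior_predictive_check",
    "behavioral_group_tests",
    "icc_two_way",
    "comparison_table",
]


@dataclass
class GroupComparison:
    """Posterior difference between two groups for one parameter."""

    parameter: str
    diff_draws: np.ndarray
    p_a_gt_b: float
    hdi95: tuple
    mean_a: float
    mean_b: float


def hdi(draws, mass: float = 0.95) -> tuple:
    """Narrowest contiguous interval containing ``mass`` posterior mass.

    Sorted-window method: slide a window of ceil(mass * n) consecutive
    order statistics and return the narrowest.
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("empty draws")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(draws)
    n = x.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return (float(x[0]), float(x[-1]))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + m - 1]))


def group_difference(draws_a, draws_b, parameter: str = "", seed: int = 0) -> GroupComparison:
    """Posterior of (A - B) from two draw sequences.

    Equal-length sequences are paired elementwise; if lengths differ the
    shorter is resampled with replacement to match.  Exact ties count
    as half toward p(A > B), preserving p(A>B) + p(B>A) = 1.
    """
    a = np.asarray(draws_a, dtype=float).reshape(-1)
    b = np.asarray(draws_b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty draws")
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        if a.size < b.size:
            a = rng.choice(a, size=b.size, replace=True)
        else:
            b = rng.choice(b, size=a.size, replace=True)
    diff = a - b
    p = float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))
    return GroupComparison(
        parameter=parameter,
        diff_draws=diff,
        p_a_gt_b=p,
        hdi95=hdi(diff, 0.95),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def comparison_table(
    samples_a: PosteriorSamples, samples_b: PosteriorSamples, label_a="A", label_b="B"
) -> pd.DataFrame:
    """Per-parameter comparison of two separate-group fits.

    One row per shared group-level parameter: group means, 95% HDIs and
    p(A > B) — the layout of a posterior group-parameter table.
    """
    rows = []
    shared = [k for k in samples_a.group_draws if k in samples_b.group_draws and not k.endswith("_sd")]
    for name in shared:
        da, db = samples_a.get(name), samples_b.get(name)
        comp = group_difference(da, db, parameter=name)
        lo_a, hi_a = hdi(da)
        lo_b, hi_b = hdi(db)
        rows.append(
            {
                "parameter": name,
                f"mean_{label_a}": comp.mean_a,
                f"lower_{label_a}": lo_a,
                f"upper_{label_a}": hi_a,
                f"mean_{label_b}": comp.mean_b,
                f"lower_{label_b}": lo_b,
                f"upper_{label_b}": hi_b,
                f"p({label_a}>{label_b})": comp.p_a_gt_b,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior predictive check
# ---------------------------------------------------------------------------


@dataclass
class PPCReport:
    """Observed vs model-generated behavior per offer cell.

    ``cells`` has one row per (aversiveness level x reward bin) with
    observed approach proportion, the posterior-predictive interval of
    the simulated proportion, RT-quantile discrepancies and a coverage
    flag; ``observed_signed_rt`` / ``replicated_signed_rt`` carry the
    signed response times (avoid decisions negative).
    """

    cells: pd.DataFrame
    observed_signed_rt: np.ndarray
    replicated_signed_rt: np.ndarray
    n_replicates: int

    @property
    def fraction_inside(self) -> float:
        return float(self.cells["inside"].mean())


def _trial_params_from_draw(samples, mats, sidx, draw_chain, draw_iter):
    """Per-trial (v, a, z, ndt) implied by one stored posterior draw."""
    sd = samples.subject_draws
    a0 = np.asarray(sd["subject.a"])[draw_chain, draw_iter][sidx]
    v0 = np.asarray(sd["subject.v"])[draw_chain, draw_iter][sidx]
    z0 = np.asarray(sd["subject.z"])[draw_chain, draw_iter][sidx]
    ndt = np.asarray(sd["subject.ndt"])[draw_chain, draw_iter][sidx]
    names_v = [f"drift.{n}" for n in mats["names_v"]]
    names_a = [f"threshold.{n}" for n in mats["names_a"]]
    names_z = [f"start.{n}" for n in mats["names_z"]]

    def slope_vec(names):
        if samples.spec.subject_level_slopes:
            return None  # handled per subject below
        return np.array([np.asarray(samples.group_draws[n])[draw_chain, draw_iter] for n in names])

    if samples.spec.subject_level_slopes:
        bv = np.stack(
            [np.asarray(sd[f"subject.{n}"])[draw_chain, draw_iter] for n in names_v], axis=1
        ) if names_v else np.zeros((len(samples.subject_ids), 0))
        ba = np.stack(
            [np.asarray(sd[f"subject.{n}"])[draw_chain, draw_iter] for n in names_a], axis=1
        ) if names_a else np.zeros((len(samples.subject_ids), 0))
        bz = np.stack(
            [np.asarray(sd[f"subject.{n}"])[draw_chain, draw_iter] for n in names_z], axis=1
        ) if names_z else np.zeros((len(samples.subject_ids), 0))
        v = v0 + np.einsum("tj,tj->t", mats["Xv"], bv[sidx])
        a = a0 + np.einsum("tj,tj->t", mats["Xa"], ba[sidx])
        z = z0 + np.einsum("tj,tj->t", mats["Xz"], bz[sidx])
    else:
        v = v0 + mats["Xv"] @ slope_vec(names_v)
        a = a0 + mats["Xa"] @ slope_vec(names_a)
        z = z0 + mats["Xz"] @ slope_vec(names_z)
    return v, a, z, ndt


def posterior_predictive_check(
    samples: PosteriorSamples,
    data: pd.DataFrame,
    n_replicates: int = 200,
    seed: int = 0,
    n_reward_bins: int = 6,
    dt: float = 2e-4,
    interval: float = 0.95,
) -> PPCReport:
    """Simulate replicated datasets from posterior draws on the observed designs.

    For each replicate a parameter vector is drawn from the stored
    posterior, per-trial DDM parameters are rebuilt on the observed
    design rows, and choices/RTs are simulated.  Cells are the observed
    aversiveness levels crossed with ``n_reward_bins`` equal-width
    reward bins; a cell is covered when the observed approach
    proportion falls inside the central ``interval`` of the replicated
    proportions.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    design, mats, subject_ids, _, choices, rts, sstart = _prepare_arrays(data, samples.spec)
    sidx = np.repeat(np.arange(len(subject_ids)), np.diff(sstart))
    rng = np.random.default_rng(seed)

    reward = design["reward"].to_numpy(dtype=float)
    aversive = design["aversiveness"].to_numpy(dtype=float)
    rew_edges = np.linspace(0.0, 5.0, n_reward_bins + 1)
    rew_bin = np.clip(np.digitize(reward, rew_edges[1:-1]), 0, n_reward_bins - 1)
    av_levels = np.sort(np.unique(aversive))
    av_idx = np.searchsorted(av_levels, aversive)
    cell_ids = av_idx * n_reward_bins + rew_bin
    n_cells = len(av_levels) * n_reward_bins

    obs_signed = np.where(choices == 1, rts, -rts)
    obs_prop = np.full(n_cells, np.nan)
    counts = np.bincount(cell_ids, minlength=n_cells)
    appr = np.bincount(cell_ids, weights=(choices == 1).astype(float), minlength=n_cells)
    nonempty = counts > 0
    obs_prop[nonempty] = appr[nonempty] / counts[nonempty]

    m, n_kept = samples.n_chains, samples.n_kept
    rep_props = np.full((n_replicates, n_cells), np.nan)
    rep_rt_med = np.full((n_replicates, n_cells), np.nan)
    rep_signed_all = []
    for r in range(n_replicates):
        c = int(rng.integers(m))
        it = int(rng.integers(n_kept))
        v, a, z, ndt = _trial_params_from_draw(samples, mats, sidx, c, it)
        ok = (a > 0) & (z > 0) & (z < 1) & (ndt >= 0)
        if not ok.all():
            # a stored draw cannot be inadmissible on its own data; guard anyway
            continue
        sim_choice, sim_rt, _ = simulate_trials(v, a, z, ndt, dt=dt, seed=int(rng.integers(2**31 - 1)))
        signed = np.where(sim_choice == 1, sim_rt, -sim_rt)
        rep_signed_all.append(signed)
        sim_appr = np.bincount(cell_ids, weights=(sim_choice == 1).astype(float), minlength=n_cells)
        rep_props[r, nonempty] = sim_appr[nonempty] / counts[nonempty]
        for cell in np.flatnonzero(nonempty):
            rep_rt_med[r, cell] = np.median(signed[cell_ids == cell])

    alpha = (1.0 - interval) / 2.0
    rows = []
    for cell in range(n_cells):
        if not nonempty[cell]:
            continue
        props = rep_props[:, cell]
        props = props[np.isfinite(props)]
        lo, hi_ = np.quantile(props, [alpha, 1.0 - alpha])
        obs_med = np.median(obs_signed[cell_ids == cell])
        rows.append(
            {
                "aversiveness": av_levels[cell // n_reward_bins],
                "reward_bin": cell % n_reward_bins,
                "n_trials": int(counts[cell]),
                "observed_approach": obs_prop[cell],
                "pp_mean": float(props.mean()),
                "pp_lower": float(lo),
                "pp_upper": float(hi_),
                "inside": bool(lo <= obs_prop[cell] <= hi_),
                "approach_discrepancy": float(obs_prop[cell] - props.mean()),
                "median_signed_rt_obs": float(obs_med),
                "median_signed_rt_rep": float(np.nanmean(rep_rt_med[:, cell])),
            }
        )
    return PPCReport(
        cells=pd.DataFrame(rows),
        observed_signed_rt=obs_signed,
        replicated_signed_rt=np.concatenate(rep_signed_all) if rep_signed_all else np.empty(0),
        n_replicates=n_replicates,
    )


def plot_ppc(report: PPCReport, path=None):
    """Overlay observed and replicated signed-RT histograms and cell proportions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    bins = np.linspace(-6, 6, 61)
    axes[0].hist(report.replicated_signed_rt, bins=bins, density=True, alpha=0.6, label="model", color="tab:red")
    axes[0].hist(report.observed_signed_rt, bins=bins, density=True, histtype="step", label="observed", color="black")
    axes[0].set_xlabel("signed RT (s; avoid < 0)")
    axes[0].legend()
    cells = report.cells
    axes[1].errorbar(
        cells["observed_approach"],
        cells["pp_mean"],
        yerr=[cells["pp_mean"] - cells["pp_lower"], cells["pp_upper"] - cells["pp_mean"]],
        fmt="o",
        ms=4,
        alpha=0.7,
    )
    axes[1].plot([0, 1], [0, 1], "k--", lw=1)
    axes[1].set_xlabel("observed approach proportion")
    axes[1].set_ylabel("replicated approach proportion")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# behavioral group regressions
# ---------------------------------------------------------------------------


def _adaptive_mwg(logpost, x0, n_iter, burn_in, seed, scales):
    """Small componentwise adaptive Metropolis sampler for the GLMs."""
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    d = x.size
    ls = np.log(np.asarray(scales, dtype=float))
    acc = np.zeros(d)
    cur = logpost(x)
    kept = np.empty((n_iter - burn_in, d))
    nbatch = 0
    for it in range(n_iter):
        for j in range(d):
            old = x[j]
            x[j] = old + math.exp(ls[j]) * rng.standard_normal()
            new = logpost(x)
            if np.isfinite(new) and math.log(rng.random()) < new - cur:
                cur = new
                acc[j] += 1
            else:
                x[j] = old
        if (it + 1) % 50 == 0 and it < burn_in:
            nbatch += 1
            delta = min(0.1, 1.0 / math.sqrt(nbatch))
            ls += np.where(acc / 50 > 0.44, delta, -delta)
            acc[:] = 0
        if it >= burn_in:
            kept[it - burn_in] = x
    return kept


def behavioral_group_tests(
    data: pd.DataFrame,
    n_iter: int = 3000,
    burn_in: int = 1000,
    seed: int = 0,
    reference_group: str | None = None,
) -> tuple[GroupComparison, GroupComparison]:
    """Hierarchical Bayesian group regressions of approach rate and RT.

    Choice is modeled by logistic regression and RT by linear
    regression, each with a group effect and subject-level intercepts.
    Returns the group-effect comparisons (reference group minus the
    other; by default the alphabetically first label, so with labels
    HC/MDD the reported probability is p(HC > MDD)).
    """
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise ValueError("behavioral group tests require exactly 2 groups")
    ref = reference_group or groups[0]
    other = [g for g in groups if g != ref][0]
    counts = data.groupby("group")["subject_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per group")

    subs = list(pd.unique(data["subject_id"]))
    sidx = data["subject_id"].map({s: i for i, s in enumerate(subs)}).to_numpy()
    S = len(subs)
    g = (data["group"] == ref).to_numpy(dtype=float)
    y_choice = (data["choice"] == 1).to_numpy(dtype=float)
    y_rt = data["rt"].to_numpy(dtype=float)

    def logistic_logpost(theta):
        b0, bg, log_su = theta[0], theta[1], theta[2]
        u = theta[3:]
        su = math.exp(log_su)
        eta = b0 + bg * g + u[sidx]
        ll = np.sum(y_choice * eta - np.logaddexp(0.0, eta))
        lp = -0.5 * (b0 / 5.0) ** 2 - 0.5 * (bg / 5.0) ** 2
        lp += -0.5 * np.sum((u / su) ** 2) - S * log_su
        lp += -0.5 * (su / 1.0) ** 2 + log_su  # half-normal(1) on su, log-scale jacobian
        return ll + lp

    def linear_logpost(theta):
        b0, bg, log_su, log_sig = theta[0], theta[1], theta[2], theta[3]
        u = theta[4:]
        su, sig = math.exp(log_su), math.exp(log_sig)
        mu = b0 + bg * g + u[sidx]
        resid = y_rt - mu
        n = y_rt.size
        ll = -0.5 * np.sum((resid / sig) ** 2) - n * log_sig
        lp = -0.5 * (b0 / 5.0) ** 2 - 0.5 * (bg / 5.0) ** 2
        lp += -0.5 * np.sum((u / su) ** 2) - S * log_su
        lp += -0.5 * (su / 1.0) ** 2 + log_su
        lp += -0.5 * (sig / 2.0) ** 2 + log_sig
        return ll + lp

    kept_c = _adaptive_mwg(
        logistic_logpost,
        np.concatenate([[0.0, 0.0, math.log(0.5)], np.zeros(S)]),
        n_iter,
        burn_in,
        seed,
        [0.2, 0.3, 0.2] + [0.2] * S,
    )
    kept_l = _adaptive_mwg(
        linear_logpost,
        np.concatenate([[float(y_rt.mean()), 0.0, math.log(0.3), math.log(max(y_rt.std(), 0.1))], np.zeros(S)]),
        n_iter,
        burn_in,
        seed + 1,
        [0.1, 0.15, 0.2, 0.05] + [0.1] * S,
    )
    bg_c = kept_c[:, 1]
    bg_l = kept_l[:, 1]
    approach = GroupComparison(
        parameter=f"approach_rate.group({ref}-{other})",
        diff_draws=bg_c,
        p_a_gt_b=float(np.mean(bg_c > 0) + 0.5 * np.mean(bg_c == 0)),
        hdi95=hdi(bg_c),
        mean_a=float(np.mean(y_choice[g == 1])),
        mean_b=float(np.mean(y_choice[g == 0])),
    )
    rt_comp = GroupComparison(
        parameter=f"rt.group({ref}-{other})",
        diff_draws=bg_l,
        p_a_gt_b=float(np.mean(bg_l > 0) + 0.5 * np.mean(bg_l == 0)),
        hdi95=hdi(bg_l),
        mean_a=float(np.mean(y_rt[g == 1])),
        mean_b=float(np.mean(y_rt[g == 0])),
    )
    return approach, rt_comp


# ---------------------------------------------------------------------------
# test-retest reliability
# ---------------------------------------------------------------------------


def icc_two_way(values_session1, values_session2) -> tuple[float, float]:
    """Two-way mixed, consistency, single-measures intraclass correlation.

    Sessions must be paired (same subjects, same order).  Returns
    (ICC, p-value).
    """
    x1 = np.asarray(values_session1, dtype=float)
    x2 = np.asarray(values_session2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("sessions must be paired 1-D arrays of equal length")
    if x1.size < 3:
        raise ValueError("ICC requires at least 3 paired subjects")
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("missing values in paired sessions")
    import pingouin as pg

    n = x1.size
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "session": np.repeat([1, 2], n),
            "value": np.concatenate([x1, x2]),
        }
    )
    res = pg.intraclass_corr(long, targets="subject", raters="session", ratings="value")
    row = res.loc[res["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
    return float(row["ICC"]), float(row["pval"])
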