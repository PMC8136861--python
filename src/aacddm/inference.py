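"""Hierarchical Bayesian estimation of the trial-level diffusion model.

Model structure
---------------
The four intercept-type parameters (threshold, drift and starting-point
intercepts, and non-decision time) are estimated per subject and drawn
from group-level normal populations; regression slopes (offer terms,
conflict, Pavlovian mapping, ROI activations and their interactions)
are estimated at the group level, reflecting the noisiness of
single-trial neural regressors.  For the classification variant
(``subject_level_slopes``) every coefficient is instead estimated per
subject under a single population distribution, so that unbiased
individual estimates exist for feature extraction.

Priors (all configurable via :class:`PriorConfig`): weakly informative
empirical priors on the intercept-type group means — threshold
N(1.5, 0.75^2) on (0, inf), non-decision time N(0.4, 0.35^2) on
[0, inf), drift N(0, 2^2), starting point N(0.5, 0.25^2) on (0, 1) —
half-normal(1) group SDs and diffuse N(0, 10^2) slope priors.

Sampling
--------
Posterior draws come from an adaptive Metropolis-within-Gibbs sampler
(componentwise Gaussian random-walk proposals whose scales adapt toward
a 0.44 acceptance rate during burn-in only, keeping the post-burn-in
chain Markov).  The trial likelihood is the Wiener first-passage-time
density from :mod:`aacddm.ddm`; trials whose implied parameters leave
the admissible region contribute zero posterior mass, and densities
below the floor contribute log(1e-12).  Correctness is validated by the
parameter-recovery, null-recovery and shrinkage oracles in the test
suite rather than by the choice of kernel.

Diagnostics: Gelman-Rubin potential scale reduction across chains,
effective sample size, and DIC (mean posterior deviance plus the
effective parameter count pD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .ddm import LOG_FLOOR, WFPT_ERR, _wfpt
from .design import FINAL_MODEL, ModelSpec, build_design, build_matrices

__all__ = [
    "PriorConfig",
    "PosteriorSamples",
    "FitDiagnostics",
    "FitError",
    "fit_model",
    "fit_groups",
    "compute_rhat",
    "effective_sample_size",
    "compute_dic",
    "dic_from_deviance",
    "default_ladder",
    "run_model_ladder",
    "FAST_PROFILE",
    "PAPER_PROFILE",
]

#: (n_chains, n_samples, burn_in) — desk-scale profile
FAST_PROFILE = (3, 1500, 500)
#: the full estimation protocol: 5 chains x 5000 samples, 2500 burn-in
PAPER_PROFILE = (5, 5000, 2500)

RHAT_THRESHOLD = 1.1
_INTERCEPT_NAMES = ("threshold.intercept", "drift.intercept", "start.intercept", "ndt.intercept")
_SD_FLOOR = 1e-3


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorConfig:
    """Prior settings for the hierarchical fit (see module docstring)."""

    intercept_mean: tuple = (1.5, 0.0, 0.5, 0.4)  # a, v, z, ndt group means
    intercept_sd: tuple = (0.75, 2.0, 0.25, 0.35)
    intercept_lower: tuple = (0.0, -np.inf, 0.0, 0.0)
    intercept_upper: tuple = (np.inf, np.inf, 1.0, np.inf)
    group_sd_scale: float = 1.0  # half-normal scale of population SDs
    slope_sd: float = 10.0  # diffuse zero-centered slope prior


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _subj_ll(a0, v0, z0, ndt, srow, kv, ka, kz, Xv, Xa, Xz, choices, rts, lo, hi, err):
    """Log likelihood of one subject's trials given intercepts and slope row."""
    if ndt < 0.0:
        return -np.inf
    ll = 0.0
    for t in range(lo, hi):
        v = v0
        a = a0
        z = z0
        for j in range(kv):
            v += srow[j] * Xv[t, j]
        for j in range(ka):
            a += srow[kv + j] * Xa[t, j]
        for j in range(kz):
            z += srow[kv + ka + j] * Xz[t, j]
        if a <= 0.0 or z <= 0.0 or z >= 1.0:
            return -np.inf
        dens = _wfpt(rts[t] - ndt, choices[t], v, a, z, err)
        if dens < 1e-12:
            ll += LOG_FLOOR
        else:
            ll += math.log(dens)
    return ll


@njit(cache=True)
def _total_ll_floor(sp, slopes, subj_rows, kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart, err):
    """Total log likelihood and floored-trial count over all subjects."""
    S = sp.shape[0]
    ll = 0.0
    nfloor = 0
    for s in range(S):
        r = subj_rows[s]
        lo = sstart[s]
        hi = sstart[s + 1]
        for t in range(lo, hi):
            v = sp[s, 1]
            a = sp[s, 0]
            z = sp[s, 2]
            ndt = sp[s, 3]
            for j in range(kv):
                v += slopes[r, j] * Xv[t, j]
            for j in range(ka):
                a += slopes[r, kv + j] * Xa[t, j]
            for j in range(kz):
                z += slopes[r, kv + ka + j] * Xz[t, j]
            if a <= 0.0 or z <= 0.0 or z >= 1.0 or ndt < 0.0:
                ll += LOG_FLOOR
                nfloor += 1
                continue
            dens = _wfpt(rts[t] - ndt, choices[t], v, a, z, err)
            if dens < 1e-12:
                ll += LOG_FLOOR
                nfloor += 1
            else:
                ll += math.log(dens)
    return ll, nfloor


@njit(cache=True)
def _norm_lp(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd)


@njit(cache=True)
def _run_chain(
    choices,
    rts,
    sstart,
    Xv,
    Xa,
    Xz,
    sp,
    hmu,
    hsd,
    slopes,
    smu,
    ssd,
    subject_slopes,
    n_iter,
    burn_in,
    seed,
    pmu,
    psd,
    plo,
    phi,
    sd_scale,
    slope_prior_sd,
    err,
):
    """One MCMC chain; returns kept draws and diagnostics counters."""
    np.random.seed(seed)
    S = sp.shape[0]
    K = slopes.shape[1]
    Seff = slopes.shape[0]
    kv = Xv.shape[1]
    ka = Xa.shape[1]
    kz = Xz.shape[1]
    subj_rows = np.zeros(S, dtype=np.int64)
    if subject_slopes:
        for s in range(S):
            subj_rows[s] = s

    # per-subject likelihood cache
    llc = np.empty(S)
    for s in range(S):
        llc[s] = _subj_ll(
            sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3], slopes[subj_rows[s]],
            kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart[s], sstart[s + 1], err,
        )

    # adaptive proposal log-scales
    ls_sp = np.empty((S, 4))
    for s in range(S):
        ls_sp[s, 0] = math.log(0.15)
        ls_sp[s, 1] = math.log(0.2)
        ls_sp[s, 2] = math.log(0.02)
        ls_sp[s, 3] = math.log(0.02)
    ls_h = np.empty(8)
    for j in range(4):
        ls_h[j] = ls_sp[0, j] - 0.7
        ls_h[4 + j] = math.log(0.1)
    ls_sl = np.full((Seff, K), math.log(0.05))
    for r in range(Seff):
        for j in range(kv + ka, K):
            ls_sl[r, j] = math.log(0.01)  # starting-point slopes live on a narrow scale
    ls_sh = np.full(2 * K, math.log(0.05))
    ls_nc = np.empty(8)
    for j in range(4):
        ls_nc[j] = ls_h[j]  # translation scale starts at the mu-proposal scale
        ls_nc[4 + j] = math.log(0.2)

    acc_sp = np.zeros((S, 4))
    acc_h = np.zeros(8)
    acc_sl = np.zeros((Seff, K))
    acc_sh = np.zeros(2 * K)
    acc_nc = np.zeros(8)
    old_nc = np.empty(S)

    n_kept = n_iter - burn_in
    sp_draws = np.empty((n_kept, S, 4))
    hyper_draws = np.empty((n_kept, 8))
    slope_draws = np.empty((n_kept, Seff, K))
    shyper_draws = np.zeros((n_kept, 2 * K))
    dev_draws = np.empty(n_kept)
    floor_draws = np.zeros(n_kept, dtype=np.int64)

    batch = 50
    nbatch = 0
    cand = np.empty(S)

    for it in range(n_iter):
        # --- subject intercepts --------------------------------------
        for s in range(S):
            for j in range(4):
                x = sp[s, j]
                prop = x + math.exp(ls_sp[s, j]) * np.random.normal()
                sp[s, j] = prop
                new_ll = _subj_ll(
                    sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3], slopes[subj_rows[s]],
                    kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart[s], sstart[s + 1], err,
                )
                logr = (
                    new_ll - llc[s]
                    + _norm_lp(prop, hmu[j], hsd[j])
                    - _norm_lp(x, hmu[j], hsd[j])
                )
                if np.isfinite(logr) and math.log(np.random.random()) < logr:
                    llc[s] = new_ll
                    acc_sp[s, j] += 1.0
                else:
                    sp[s, j] = x

        # --- slopes ---------------------------------------------------
        if subject_slopes:
            for s in range(S):
                for j in range(K):
                    x = slopes[s, j]
                    prop = x + math.exp(ls_sl[s, j]) * np.random.normal()
                    slopes[s, j] = prop
                    new_ll = _subj_ll(
                        sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3], slopes[s],
                        kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart[s], sstart[s + 1], err,
                    )
                    logr = (
                        new_ll - llc[s]
                        + _norm_lp(prop, smu[j], ssd[j])
                        - _norm_lp(x, smu[j], ssd[j])
                    )
                    if np.isfinite(logr) and math.log(np.random.random()) < logr:
                        llc[s] = new_ll
                        acc_sl[s, j] += 1.0
                    else:
                        slopes[s, j] = x
            # slope population hyperparameters
            for j in range(K):
                x = smu[j]
                prop = x + math.exp(ls_sh[j]) * np.random.normal()
                logr = _norm_lp(prop, 0.0, slope_prior_sd) - _norm_lp(x, 0.0, slope_prior_sd)
                for s in range(S):
                    logr += _norm_lp(slopes[s, j], prop, ssd[j]) - _norm_lp(slopes[s, j], x, ssd[j])
                if np.isfinite(logr) and math.log(np.random.random()) < logr:
                    smu[j] = prop
                    acc_sh[j] += 1.0
                # scale parameters walk on the log scale (Jacobian log(prop/x))
                x = ssd[j]
                prop = x * math.exp(math.exp(ls_sh[K + j]) * np.random.normal())
                if prop > _SD_FLOOR:
                    logr = -(prop * prop - x * x) / (2.0 * sd_scale * sd_scale) + math.log(prop / x)
                    for s in range(S):
                        logr += _norm_lp(slopes[s, j], smu[j], prop) - _norm_lp(slopes[s, j], smu[j], x)
                    if np.isfinite(logr) and math.log(np.random.random()) < logr:
                        ssd[j] = prop
                        acc_sh[K + j] += 1.0
        else:
            for j in range(K):
                x = slopes[0, j]
                prop = x + math.exp(ls_sl[0, j]) * np.random.normal()
                slopes[0, j] = prop
                tot_new = 0.0
                ok = True
                for s in range(S):
                    cand[s] = _subj_ll(
                        sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3], slopes[0],
                        kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart[s], sstart[s + 1], err,
                    )
                    if not np.isfinite(cand[s]):
                        ok = False
                        break
                    tot_new += cand[s]
                if ok:
                    logr = (
                        tot_new - llc.sum()
                        + _norm_lp(prop, 0.0, slope_prior_sd)
                        - _norm_lp(x, 0.0, slope_prior_sd)
                    )
                    if math.log(np.random.random()) < logr:
                        llc[:] = cand
                        acc_sl[0, j] += 1.0
                    else:
                        slopes[0, j] = x
                else:
                    slopes[0, j] = x

        # --- intercept population hyperparameters ---------------------
        # several sweeps per iteration: these conditionals touch no trial
        # likelihood, so extra sweeps are nearly free and speed up mixing
        # of the group means and SDs
        for _ in range(3):
          for j in range(4):
            x = hmu[j]
            prop = x + math.exp(ls_h[j]) * np.random.normal()
            if plo[j] < prop < phi[j]:
                logr = _norm_lp(prop, pmu[j], psd[j]) - _norm_lp(x, pmu[j], psd[j])
                for s in range(S):
                    logr += _norm_lp(sp[s, j], prop, hsd[j]) - _norm_lp(sp[s, j], x, hsd[j])
                if np.isfinite(logr) and math.log(np.random.random()) < logr:
                    hmu[j] = prop
                    acc_h[j] += 1.0
            x = hsd[j]
            prop = x * math.exp(math.exp(ls_h[4 + j]) * np.random.normal())
            if prop > _SD_FLOOR:
                logr = -(prop * prop - x * x) / (2.0 * sd_scale * sd_scale) + math.log(prop / x)
                for s in range(S):
                    logr += _norm_lp(sp[s, j], hmu[j], prop) - _norm_lp(sp[s, j], hmu[j], x)
                if np.isfinite(logr) and math.log(np.random.random()) < logr:
                    hsd[j] = prop
                    acc_h[4 + j] += 1.0

        # --- interweaving moves ---------------------------------------
        # Update (group mean, group SD) of each intercept family with the
        # subject effects held fixed on the standardized (non-centered)
        # scale: a translation move shifts the whole family with its mean,
        # a rescaling move contracts/expands it around the mean together
        # with the SD.  These moves decorrelate the population SD from the
        # slowly-moving subject intercepts.
        for j in range(4):
            # translation
            shift = math.exp(ls_nc[j]) * np.random.normal()
            prop_mu = hmu[j] + shift
            if plo[j] < prop_mu < phi[j]:
                tot_new = 0.0
                ok = True
                for s in range(S):
                    sp[s, j] += shift
                    cand[s] = _subj_ll(
                        sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3], slopes[subj_rows[s]],
                        kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart[s], sstart[s + 1], err,
                    )
                    if not np.isfinite(cand[s]):
                        ok = False
                    tot_new += cand[s]
                logr = (
                    tot_new - llc.sum()
                    + _norm_lp(prop_mu, pmu[j], psd[j])
                    - _norm_lp(hmu[j], pmu[j], psd[j])
                )
                if ok and math.log(np.random.random()) < logr:
                    hmu[j] = prop_mu
                    llc[:] = cand
                    acc_nc[j] += 1.0
                else:
                    for s in range(S):
                        sp[s, j] -= shift
            # rescaling (log random walk on the SD, Jacobian log c)
            c = math.exp(math.exp(ls_nc[4 + j]) * np.random.normal())
            prop_sd = hsd[j] * c
            if prop_sd > _SD_FLOOR:
                tot_new = 0.0
                ok = True
                for s in range(S):
                    old_nc[s] = sp[s, j]
                    sp[s, j] = hmu[j] + c * (sp[s, j] - hmu[j])
                    cand[s] = _subj_ll(
                        sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3], slopes[subj_rows[s]],
                        kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart[s], sstart[s + 1], err,
                    )
                    if not np.isfinite(cand[s]):
                        ok = False
                    tot_new += cand[s]
                logr = (
                    tot_new - llc.sum()
                    - (prop_sd * prop_sd - hsd[j] * hsd[j]) / (2.0 * sd_scale * sd_scale)
                    + math.log(c)
                )
                if ok and math.log(np.random.random()) < logr:
                    hsd[j] = prop_sd
                    llc[:] = cand
                    acc_nc[4 + j] += 1.0
                else:
                    for s in range(S):
                        sp[s, j] = old_nc[s]

        # --- adaptation (burn-in only) --------------------------------
        if (it + 1) % batch == 0 and it < burn_in:
            nbatch += 1
            delta = min(0.1, 1.0 / math.sqrt(nbatch))
            for s in range(S):
                for j in range(4):
                    ls_sp[s, j] += delta if acc_sp[s, j] / batch > 0.44 else -delta
                    acc_sp[s, j] = 0.0
            for r in range(Seff):
                for j in range(K):
                    ls_sl[r, j] += delta if acc_sl[r, j] / batch > 0.44 else -delta
                    acc_sl[r, j] = 0.0
            for j in range(8):
                # 3 hyper sweeps per iteration
                ls_h[j] += delta if acc_h[j] / (3.0 * batch) > 0.44 else -delta
                acc_h[j] = 0.0
                ls_nc[j] += delta if acc_nc[j] / batch > 0.3 else -delta
                acc_nc[j] = 0.0
            for j in range(2 * K):
                ls_sh[j] += delta if acc_sh[j] / batch > 0.44 else -delta
                acc_sh[j] = 0.0

        # --- storage --------------------------------------------------
        if it >= burn_in:
            idx = it - burn_in
            sp_draws[idx] = sp
            for j in range(4):
                hyper_draws[idx, j] = hmu[j]
                hyper_draws[idx, 4 + j] = hsd[j]
            slope_draws[idx] = slopes
            if subject_slopes:
                for j in range(K):
                    shyper_draws[idx, j] = smu[j]
                    shyper_draws[idx, K + j] = ssd[j]
            ll, nf = _total_ll_floor(
                sp, slopes, subj_rows, kv, ka, kz, Xv, Xa, Xz, choices, rts, sstart, err
            )
            dev_draws[idx] = -2.0 * ll
            floor_draws[idx] = nf

    return sp_draws, hyper_draws, slope_draws, shyper_draws, dev_draws, floor_draws


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws with chain structure.

    ``group_draws`` maps a parameter name (e.g. ``drift.reward``,
    ``threshold.intercept``, ``start.intercept_sd``) to an array of
    shape (n_chains, n_kept); ``subject_draws`` maps subject-level
    parameter names (``subject.a`` ... and, in the classification
    variant, ``subject.drift.reward`` ...) to (n_chains, n_kept, S).
    """

    group_draws: Mapping[str, np.ndarray]
    subject_draws: Mapping[str, np.ndarray]
    subject_ids: list
    subject_groups: list
    spec: ModelSpec
    n_chains: int
    n_samples: int
    burn_in: int
    seed: int
    deviance: np.ndarray  # (n_chains, n_kept)
    floor_fraction: float = 0.0

    def get(self, name: str) -> np.ndarray:
        """Flattened (all chains pooled) draws for a group-level parameter."""
        return np.asarray(self.group_draws[name]).reshape(-1)

    @property
    def n_kept(self) -> int:
        return self.n_samples - self.burn_in

    def subject_means(self) -> pd.DataFrame:
        """Per-subject posterior means, one row per subject."""
        out = {}
        for name, arr in self.subject_draws.items():
            out[name] = np.asarray(arr).mean(axis=(0, 1))
        df = pd.DataFrame(out, index=pd.Index(self.subject_ids, name="subject_id"))
        df["group"] = self.subject_groups
        return df

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            **{f"g::{k}": v for k, v in self.group_draws.items()},
            **{f"s::{k}": v for k, v in self.subject_draws.items()},
            deviance=self.deviance,
            meta=np.array(
                [self.n_chains, self.n_samples, self.burn_in, self.seed], dtype=np.int64
            ),
            subject_ids=np.array(self.subject_ids, dtype=object),
            subject_groups=np.array(self.subject_groups, dtype=object),
        )


@dataclass
class FitDiagnostics:
    """Convergence and fit-quality summaries of one model fit."""

    rhat: Mapping[str, float]
    ess: Mapping[str, float]
    dic: float | None
    pd_eff: float | None
    floor_triggered: int
    warnings: list = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _prepare_arrays(data: pd.DataFrame, spec: ModelSpec):
    design = build_design(data, z_scope=spec.z_scope)
    design = design.sort_values(["subject_id", "trial"], kind="stable").reset_index(drop=True)
    mats = build_matrices(design, spec)
    subject_ids = list(pd.unique(design["subject_id"]))
    sidx = design["subject_id"].map({s: i for i, s in enumerate(subject_ids)}).to_numpy()
    counts = np.bincount(sidx, minlength=len(subject_ids))
    sstart = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    groups = [design.loc[design["subject_id"] == s, "group"].iloc[0] for s in subject_ids]
    choices = design["choice"].to_numpy(dtype=np.int64)
    rts = design["rt"].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(rts)) or np.any(rts <= 0):
        raise ValueError("all trials must carry a positive response time")
    return design, mats, subject_ids, groups, choices, rts, sstart


def _slope_names(mats) -> list[str]:
    return (
        [f"drift.{n}" for n in mats["names_v"]]
        + [f"threshold.{n}" for n in mats["names_a"]]
        + [f"start.{n}" for n in mats["names_z"]]
    )


def fit_model(
    data,
    spec: ModelSpec = FINAL_MODEL,
    n_chains: int = 5,
    n_samples: int = 5000,
    burn_in: int = 2500,
    seed: int = 0,
    priors: PriorConfig = PriorConfig(),
    profile: str | None = None,
    err: float = WFPT_ERR,
) -> tuple[PosteriorSamples, FitDiagnostics]:
    """Fit the hierarchical model to one population of subjects.

    ``profile`` "fast" (3 chains x 1500 samples, 500 burn-in) or
    "paper" (5 x 5000, 2500) overrides the chain arguments.  For
    separate-groups inference call :func:`fit_groups`; this function
    raises if ``spec.grouping == "separate"`` and the table contains
    more than one group label.
    """
    if profile == "fast":
        n_chains, n_samples, burn_in = FAST_PROFILE
    elif profile == "paper":
        n_chains, n_samples, burn_in = PAPER_PROFILE
    elif profile is not None:
        raise ValueError(f"unknown profile {profile!r}")
    if n_samples <= burn_in:
        raise ValueError("n_samples must exceed burn_in")
    if spec.grouping not in ("separate", "mixed", "single"):
        raise ValueError(f"unknown grouping mode {spec.grouping!r}")
    if isinstance(data, (str,)) or hasattr(data, "__fspath__"):
        data = pd.read_csv(data)
    if spec.grouping == "separate" and data["group"].nunique() > 1:
        raise ValueError(
            "spec.grouping='separate' expects a single-group table; use fit_groups()"
        )

    design, mats, subject_ids, groups, choices, rts, sstart = _prepare_arrays(data, spec)
    S = len(subject_ids)
    Xv, Xa, Xz = mats["Xv"], mats["Xa"], mats["Xz"]
    K = Xv.shape[1] + Xa.shape[1] + Xz.shape[1]
    Seff = S if spec.subject_level_slopes else 1
    slope_names = _slope_names(mats)

    pmu = np.array(priors.intercept_mean)
    psd = np.array(priors.intercept_sd)
    plo = np.array(priors.intercept_lower)
    phi = np.array(priors.intercept_upper)

    min_rt = np.array([rts[sstart[s] : sstart[s + 1]].min() for s in range(S)])

    n_kept = n_samples - burn_in
    sp_all = np.empty((n_chains, n_kept, S, 4))
    hy_all = np.empty((n_chains, n_kept, 8))
    sl_all = np.empty((n_chains, n_kept, Seff, K))
    sh_all = np.empty((n_chains, n_kept, 2 * K))
    dev_all = np.empty((n_chains, n_kept))
    floor_total = 0

    for chain in range(n_chains):
        chain_seed = int((seed * 100003 + 7919 * chain + 13) % (2**31 - 1))
        rng = np.random.default_rng(chain_seed)
        sp = np.empty((S, 4))
        sp[:, 0] = 1.8 + 0.2 * rng.standard_normal(S)
        sp[:, 1] = 0.2 * rng.standard_normal(S)
        sp[:, 2] = np.clip(0.5 + 0.03 * rng.standard_normal(S), 0.35, 0.65)
        sp[:, 3] = np.clip(0.8 * min_rt + 0.02 * rng.standard_normal(S), 0.05, None)
        hmu = sp.mean(axis=0)
        hsd = np.array([0.3, 0.4, 0.05, 0.15])
        slopes = 0.01 * rng.standard_normal((Seff, K))
        smu = np.zeros(K)
        ssd = np.full(K, 0.1)
        out = _run_chain(
            choices,
            rts,
            sstart,
            Xv,
            Xa,
            Xz,
            sp,
            hmu,
            hsd,
            slopes,
            smu,
            ssd,
            bool(spec.subject_level_slopes),
            int(n_samples),
            int(burn_in),
            chain_seed,
            pmu,
            psd,
            plo,
            phi,
            float(priors.group_sd_scale),
            float(priors.slope_sd),
            float(err),
        )
        sp_all[chain], hy_all[chain], sl_all[chain], sh_all[chain], dev_all[chain], fl = out
        floor_total += int(fl.sum())
        if not np.isfinite(dev_all[chain]).all():
            raise FitError(f"non-finite deviance in chain {chain}")

    group_draws: dict[str, np.ndarray] = {}
    for j, name in enumerate(_INTERCEPT_NAMES):
        group_draws[name] = hy_all[:, :, j]
        group_draws[name + "_sd"] = hy_all[:, :, 4 + j]
    if spec.subject_level_slopes:
        for j, name in enumerate(slope_names):
            group_draws[name] = sh_all[:, :, j]
            group_draws[name + "_sd"] = sh_all[:, :, K + j]
    else:
        for j, name in enumerate(slope_names):
            group_draws[name] = sl_all[:, :, 0, j]

    subject_draws: dict[str, np.ndarray] = {
        "subject.a": sp_all[:, :, :, 0],
        "subject.v": sp_all[:, :, :, 1],
        "subject.z": sp_all[:, :, :, 2],
        "subject.ndt": sp_all[:, :, :, 3],
    }
    if spec.subject_level_slopes:
        for j, name in enumerate(slope_names):
            subject_draws[f"subject.{name}"] = sl_all[:, :, :, j]

    n_trials_total = len(rts)
    samples = PosteriorSamples(
        group_draws=group_draws,
        subject_draws=subject_draws,
        subject_ids=subject_ids,
        subject_groups=groups,
        spec=spec,
        n_chains=n_chains,
        n_samples=n_samples,
        burn_in=burn_in,
        seed=seed,
        deviance=dev_all,
        floor_fraction=floor_total / (n_chains * n_kept * n_trials_total),
    )

    rhat = compute_rhat(samples) if n_chains >= 2 else {}
    ess = effective_sample_size(samples)
    dic, pd_eff = _dic_internal(samples, choices, rts, sstart, mats)
    warns = []
    if rhat:
        bad = {k: v for k, v in rhat.items() if v >= RHAT_THRESHOLD}
        if bad:
            warns.append(f"convergence warning: rhat >= {RHAT_THRESHOLD} for {sorted(bad)}")
            warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
    diag = FitDiagnostics(
        rhat=rhat, ess=ess, dic=dic, pd_eff=pd_eff, floor_triggered=floor_total, warnings=warns
    )
    return samples, diag


def fit_groups(data, spec: ModelSpec = FINAL_MODEL, seed: int = 0, **kwargs) -> dict:
    """Fit each group separately with identical priors (separate-groups mode)."""
    if isinstance(data, (str,)) or hasattr(data, "__fspath__"):
        data = pd.read_csv(data)
    out = {}
    for i, (label, sub) in enumerate(sorted(data.groupby("group"))):
        out[label] = fit_model(
            sub.reset_index(drop=True),
            spec=spec.replace(grouping="separate"),
            seed=seed + 1000 * i,
            **kwargs,
        )
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _rhat_1d(draws: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction for (m, n) draws."""
    m, n = draws.shape
    means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0
    vhat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(vhat / W))


def compute_rhat(samples: PosteriorSamples, parameters: Sequence[str] | None = None) -> dict:
    """Gelman-Rubin statistic per group-level parameter (requires >= 2 chains)."""
    if samples.n_chains < 2:
        raise ValueError("rhat requires at least 2 chains")
    names = parameters if parameters is not None else list(samples.group_draws)
    return {name: _rhat_1d(np.asarray(samples.group_draws[name])) for name in names}


def _ess_1d(draws: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    m, n = draws.shape
    rho_sum = 0.0
    for c in range(m):
        x = draws[c] - draws[c].mean()
        var = (x * x).mean()
        if var == 0:
            continue
        acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
        s = 0.0
        for lag in range(1, n):
            pair = acf[lag] + (acf[lag + 1] if lag + 1 < n else 0.0)
            if pair < 0:
                break
            s += acf[lag]
        rho_sum += s
    tau = 1.0 + 2.0 * rho_sum / m
    return float(m * n / max(tau, 1.0))


def effective_sample_size(samples: PosteriorSamples) -> dict:
    return {name: _ess_1d(np.asarray(arr)) for name, arr in samples.group_draws.items()}


def dic_from_deviance(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC and effective parameter count from deviance draws.

    DIC = mean deviance + pD with pD = mean deviance - deviance at the
    posterior means.
    """
    dbar = float(np.mean(deviance_draws))
    if not np.isfinite(dbar) or not np.isfinite(deviance_at_mean):
        raise FitError("non-finite deviance")
    pd_eff = dbar - float(deviance_at_mean)
    return dbar + pd_eff, pd_eff


def _dic_internal(samples, choices, rts, sstart, mats):
    sp_mean = np.stack(
        [np.asarray(samples.subject_draws[f"subject.{k}"]).mean(axis=(0, 1)) for k in ("a", "v", "z", "ndt")],
        axis=1,
    )
    slope_names = (
        [f"drift.{n}" for n in mats["names_v"]]
        + [f"threshold.{n}" for n in mats["names_a"]]
        + [f"start.{n}" for n in mats["names_z"]]
    )
    S = sp_mean.shape[0]
    if samples.spec.subject_level_slopes:
        slopes_mean = np.stack(
            [np.asarray(samples.subject_draws[f"subject.{n}"]).mean(axis=(0, 1)) for n in slope_names],
            axis=1,
        ) if slope_names else np.zeros((S, 0))
        subj_rows = np.arange(S, dtype=np.int64)
    else:
        slopes_mean = np.array([[samples.get(n).mean() for n in slope_names]])
        subj_rows = np.zeros(S, dtype=np.int64)
    Xv, Xa, Xz = mats["Xv"], mats["Xa"], mats["Xz"]
    ll, _ = _total_ll_floor(
        np.ascontiguousarray(sp_mean),
        np.ascontiguousarray(slopes_mean),
        subj_rows,
        Xv.shape[1],
        Xa.shape[1],
        Xz.shape[1],
        Xv,
        Xa,
        Xz,
        choices,
        rts,
        sstart,
        WFPT_ERR,
    )
    return dic_from_deviance(samples.deviance, -2.0 * ll)


def compute_dic(samples: PosteriorSamples, data) -> float:
    """Deviance information criterion of a stored fit on its data."""
    if isinstance(data, (str,)) or hasattr(data, "__fspath__"):
        data = pd.read_csv(data)
    _, mats, _, _, choices, rts, sstart = _prepare_arrays(data, samples.spec)
    dic, _ = _dic_internal(samples, choices, rts, sstart, mats)
    return dic


# ---------------------------------------------------------------------------
# model ladder
# ---------------------------------------------------------------------------


def default_ladder(roi: bool = True) -> list[ModelSpec]:
    """The incremental model-comparison ladder, base model first."""
    base = ModelSpec(
        name="linear-reward",
        log_reward=False,
        d_reward=False,
        d_averse=False,
        conflict_on_threshold=False,
        pavlovian_on_start=False,
        roi=False,
    )
    ladder = [
        base,
        base.replace(name="log-reward", log_reward=True),
        base.replace(name="log-reward+dreward", log_reward=True, d_reward=True),
        base.replace(name="log-reward+dreward+daverse", log_reward=True, d_reward=True, d_averse=True),
        base.replace(name="+conflict", log_reward=True, d_reward=True, conflict_on_threshold=True),
        base.replace(
            name="+pavlovian",
            log_reward=True,
            d_reward=True,
            conflict_on_threshold=True,
            pavlovian_on_start=True,
        ),
    ]
    if roi:
        ladder.append(FINAL_MODEL)
    return ladder


def run_model_ladder(data, ladder: Sequence[ModelSpec] | None = None, **fit_kwargs) -> pd.DataFrame:
    """Fit every spec on the same data and rank by DIC (ascending).

    Failed members are annotated rather than aborting the table.
    """
    ladder = list(ladder) if ladder is not None else default_ladder()
    rows = []
    for spec in ladder:
        try:
            _, diag = fit_model(data, spec=spec, **fit_kwargs)
            rows.append(
                {
                    "model": spec.name,
                    "dic": diag.dic,
                    "pd": diag.pd_eff,
                    "max_rhat": diag.max_rhat if diag.rhat else np.nan,
                    "error": "",
                }
            )
        except Exception as exc:  # annotate, keep going
            rows.append({"model": spec.name, "dic": np.nan, "pd": np.nan, "max_rhat": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("dic", na_position="last").reset_index(drop=True)
    table["best"] = False
    if table["dic"].notna().any():
        table.loc[0, "best"] = True
    return table
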