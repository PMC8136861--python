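"""Wiener diffusion kernel for two-choice approach-avoidance decisions.

Each trial is modeled as a one-dimensional Wiener process with unit
diffusion coefficient, starting at ``z * a`` between an avoid bound at 0
and an approach bound at ``a``, drifting at rate ``v`` (positive toward
approach).  The first bound crossed determines the choice; the response
time is the crossing time plus a non-decision component ``ndt`` covering
stimulus encoding and motor output.

The module provides

* the first-passage-time density (``wfpt_density``) evaluated with the
  standard small-time / large-time series expansions and an
  accuracy-driven term count (truncation error <= ``WFPT_ERR``),
* the closed-form absorption probability (``upper_bound_probability``),
* an Euler-Maruyama trial simulator (``simulate_trial`` /
  ``simulate_trials``), and
* a floored trial log-likelihood (``trial_loglik``) safe for MCMC.

All heavy loops are numba-compiled; the jitted primitives are reused by
the hierarchical sampler in :mod:`aacddm.inference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "APPROACH",
    "AVOID",
    "DDMTrialParams",
    "TrialOutcome",
    "SimulationFailure",
    "wfpt_density",
    "trial_loglik",
    "upper_bound_probability",
    "simulate_trial",
    "simulate_trials",
]

APPROACH = 1  # upper bound
AVOID = 0  # lower bound

#: default truncation error of the series expansions
WFPT_ERR = 1e-7
#: density floor protecting samplers from -inf log likelihood
DENSITY_FLOOR = 1e-12
LOG_FLOOR = math.log(DENSITY_FLOOR)
#: default Euler-Maruyama step (seconds)
DEFAULT_DT = 1e-3
#: cap on a single simulated decision (seconds); trials hitting it are resampled
MAX_DECISION_TIME = 20.0
MAX_RETRIES = 10


class SimulationFailure(RuntimeError):
    """A simulated trial failed to absorb within the time cap after retries."""


@dataclass(frozen=True)
class DDMTrialParams:
    """Decision parameters of a single trial.

    v : drift rate (evidence/s, positive toward approach)
    a : boundary separation (> 0)
    z : relative starting point, fraction of ``a`` in (0, 1)
    ndt : non-decision time (s, >= 0)

    The intra-trial diffusion coefficient is fixed at 1 (scaling
    convention); all parameter magnitudes are on that scale.
    """

    v: float
    a: float
    z: float
    ndt: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.v, self.a, self.z, self.ndt]).all():
            raise ValueError("non-finite DDM parameter")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"relative starting point must lie in (0, 1), got z={self.z}")
        if self.ndt < 0:
            raise ValueError(f"non-decision time must be nonnegative, got ndt={self.ndt}")


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one trial: choice (1 = approach, 0 = avoid) and RT in seconds."""

    choice: int
    rt: float


def _choice_code(choice) -> int:
    if choice in (APPROACH, AVOID):
        return int(choice)
    if isinstance(choice, str):
        key = choice.lower()
        if key == "approach":
            return APPROACH
        if key == "avoid":
            return AVOID
    raise ValueError(f"choice must be 'approach'/'avoid' or 1/0, got {choice!r}")


@njit(cache=True)
def _wfpt_lower(t, v, a, w, err):
    """First-passage density at the lower bound at decision time ``t``.

    Parameters are drift ``v``, separation ``a`` and relative start ``w``.
    Series regime (small- vs large-time) is selected by comparing the
    number of terms each expansion needs for truncation error ``err``.
    """
    if t <= 0.0:
        return 0.0
    tt = t / (a * a)  # time in units of a**2

    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        if ks < math.sqrt(tt) + 1.0:
            ks = math.sqrt(tt) + 1.0
    else:
        ks = 2.0
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        if kl < 1.0 / (math.pi * math.sqrt(tt)):
            kl = 1.0 / (math.pi * math.sqrt(tt))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = K // 2
        p = 0.0
        for k in range(lo, hi + 1):
            y = w + 2.0 * k
            p += y * math.exp(-(y * y) / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        p = 0.0
        for k in range(1, K + 1):
            p += (
                k
                * math.exp(-(k * k) * (math.pi * math.pi) * tt / 2.0)
                * math.sin(k * math.pi * w)
            )
        p *= math.pi
    if p < 0.0:
        p = 0.0

    expo = -v * a * w - v * v * t / 2.0
    if expo < -700.0:
        return 0.0
    return p * math.exp(expo) / (a * a)


@njit(cache=True)
def _wfpt(t_dec, choice, v, a, z, err):
    """Density at decision time ``t_dec`` for the named bound (1 upper, 0 lower).

    The upper-bound density is the lower-bound density after the
    reflection v -> -v, z -> 1 - z.
    """
    if choice == 1:
        return _wfpt_lower(t_dec, -v, a, 1.0 - z, err)
    return _wfpt_lower(t_dec, v, a, z, err)


def wfpt_density(rt: float, choice, params: DDMTrialParams, err: float = WFPT_ERR) -> float:
    """First-passage density of (choice, rt) under ``params``.

    Returns exactly 0 for ``rt <= ndt`` (no decision time has elapsed).
    """
    code = _choice_code(choice)
    t_dec = rt - params.ndt
    if t_dec <= 0:
        return 0.0
    return _wfpt(t_dec, code, params.v, params.a, params.z, err)


def trial_loglik(
    outcome: TrialOutcome,
    params: DDMTrialParams,
    floor: float = DENSITY_FLOOR,
) -> float:
    """Log wfpt density with a floor keeping samplers finite.

    Densities below ``floor`` (including the exact zero at rt <= ndt)
    contribute ``log(floor)``.
    """
    dens = wfpt_density(outcome.rt, outcome.choice, params)
    return math.log(max(dens, floor))


def upper_bound_probability(params: DDMTrialParams) -> float:
    """Closed-form probability of absorption at the approach (upper) bound.

    P = (1 - exp(-2 v z a)) / (1 - exp(-2 v a)) for v != 0, continuously
    extended to ``z`` at v = 0.
    """
    x = 2.0 * params.v * params.a
    if abs(x) < 1e-12:
        return params.z
    return math.expm1(-x * params.z) / math.expm1(-x)


def _simulate_batch(v, a, z, ndt, dt, t_max, max_retries, seed):
    """Euler-Maruyama simulation of one trial per parameter row.

    Vectorized over trials: all still-diffusing paths advance one step
    at a time; absorbed paths are compacted away.  Paths reaching the
    time cap are resampled (counted in ``n_capped``); a choice of -1
    marks exhausted retries for that trial.
    """
    rng = np.random.default_rng(seed)
    n = v.shape[0]
    choices = np.full(n, -1, dtype=np.int64)
    rts = np.full(n, np.nan)
    n_capped = 0
    sq = math.sqrt(dt)
    vdt = v * dt
    pending = np.arange(n)
    for _ in range(max_retries):
        if pending.size == 0:
            break
        idx = pending
        x = z[idx] * a[idx]
        t = 0.0
        while idx.size and t < t_max:
            t += dt
            x += vdt[idx] + sq * rng.standard_normal(idx.size)
            up = x >= a[idx]
            lo = x <= 0.0
            done = up | lo
            if done.any():
                d = idx[done]
                choices[d] = np.where(up[done], 1, 0)
                rts[d] = t + ndt[d]
                keep = ~done
                idx = idx[keep]
                x = x[keep]
        n_capped += idx.size
        pending = idx
    return choices, rts, n_capped


def simulate_trials(
    v,
    a,
    z,
    ndt,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    t_max: float = MAX_DECISION_TIME,
    max_retries: int = MAX_RETRIES,
):
    """Simulate one trial per row of the parameter arrays.

    Returns ``(choices, rts, n_capped)`` where ``n_capped`` counts
    resampled cap-crossing attempts.  Raises :class:`SimulationFailure`
    if any trial exhausts its retries.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = np.ascontiguousarray(v, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    z = np.ascontiguousarray(z, dtype=np.float64)
    ndt = np.ascontiguousarray(ndt, dtype=np.float64)
    if not (v.shape == a.shape == z.shape == ndt.shape):
        raise ValueError("parameter arrays must share a common shape")
    if np.any(a <= 0) or np.any((z <= 0) | (z >= 1)) or np.any(ndt < 0):
        raise ValueError("invalid trial parameters (need a > 0, 0 < z < 1, ndt >= 0)")
    choices, rts, n_capped = _simulate_batch(
        v, a, z, ndt, float(dt), float(t_max), int(max_retries), int(seed) % (2**31)
    )
    if np.any(choices < 0):
        bad = int(np.flatnonzero(choices < 0)[0])
        raise SimulationFailure(
            f"trial {bad} failed to absorb within {t_max}s after {max_retries} retries "
            f"(v={v[bad]:.3f}, a={a[bad]:.3f}, z={z[bad]:.3f}, ndt={ndt[bad]:.3f})"
        )
    return choices, rts, n_capped


def simulate_trial(
    params: DDMTrialParams,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    t_max: float = MAX_DECISION_TIME,
    max_retries: int = MAX_RETRIES,
) -> TrialOutcome:
    """Simulate a single trial by Euler-Maruyama integration."""
    choices, rts, _ = simulate_trials(
        np.array([params.v]),
        np.array([params.a]),
        np.array([params.z]),
        np.array([params.ndt]),
        dt=dt,
        seed=seed,
        t_max=t_max,
        max_retries=max_retries,
    )
    return TrialOutcome(choice=int(choices[0]), rt=float(rts[0]))
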