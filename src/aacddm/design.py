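"""Trial-level design construction and coefficient-to-parameter mapping.

The analysis expresses the three decision parameters of each trial as
linear functions of the offer and of trial-by-trial ROI activity:

* drift rate      v_t = intercept + reward + aversiveness + caudate + pACC
                        + reward:caudate + aversiveness:pACC + dReward
* threshold       a_t = intercept + STN + conflict + conflict:STN
* starting point  z_t = intercept + Pavlovian + accumbens + accumbens:Pavlovian
* non-decision time: a subject-level constant (no trial regressors)

where the reward term is log-transformed (log of the offered points, 0
at a zero offer, with the dReward dummy absorbing the zero-offer
offset), conflict is |reward - aversiveness| on the raw offer scale,
and every non-dummy regressor is z-transformed (within subject by
default).  Links are identity; a trial whose implied a <= 0 or z
outside (0, 1) signals a constraint violation that the sampler treats
as zero posterior mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import DDMTrialParams

__all__ = [
    "CANONICAL_COLUMNS",
    "ROI_COLUMNS",
    "DRIFT_SLOTS",
    "THRESHOLD_SLOTS",
    "START_SLOTS",
    "NDT_SLOTS",
    "CoefficientSet",
    "ModelSpec",
    "FINAL_MODEL",
    "DegenerateDesignError",
    "ConstraintViolation",
    "build_design",
    "build_matrices",
    "compute_trial_params",
    "read_trials",
    "write_trials",
]

#: canonical trial-table column order (one row per trial)
CANONICAL_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "run",
    "trial",
    "reward",
    "aversiveness",
    "pavlovian",
    "choice",
    "rt",
    "caudate",
    "pacc",
    "nacc",
    "stn",
]
ROI_COLUMNS = ["caudate", "pacc", "nacc", "stn"]

# coefficient slots of the full model, one set per regression
DRIFT_SLOTS = (
    "intercept",
    "reward",
    "aversiveness",
    "caudate",
    "pacc",
    "reward:caudate",
    "aversiveness:pacc",
    "d_reward",
)
THRESHOLD_SLOTS = ("intercept", "stn", "conflict", "conflict:stn")
START_SLOTS = ("intercept", "pavlovian", "accumbens", "accumbens:pavlovian")
NDT_SLOTS = ("intercept",)


class DegenerateDesignError(ValueError):
    """A regressor is constant within a standardization scope."""


class ConstraintViolation(ValueError):
    """A trial's implied parameters left the admissible region (a > 0, 0 < z < 1)."""


def _check_slots(name: str, mapping: Mapping[str, float], slots: Sequence[str]) -> dict:
    extra = set(mapping) - set(slots)
    missing = set(slots) - set(mapping)
    if extra or missing:
        raise ValueError(
            f"{name} coefficients must carry exactly the slots {list(slots)}; "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )
    return {k: float(mapping[k]) for k in slots}


@dataclass(frozen=True)
class CoefficientSet:
    """Intercepts and slopes of the three trial-level regressions plus ndt.

    Slot names follow the model's coefficient table exactly (8 drift, 4
    threshold, 4 starting-point and 1 non-decision-time coefficients).
    """

    threshold: Mapping[str, float]
    ndt: Mapping[str, float]
    drift: Mapping[str, float]
    start: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "threshold", _check_slots("threshold", self.threshold, THRESHOLD_SLOTS))
        object.__setattr__(self, "ndt", _check_slots("ndt", self.ndt, NDT_SLOTS))
        object.__setattr__(self, "drift", _check_slots("drift", self.drift, DRIFT_SLOTS))
        object.__setattr__(self, "start", _check_slots("start", self.start, START_SLOTS))

    @classmethod
    def from_partial(cls, threshold=None, ndt=None, drift=None, start=None) -> "CoefficientSet":
        """Build a full set with unspecified slots at 0 (intercepts must be given)."""

        def fill(given, slots):
            out = {s: 0.0 for s in slots}
            out.update(given or {})
            return out

        return cls(
            threshold=fill(threshold, THRESHOLD_SLOTS),
            ndt=fill(ndt, NDT_SLOTS),
            drift=fill(drift, DRIFT_SLOTS),
            start=fill(start, START_SLOTS),
        )

    def with_intercepts(self, a: float, v: float, z: float, ndt: float) -> "CoefficientSet":
        """Copy of this set with the four intercept-type slots replaced."""
        return CoefficientSet(
            threshold={**self.threshold, "intercept": a},
            ndt={"intercept": ndt},
            drift={**self.drift, "intercept": v},
            start={**self.start, "intercept": z},
        )


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model ladder plus estimation structure.

    Component toggles follow the model-comparison ladder: the functional
    form of the reward term, zero-offer dummies, conflict on threshold,
    Pavlovian mapping on starting point, and the four ROI regressors.
    ``grouping`` is "separate" (fit one population), "mixed" (group
    dummy and dummy-by-regressor interactions) or "single" (one pooled
    population; with ``subject_level_slopes`` this is the classification
    variant where every coefficient is estimated per subject).
    """

    name: str = "final"
    log_reward: bool = True
    d_reward: bool = True
    d_averse: bool = False
    conflict_on_threshold: bool = True
    pavlovian_on_start: bool = True
    roi: bool = True
    grouping: str = "separate"
    subject_level_slopes: bool = False
    z_scope: str = "subject"  # standardization scope: "subject" or "pooled"

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


FINAL_MODEL = ModelSpec(name="final")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def build_design(trials: pd.DataFrame, z_scope: str = "subject") -> pd.DataFrame:
    """Construct the standardized trial-level design.

    Adds to a copy of the trial table the candidate regressor columns:
    ``log_reward_z`` (log of the offered reward, 0 at zero offers, then
    z-scored), ``reward_z`` (linear form), ``aversiveness_z``,
    ``conflict_z`` (|reward - aversiveness| of the raw offers, z-scored),
    the dummies ``d_reward``/``d_averse`` and the re-standardized ROI
    regressors.  Standardization is within subject (default) or pooled.

    Raises :class:`DegenerateDesignError` naming subject and column if a
    regressor is constant within its scope.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if z_scope not in ("subject", "pooled"):
        raise ValueError(f"unknown standardization scope {z_scope!r}")
    df = trials.copy()
    bad = (df["reward"] == 0) & (df["aversiveness"] == 0)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} trials offer reward 0 and aversiveness 0")

    reward = df["reward"].to_numpy(dtype=float)
    df["d_reward"] = (reward == 0).astype(float)
    df["d_averse"] = (df["aversiveness"].to_numpy(dtype=float) == 0).astype(float)
    log_reward = np.zeros_like(reward)
    pos = reward > 0
    log_reward[pos] = np.log(reward[pos])
    df["_log_reward"] = log_reward
    df["_conflict"] = np.abs(reward - df["aversiveness"].to_numpy(dtype=float))

    raw_to_z = {
        "_log_reward": "log_reward_z",
        "reward": "reward_z",
        "aversiveness": "aversiveness_z",
        "_conflict": "conflict_z",
        **{c: c for c in ROI_COLUMNS},
    }
    groups = [("pooled", df.index)] if z_scope == "pooled" else list(df.groupby("subject_id").groups.items())
    for raw, out in raw_to_z.items():
        col = df[raw].to_numpy(dtype=float)
        res = np.empty_like(col)
        for label, idx in groups:
            loc = df.index.get_indexer(idx)
            sub = col[loc]
            if np.unique(sub).size < 2:
                raise DegenerateDesignError(
                    f"regressor {out!r} is constant for subject {label!r}"
                )
            res[loc] = _zscore(sub)
        df[out] = res
    return df.drop(columns=["_log_reward", "_conflict"])


def drift_columns(spec: ModelSpec) -> list[tuple[str, tuple]]:
    """(slot name, design column(s)) pairs for the drift regression."""
    rew = "log_reward_z" if spec.log_reward else "reward_z"
    cols = [("reward", (rew,)), ("aversiveness", ("aversiveness_z",))]
    if spec.roi:
        cols += [
            ("caudate", ("caudate",)),
            ("pacc", ("pacc",)),
            ("reward:caudate", (rew, "caudate")),
            ("aversiveness:pacc", ("aversiveness_z", "pacc")),
        ]
    if spec.d_reward:
        cols.append(("d_reward", ("d_reward",)))
    if spec.d_averse:
        cols.append(("d_averse", ("d_averse",)))
    return cols


def threshold_columns(spec: ModelSpec) -> list[tuple[str, tuple]]:
    cols = []
    if spec.roi:
        cols.append(("stn", ("stn",)))
    if spec.conflict_on_threshold:
        cols.append(("conflict", ("conflict_z",)))
    if spec.roi and spec.conflict_on_threshold:
        cols.append(("conflict:stn", ("conflict_z", "stn")))
    return cols


def start_columns(spec: ModelSpec) -> list[tuple[str, tuple]]:
    cols = []
    if spec.pavlovian_on_start:
        cols.append(("pavlovian", ("pavlovian",)))
    if spec.roi:
        cols.append(("accumbens", ("nacc",)))
    if spec.pavlovian_on_start and spec.roi:
        cols.append(("accumbens:pavlovian", ("nacc", "pavlovian")))
    return cols


def _matrix(df: pd.DataFrame, cols: list[tuple[str, tuple]]) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    X = np.empty((n, len(cols)), dtype=np.float64)
    names = []
    for j, (slot, parts) in enumerate(cols):
        col = np.ones(n)
        for p in parts:
            col = col * df[p].to_numpy(dtype=float)
        X[:, j] = col
        names.append(slot)
    return np.ascontiguousarray(X), names


def build_matrices(design: pd.DataFrame, spec: ModelSpec) -> dict:
    """Slope design matrices (intercepts excluded) for the three regressions.

    For ``grouping == "mixed"`` each matrix is augmented with a group
    dummy main effect and dummy-by-regressor interactions, giving a
    direct posterior for each group difference.
    """
    out = {}
    for key, cols in (
        ("v", drift_columns(spec)),
        ("a", threshold_columns(spec)),
        ("z", start_columns(spec)),
    ):
        X, names = _matrix(design, cols)
        if spec.grouping == "mixed":
            g = (design["group"] == sorted(design["group"].unique())[0]).to_numpy(dtype=float)
            blocks = [X, g[:, None]]
            gnames = names + ["group"]
            if X.shape[1]:
                blocks.append(X * g[:, None])
                gnames += [f"{n}:group" for n in names]
            X = np.ascontiguousarray(np.hstack(blocks))
            names = gnames
        out[f"X{key}"] = X
        out[f"names_{key}"] = names
    return out


def compute_trial_params(coeffs: CoefficientSet, row: Mapping[str, float]) -> DDMTrialParams:
    """Map a full coefficient set and one design row to trial parameters.

    ``row`` must expose the standardized regressors of
    :func:`build_design` (``log_reward_z``, ``aversiveness_z``,
    ``conflict_z``, ``d_reward``, ``pavlovian`` and the four ROI
    columns).  Identity links; an inadmissible a or z raises
    :class:`ConstraintViolation` (samplers instead assign such trials
    zero posterior mass).
    """
    d, th, st = coeffs.drift, coeffs.threshold, coeffs.start
    v = (
        d["intercept"]
        + d["reward"] * row["log_reward_z"]
        + d["aversiveness"] * row["aversiveness_z"]
        + d["caudate"] * row["caudate"]
        + d["pacc"] * row["pacc"]
        + d["reward:caudate"] * row["log_reward_z"] * row["caudate"]
        + d["aversiveness:pacc"] * row["aversiveness_z"] * row["pacc"]
        + d["d_reward"] * row["d_reward"]
    )
    a = (
        th["intercept"]
        + th["stn"] * row["stn"]
        + th["conflict"] * row["conflict_z"]
        + th["conflict:stn"] * row["conflict_z"] * row["stn"]
    )
    z = (
        st["intercept"]
        + st["pavlovian"] * row["pavlovian"]
        + st["accumbens"] * row["nacc"]
        + st["accumbens:pavlovian"] * row["nacc"] * row["pavlovian"]
    )
    ndt = coeffs.ndt["intercept"]
    if a <= 0 or not 0 < z < 1:
        raise ConstraintViolation(f"inadmissible trial parameters a={a:.4f}, z={z:.4f}")
    return DDMTrialParams(v=float(v), a=float(a), z=float(z), ndt=float(ndt))


def read_trials(path) -> pd.DataFrame:
    """Read a canonical trial-table CSV."""
    df = pd.read_csv(path)
    missing = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table misses columns {sorted(missing)}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a canonical trial-table CSV."""
    df.to_csv(path, index=False, columns=[c for c in CANONICAL_COLUMNS if c in df.columns])
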