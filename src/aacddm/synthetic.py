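"""Synthetic task designs, ROI series and model-generated behavior.

The generator emulates an approach-avoidance conflict task: 105 trials
over 3 runs, offers drawn from a 16-level reward x 6-level aversiveness
grid on [0, 5] with the (0, 0) cell excluded, and a push/pull response
mapping (the Pavlovian-congruency dummy) counterbalanced across trials.
Per-trial ROI activations (caudate, pACC, accumbens, STN) are generated
directly as within-subject z-scored series — standard normal by
default, with opt-in linear coupling to the offers.  Choices and RTs
are simulated from the drift-diffusion model itself, so the generating
trial parameters are known exactly and downstream estimation can be
validated by parameter recovery.

Default group-mean coefficients (``HC_COEFFS`` / ``MDD_COEFFS``) encode
a healthy-control-like and a depressed-like population; between-subject
variability applies to the four intercept-type parameters only,
mirroring the estimation model's subject-level structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import simulate_trials
from .design import CANONICAL_COLUMNS, ROI_COLUMNS, CoefficientSet, build_design

__all__ = [
    "REWARD_LEVELS",
    "AVERSIVENESS_LEVELS",
    "HC_COEFFS",
    "MDD_COEFFS",
    "DEFAULT_SUBJECT_SD",
    "TaskDesign",
    "GroupSpec",
    "SyntheticDataset",
    "AdmissibilityError",
    "generate_task",
    "generate_roi_signals",
    "generate_dataset",
    "generate_followup",
]

#: 16 equally spaced reward levels and 6 aversiveness levels on [0, 5]
REWARD_LEVELS = np.linspace(0.0, 5.0, 16)
AVERSIVENESS_LEVELS = np.linspace(0.0, 5.0, 6)

#: default group-mean coefficients for the healthy-control-like population
HC_COEFFS = CoefficientSet(
    threshold={"intercept": 2.244, "stn": 0.055, "conflict": 0.182, "conflict:stn": 0.042},
    ndt={"intercept": 0.737},
    drift={
        "intercept": 0.665,
        "reward": 0.701,
        "aversiveness": -0.564,
        "caudate": 0.012,
        "pacc": 0.035,
        "reward:caudate": -0.027,
        "aversiveness:pacc": -0.006,
        "d_reward": -1.105,
    },
    start={"intercept": 0.536, "pavlovian": 0.018, "accumbens": 0.009, "accumbens:pavlovian": -0.001},
)

#: default group-mean coefficients for the depressed-like population
MDD_COEFFS = CoefficientSet(
    threshold={"intercept": 2.259, "stn": 0.058, "conflict": 0.145, "conflict:stn": 0.008},
    ndt={"intercept": 0.661},
    drift={
        "intercept": 0.783,
        "reward": 0.577,
        "aversiveness": -0.571,
        "caudate": -0.035,
        "pacc": 0.100,
        "reward:caudate": 0.014,
        "aversiveness:pacc": -0.017,
        "d_reward": -0.974,
    },
    start={"intercept": 0.497, "pavlovian": -0.014, "accumbens": -0.014, "accumbens:pavlovian": 0.011},
)

#: between-subject SDs of the intercept-type parameters, chosen so that
#: the simulated spread of subject parameters is of the order implied by
#: group-mean uncertainty at n ~ 24 subjects
DEFAULT_SUBJECT_SD = {"a": 0.4, "v": 0.6, "z": 0.05, "ndt": 0.2}


class AdmissibilityError(RuntimeError):
    """Generated trial parameters left the admissible region."""


@dataclass(frozen=True)
class TaskDesign:
    """One subject-session's task layout (no behavior)."""

    n_trials: int
    n_runs: int
    reward_levels: np.ndarray
    aversiveness_levels: np.ndarray
    trials: pd.DataFrame  # columns: run, trial, reward, aversiveness, pavlovian


@dataclass(frozen=True)
class GroupSpec:
    """Generating population: label, mean coefficients and subject-level SDs."""

    label: str
    coefficients: CoefficientSet
    subject_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBJECT_SD))

    def __post_init__(self) -> None:
        missing = {"a", "v", "z", "ndt"} - set(self.subject_sd)
        if missing:
            raise ValueError(f"subject_sd misses entries {sorted(missing)}")
        if any(float(s) < 0 for s in self.subject_sd.values()):
            raise ValueError("subject_sd entries must be nonnegative")


@dataclass
class SyntheticDataset:
    """Generated trials plus the true per-subject generating parameters."""

    trials: pd.DataFrame
    true_params: pd.DataFrame  # one row per subject: group, a, v, z, ndt
    groups: Sequence[GroupSpec]
    seed: int
    session: int = 1
    #: true per-trial decision parameters (aligned with ``trials`` rows)
    trial_params: pd.DataFrame | None = None

    def to_csv(self, directory) -> tuple[Path, Path]:
        """Write the canonical trial CSV and a JSON sidecar of true parameters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        trials_path = directory / f"trials_session{self.session}.csv"
        self.trials.to_csv(trials_path, index=False, columns=CANONICAL_COLUMNS)
        sidecar = {
            "seed": int(self.seed),
            "session": int(self.session),
            "subjects": self.true_params.reset_index().to_dict(orient="records"),
            "group_means": {
                g.label: {
                    "threshold": g.coefficients.threshold,
                    "ndt": g.coefficients.ndt,
                    "drift": g.coefficients.drift,
                    "start": g.coefficients.start,
                    "subject_sd": dict(g.subject_sd),
                }
                for g in self.groups
            },
        }
        params_path = directory / f"true_params_session{self.session}.json"
        params_path.write_text(json.dumps(sidecar, indent=1))
        return trials_path, params_path


def generate_task(n_trials: int = 105, n_runs: int = 3, seed=None, rng=None) -> TaskDesign:
    """Sample a task design: offers uniform over the admissible grid cells.

    The (reward = 0, aversiveness = 0) cell is excluded and the
    Pavlovian mapping dummy is balanced to within one trial.
    """
    if n_trials < 1 or n_runs < 1:
        raise ValueError("n_trials and n_runs must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cells = [
        (r, a)
        for r in REWARD_LEVELS
        for a in AVERSIVENESS_LEVELS
        if not (r == 0.0 and a == 0.0)
    ]
    idx = rng.integers(0, len(cells), size=n_trials)
    reward = np.array([cells[i][0] for i in idx])
    aversive = np.array([cells[i][1] for i in idx])
    pav = np.zeros(n_trials, dtype=int)
    pav[: n_trials // 2] = 1
    rng.shuffle(pav)
    run = np.concatenate([np.full(len(chunk), i + 1) for i, chunk in enumerate(np.array_split(np.arange(n_trials), n_runs))])
    trials = pd.DataFrame(
        {
            "run": run,
            "trial": np.arange(1, n_trials + 1),
            "reward": reward,
            "aversiveness": aversive,
            "pavlovian": pav,
        }
    )
    return TaskDesign(
        n_trials=n_trials,
        n_runs=n_runs,
        reward_levels=REWARD_LEVELS.copy(),
        aversiveness_levels=AVERSIVENESS_LEVELS.copy(),
        trials=trials,
    )


def generate_roi_signals(
    design: TaskDesign,
    coupling: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 1.0,
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Per-trial ROI activations, z-scored across the design's trials.

    ``coupling`` optionally maps an ROI to offer weights, e.g.
    ``{"caudate": {"reward": 0.5}}`` adds 0.5 x the z-scored reward to
    the caudate series before Gaussian noise of scale ``noise_sd`` and
    final standardization (mean 0, sd 1).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if design.n_trials == 0 or len(design.trials) == 0:
        raise ValueError("empty task design")
    rng = rng if rng is not None else np.random.default_rng(seed)
    coupling = coupling or {}
    unknown = set(coupling) - set(ROI_COLUMNS)
    if unknown:
        raise ValueError(f"unknown ROI names in coupling: {sorted(unknown)}")

    def z(x):
        x = np.asarray(x, dtype=float)
        return (x - x.mean()) / x.std()

    out = {}
    for roi in ROI_COLUMNS:
        raw = rng.normal(0.0, noise_sd, size=design.n_trials)
        w = coupling.get(roi, {})
        if "reward" in w:
            raw = raw + w["reward"] * z(design.trials["reward"])
        if "aversiveness" in w:
            raw = raw + w["aversiveness"] * z(design.trials["aversiveness"])
        out[roi] = z(raw)
    return pd.DataFrame(out)


def _draw_intercepts(coeffs: CoefficientSet, subject_sd: Mapping[str, float], rng) -> dict:
    """Draw one subject's intercepts around the group means.

    Redraws (up to 1000 times) until the baseline parameters are
    admissible (a > 0, z in (0, 1), ndt > 0).
    """
    means = {
        "a": coeffs.threshold["intercept"],
        "v": coeffs.drift["intercept"],
        "z": coeffs.start["intercept"],
        "ndt": coeffs.ndt["intercept"],
    }
    for _ in range(1000):
        draw = {k: means[k] + float(subject_sd[k]) * rng.standard_normal() for k in means}
        if draw["a"] > 0 and 0 < draw["z"] < 1 and draw["ndt"] > 0:
            return draw
    raise AdmissibilityError("could not draw admissible subject intercepts")


def generate_dataset(
    groups: Sequence[GroupSpec],
    n_subjects_per_group: int,
    n_trials: int = 105,
    n_runs: int = 3,
    seed: int = 0,
    session: int = 1,
    roi_coupling=None,
    roi_noise_sd: float = 1.0,
    dt: float = 2e-4,
    subject_intercepts: Mapping[str, Mapping[str, float]] | None = None,
) -> SyntheticDataset:
    """Generate a full multi-subject dataset from the model.

    Per subject: a fresh task design and ROI series, subject intercepts
    drawn around the group means (or taken from ``subject_intercepts``
    keyed by subject id, as for a follow-up session), per-trial DDM
    parameters from the standardized design, and choices/RTs simulated
    by Euler-Maruyama integration of the diffusion.

    Raises :class:`AdmissibilityError` with the offending trial indices
    if any implied a_t <= 0 or z_t outside (0, 1).
    """
    if n_subjects_per_group <= 0:
        raise ValueError("n_subjects_per_group must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    true_rows = []
    tp_rows = []
    for group in groups:
        for i in range(n_subjects_per_group):
            sid = f"{group.label}{i:03d}"
            task = generate_task(n_trials=n_trials, n_runs=n_runs, rng=rng)
            roi = generate_roi_signals(task, coupling=roi_coupling, noise_sd=roi_noise_sd, rng=rng)
            if subject_intercepts is not None:
                icpt = dict(subject_intercepts[sid])
            else:
                icpt = _draw_intercepts(group.coefficients, group.subject_sd, rng)
            coeffs = group.coefficients.with_intercepts(icpt["a"], icpt["v"], icpt["z"], icpt["ndt"])

            df = task.trials.copy()
            df.insert(0, "subject_id", sid)
            df.insert(1, "group", group.label)
            df.insert(2, "session", session)
            for c in ROI_COLUMNS:
                df[c] = roi[c].to_numpy()
            df["choice"] = 0
            df["rt"] = np.nan
            designed = build_design(df, z_scope="subject")

            d, th, st = coeffs.drift, coeffs.threshold, coeffs.start
            col = lambda name: designed[name].to_numpy(dtype=float)  # noqa: E731
            v = (
                d["intercept"]
                + d["reward"] * col("log_reward_z")
                + d["aversiveness"] * col("aversiveness_z")
                + d["caudate"] * col("caudate")
                + d["pacc"] * col("pacc")
                + d["reward:caudate"] * col("log_reward_z") * col("caudate")
                + d["aversiveness:pacc"] * col("aversiveness_z") * col("pacc")
                + d["d_reward"] * col("d_reward")
            )
            a = (
                th["intercept"]
                + th["stn"] * col("stn")
                + th["conflict"] * col("conflict_z")
                + th["conflict:stn"] * col("conflict_z") * col("stn")
            )
            zz = (
                st["intercept"]
                + st["pavlovian"] * col("pavlovian")
                + st["accumbens"] * col("nacc")
                + st["accumbens:pavlovian"] * col("nacc") * col("pavlovian")
            )
            bad = np.flatnonzero((a <= 0) | (zz <= 0) | (zz >= 1))
            if bad.size:
                raise AdmissibilityError(
                    f"subject {sid}: inadmissible trial parameters at trials {list(bad + 1)}"
                )
            ndt = np.full(n_trials, icpt["ndt"])
            sim_seed = int(rng.integers(0, 2**31 - 1))
            choices, rts, _ = simulate_trials(v, a, zz, ndt, dt=dt, seed=sim_seed)
            df["choice"] = choices
            df["rt"] = rts
            rows.append(df[CANONICAL_COLUMNS])
            true_rows.append({"subject_id": sid, "group": group.label, **icpt})
            tp_rows.append(
                pd.DataFrame(
                    {"subject_id": sid, "trial": df["trial"].to_numpy(), "v": v, "a": a, "z": zz, "ndt": ndt}
                )
            )
    trials = pd.concat(rows, ignore_index=True)
    true_params = pd.DataFrame(true_rows).set_index("subject_id")
    return SyntheticDataset(
        trials=trials,
        true_params=true_params,
        groups=list(groups),
        seed=int(seed),
        session=session,
        trial_params=pd.concat(tp_rows, ignore_index=True),
    )


def generate_followup(dataset: SyntheticDataset, seed: int, session: int = 2, **kwargs) -> SyntheticDataset:
    """Second-session dataset for the same subjects.

    Subject intercepts are carried over from ``dataset`` (stable
    individual traits); the task design, ROI noise and diffusion noise
    are redrawn, emulating a re-test.
    """
    n_per_group = dataset.true_params.groupby("group").size()
    n = int(n_per_group.iloc[0])
    if not (n_per_group == n).all():
        raise ValueError("follow-up generation requires equal group sizes")
    intercepts = {
        sid: {k: float(row[k]) for k in ("a", "v", "z", "ndt")}
        for sid, row in dataset.true_params.iterrows()
    }
    return generate_dataset(
        dataset.groups,
        n_subjects_per_group=n,
        seed=seed,
        session=session,
        subject_intercepts=intercepts,
        **kwargs,
    )
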