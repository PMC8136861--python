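"""Classification of clinical status from individual computational parameters.

Per-subject features are posterior means from a single-population fit
in which every regression coefficient is estimated at the subject level
— fitting one pooled population (no group labels) prevents the
classifier from exploiting hierarchical shrinkage toward group means,
which would leak diagnosis into the features.  Three feature sets are
supported: the full computational set including ROI-modulation terms
(``computational+neural``), the same without ROI terms
(``computational``), and raw behavioral/ROI summaries
(``behavioral+roi``: mean RT, approach rate, mean ROI activation).

The classifier is L2-regularized logistic regression.  The
regularization strength is selected by repeated stratified k-fold
cross-validation on the training portion of a stratified holdout
split; the selected configuration is refit and scored on the held-out
30% by ROC AUC.  Feature standardization always uses training-fold
statistics only.  Follow-up transfer freezes the baseline classifier;
the leave-one-subject-out variant retrains with the predicted subject
excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .design import ROI_COLUMNS
from .inference import PosteriorSamples

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "BiasProtectionError",
    "SchemaError",
    "C_GRID",
    "extract_features",
    "train_and_evaluate",
    "transfer_evaluate",
    "leave_one_subject_out",
    "pairwise_auc",
    "REMITTER_THRESHOLD",
]

#: L2 regularization grid (inverse strength)
C_GRID = tuple(10.0**k for k in range(-3, 4))
#: follow-up depression score at or below which a subject counts as remitted
REMITTER_THRESHOLD = 7.0

_ROI_TOKENS = ("stn", "caudate", "pacc", "accumbens")


class BiasProtectionError(ValueError):
    """Computational features were requested from a group-labeled fit."""


class SchemaError(ValueError):
    """Feature tables disagree on their feature columns."""


@dataclass
class FeatureTable:
    """One row per subject: features, diagnosis label and feature-set id."""

    features: pd.DataFrame  # index subject_id
    labels: pd.Series  # {"MDD", "HC"}-style labels aligned with features
    feature_set: str
    extra: pd.DataFrame | None = None  # e.g. follow-up symptom scores

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the subject index")


@dataclass
class ClassifierReport:
    """Cross-validation and held-out performance of one trained classifier."""

    auc: float  # mean held-out AUC over splits
    auc_per_split: np.ndarray
    best_c: float
    cv_table: pd.DataFrame  # mean CV AUC per regularization strength
    coefficients: pd.Series  # mean standardized coefficients (plus intercept)
    importance: list  # feature names sorted by |coefficient|, descending
    model: Pipeline  # frozen pipeline refit on the full table
    feature_names: list
    classes: list


def extract_features(
    samples: PosteriorSamples | None,
    mode: str,
    data: pd.DataFrame | None = None,
) -> FeatureTable:
    """Assemble the per-subject feature table for one feature-set id.

    Computational modes require a fit with ``grouping='single'`` and
    subject-level coefficients; supplying a group-labeled fit raises
    :class:`BiasProtectionError`.  ``behavioral+roi`` needs the trial
    table instead.
    """
    if mode == "behavioral+roi":
        if data is None:
            raise ValueError("behavioral+roi features need the trial table")
        per = data.groupby("subject_id")
        feats = pd.DataFrame(
            {
                "mean_rt": per["rt"].mean(),
                "approach_rate": per["choice"].apply(lambda c: float((c == 1).mean())),
                **{f"mean_{roi}": per[roi].mean() for roi in ROI_COLUMNS},
            }
        )
        labels = per["group"].first()
        return FeatureTable(features=feats, labels=labels.rename("label"), feature_set=mode)

    if mode not in ("computational+neural", "computational"):
        raise ValueError(f"unknown feature set {mode!r}")
    if samples is None:
        raise ValueError("computational features need a posterior fit")
    if samples.spec.grouping != "single" or not samples.spec.subject_level_slopes:
        raise BiasProtectionError(
            "computational features must come from a single-population fit with "
            "subject-level coefficients (shrinkage toward group means leaks labels)"
        )
    means = samples.subject_means()
    labels = means.pop("group").rename("label")
    feats = means.rename(columns=lambda c: c.removeprefix("subject."))
    if mode == "computational":
        keep = [c for c in feats.columns if not any(tok in c for tok in _ROI_TOKENS)]
        feats = feats[keep]
    return FeatureTable(features=feats, labels=labels, feature_set=mode)


def pairwise_auc(scores, labels, positive) -> float:
    """AUC by brute-force pairwise comparison.

    The probability that a randomly drawn positive scores above a
    randomly drawn negative, ties counting half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes for AUC")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def _make_pipeline(c: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=c, solver="lbfgs", max_iter=2000)),  # L2 penalty
        ]
    )


def _positive_label(labels: pd.Series) -> str:
    # score the clinical class when present, else the lexically last label
    uniq = sorted(pd.unique(labels))
    return "MDD" if "MDD" in uniq else uniq[-1]


def train_and_evaluate(
    table: FeatureTable,
    n_repeats: int = 100,
    k: int = 10,
    holdout_fraction: float = 0.3,
    seed: int = 0,
    n_holdout_splits: int = 10,
    c_grid: Sequence[float] = C_GRID,
) -> ClassifierReport:
    """Train, select and evaluate the regularized logistic classifier.

    For each of ``n_holdout_splits`` stratified holdout splits: the
    regularization strength with the highest mean AUC under repeated
    stratified k-fold cross-validation on the training portion is
    refit on that portion and scored on the held-out fraction.  The
    reported AUC is the mean over splits; the frozen ``model`` is the
    best configuration refit on the full table (used for transfer).
    """
    X = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 subjects each")
    pos = _positive_label(table.labels)

    splitter = StratifiedShuffleSplit(
        n_splits=n_holdout_splits, test_size=holdout_fraction, random_state=seed
    )
    auc_per_split = []
    coefs = []
    cv_rows = {c: [] for c in c_grid}
    best_cs = []
    for split_i, (tr, te) in enumerate(splitter.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        k_eff = min(k, int(np.unique(ytr, return_counts=True)[1].min()))
        if k_eff < 2:
            raise ValueError("training portion too small for stratified folds")
        cv = RepeatedStratifiedKFold(n_splits=k_eff, n_repeats=n_repeats, random_state=seed + split_i)
        mean_auc = {}
        for c in c_grid:
            scores = []
            for f_tr, f_te in cv.split(Xtr, ytr):
                if len(np.unique(ytr[f_te])) < 2:
                    continue
                pipe = _make_pipeline(c)
                pipe.fit(Xtr[f_tr], ytr[f_tr])
                p = pipe.predict_proba(Xtr[f_te])[:, list(pipe.classes_).index(pos)]
                scores.append(roc_auc_score(ytr[f_te] == pos, p))
            mean_auc[c] = float(np.mean(scores)) if scores else np.nan
            cv_rows[c].append(mean_auc[c])
        best_c = max(c_grid, key=lambda c: (mean_auc[c], c))
        best_cs.append(best_c)
        final = _make_pipeline(best_c)
        final.fit(Xtr, ytr)
        p = final.predict_proba(X[te])[:, list(final.classes_).index(pos)]
        auc_per_split.append(roc_auc_score(y[te] == pos, p))
        w = final.named_steps["logit"].coef_.ravel()
        if pos != final.classes_[1]:
            w = -w
        coefs.append(np.concatenate([w, final.named_steps["logit"].intercept_]))

    auc_per_split = np.asarray(auc_per_split)
    best_c_overall = max(set(best_cs), key=best_cs.count)
    frozen = _make_pipeline(best_c_overall)
    frozen.fit(X, y)

    feature_names = list(table.features.columns)
    coef_mean = pd.Series(
        np.mean(coefs, axis=0), index=feature_names + ["intercept"], name="coefficient"
    )
    importance = list(coef_mean.drop("intercept").abs().sort_values(ascending=False).index)
    cv_table = pd.DataFrame(
        {"C": list(c_grid), "mean_cv_auc": [float(np.nanmean(cv_rows[c])) for c in c_grid]}
    )
    return ClassifierReport(
        auc=float(auc_per_split.mean()),
        auc_per_split=auc_per_split,
        best_c=float(best_c_overall),
        cv_table=cv_table,
        coefficients=coef_mean,
        importance=importance,
        model=frozen,
        feature_names=feature_names,
        classes=list(classes),
    )


def _check_schema(report: ClassifierReport, table: FeatureTable) -> pd.DataFrame:
    missing = set(report.feature_names) - set(table.features.columns)
    extra = set(table.features.columns) - set(report.feature_names)
    if missing or extra:
        raise SchemaError(f"feature mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
    return table.features[report.feature_names]


def transfer_evaluate(
    trained: ClassifierReport,
    followup_table: FeatureTable,
    relabel_remitters: bool = False,
    score_column: str = "hamd",
) -> dict:
    """Apply the frozen baseline classifier to follow-up features.

    With ``relabel_remitters`` any subject whose follow-up depression
    score (``extra[score_column]``) is at or below the remission
    threshold is scored as HC.
    """
    X = _check_schema(trained, followup_table).to_numpy(dtype=float)
    y = followup_table.labels.copy()
    if relabel_remitters and followup_table.extra is not None and score_column in followup_table.extra:
        scores = followup_table.extra[score_column].reindex(y.index)
        y = y.mask((y == "MDD") & (scores <= REMITTER_THRESHOLD), "HC")
    pos = _positive_label(y)
    proba = trained.model.predict_proba(X)[:, list(trained.model.classes_).index(pos)]
    pred = trained.model.predict(X)
    out = {"accuracy": float(accuracy_score(y, pred)), "n": int(len(y))}
    out["auc"] = float(roc_auc_score(y == pos, proba)) if y.nunique() == 2 else float("nan")
    return out


def leave_one_subject_out(
    baseline_table: FeatureTable,
    followup_table: FeatureTable,
    c: float | None = None,
    seed: int = 0,
) -> dict:
    """Out-of-sample follow-up prediction: one retrain per follow-up subject.

    For each follow-up subject the classifier is retrained on the
    baseline table with that subject removed, then predicts the
    held-out follow-up row.  ``c`` fixes the regularization strength
    (default: selected once by 5-fold CV on the full baseline table).
    """
    Xb = baseline_table.features
    Xf = _check_schema_tables(baseline_table, followup_table)
    missing_ids = set(followup_table.features.index) - set(Xb.index)
    if missing_ids:
        raise SchemaError(f"follow-up subjects missing from baseline: {sorted(missing_ids)}")
    if c is None:
        rep = train_and_evaluate(
            baseline_table, n_repeats=2, k=5, n_holdout_splits=3, seed=seed
        )
        c = rep.best_c
    preds = []
    for sid in followup_table.features.index:
        keep = Xb.index != sid
        pipe = _make_pipeline(c)
        pipe.fit(Xb.loc[keep].to_numpy(dtype=float), baseline_table.labels.loc[keep].to_numpy())
        pred = pipe.predict(Xf.loc[[sid]].to_numpy(dtype=float))[0]
        preds.append({"subject_id": sid, "predicted": pred, "true": followup_table.labels.loc[sid]})
    pred_df = pd.DataFrame(preds).set_index("subject_id")
    return {
        "accuracy": float((pred_df["predicted"] == pred_df["true"]).mean()),
        "n_iterations": int(len(pred_df)),
        "predictions": pred_df,
    }


def _check_schema_tables(a: FeatureTable, b: FeatureTable) -> pd.DataFrame:
    missing = set(a.features.columns) - set(b.features.columns)
    extra = set(b.features.columns) - set(a.features.columns)
    if missing or extra:
        raise SchemaError(f"feature mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
    return b.features[list(a.features.columns)]


def plot_roc(report: ClassifierReport, table: FeatureTable, path=None):
    """ROC curve of the frozen classifier on a feature table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    pos = _positive_label(table.labels)
    X = _check_schema(report, table).to_numpy(dtype=float)
    proba = report.model.predict_proba(X)[:, list(report.model.classes_).index(pos)]
    fpr, tpr, _ = roc_curve(table.labels == pos, proba)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, color="purple", label=f"held-out AUC = {report.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
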