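"""Tests of feature extraction and cross-validated phenotype classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from aacddm.classify import (
    BiasProtectionError,
    FeatureTable,
    SchemaError,
    extract_features,
    leave_one_subject_out,
    pairwise_auc,
    train_and_evaluate,
    transfer_evaluate,
)


def _gaussian_table(n_per_class=30, n_features=6, effect=0.0, seed=0, labels=("HC", "MDD")):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, n_features))
    X[n_per_class:, 0] += effect
    idx = pd.Index([f"s{i:03d}" for i in range(2 * n_per_class)], name="subject_id")
    feats = pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(n_features)])
    y = pd.Series([labels[0]] * n_per_class + [labels[1]] * n_per_class, index=idx, name="label")
    return FeatureTable(features=feats, labels=y, feature_set="test")


class TestExtractFeatures:
    def test_computational_modes_and_roi_exclusion(self, single_population_fit):
        samples, _ = single_population_fit
        full = extract_features(samples, "computational+neural")
        slim = extract_features(samples, "computational")
        roi_tokens = ("stn", "caudate", "pacc", "accumbens")
        assert any(any(t in c for t in roi_tokens) for c in full.features.columns)
        assert not any(any(t in c for t in roi_tokens) for c in slim.features.columns)
        assert set(slim.features.columns) < set(full.features.columns)
        assert set(full.labels.unique()) == {"HC", "MDD"}
        assert not full.features.isna().any().any()

    def test_group_labeled_fit_rejected(self, recovery_fit):
        samples, _ = recovery_fit
        with pytest.raises(BiasProtectionError):
            extract_features(samples, "computational")

    def test_behavioral_roi_summaries(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s1"] * 4,
                "group": "MDD",
                "choice": [1, 1, 1, 0],
                "rt": [1.0, 2.0, 3.0, 2.0],
                "caudate": [0.5, -0.5, 1.0, -1.0],
                "pacc": 0.0,
                "nacc": 0.25,
                "stn": -0.25,
            }
        )
        table = extract_features(None, "behavioral+roi", data=df)
        row = table.features.loc["s1"]
        assert row["approach_rate"] == pytest.approx(0.75)
        assert row["mean_rt"] == pytest.approx(2.0)
        assert row["mean_caudate"] == pytest.approx(0.0)
        assert table.labels.loc["s1"] == "MDD"

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="feature set"):
            extract_features(None, "bogus", data=pd.DataFrame())


class TestPairwiseAUC:
    def test_matches_rank_implementation_exactly(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(80)
        labels = np.array(["MDD" if rng.random() < 0.5 else "HC" for _ in range(80)])
        expected = roc_auc_score(labels == "MDD", scores)
        assert pairwise_auc(scores, labels, "MDD") == pytest.approx(expected, abs=1e-12)

    def test_ties_count_half(self):
        scores = np.array([1.0, 1.0, 0.0])
        labels = np.array(["MDD", "HC", "HC"])
        assert pairwise_auc(scores, labels, "MDD") == pytest.approx((1 + 0.5) / 2)


class TestTrainAndEvaluate:
    def test_perfectly_separable_features(self):
        table = _gaussian_table(n_per_class=20, effect=10.0, seed=2)
        report = train_and_evaluate(table, n_repeats=2, k=5, n_holdout_splits=3, seed=0)
        assert report.auc == 1.0

    def test_noise_features_not_separable(self):
        table = _gaussian_table(n_per_class=30, effect=0.0, seed=3)
        report = train_and_evaluate(table, n_repeats=2, k=5, n_holdout_splits=4, seed=0)
        assert report.auc < 0.95

    def test_label_leakage_canary(self):
        """A feature equal to the label is the only way to reach AUC 1.0 on
        noise: deliberate leakage is detected, absence of it stays near chance."""
        table = _gaussian_table(n_per_class=20, effect=0.0, seed=4)
        leaked = table.features.copy()
        leaked["canary"] = (table.labels == "MDD").astype(float)
        with_canary = FeatureTable(features=leaked, labels=table.labels, feature_set="test")
        report = train_and_evaluate(with_canary, n_repeats=2, k=5, n_holdout_splits=3, seed=1)
        assert report.auc == 1.0
        assert report.importance[0] == "canary"

    def test_importance_invariant_to_feature_order(self):
        table = _gaussian_table(n_per_class=25, effect=1.5, seed=5)
        report = train_and_evaluate(table, n_repeats=2, k=5, n_holdout_splits=3, seed=2)
        permuted = FeatureTable(
            features=table.features[list(reversed(table.features.columns))],
            labels=table.labels,
            feature_set="test",
        )
        report_p = train_and_evaluate(permuted, n_repeats=2, k=5, n_holdout_splits=3, seed=2)
        assert report.importance == report_p.importance
        assert report.auc == pytest.approx(report_p.auc, abs=1e-12)

    def test_single_class_rejected(self):
        table = _gaussian_table(n_per_class=10, seed=6)
        bad = FeatureTable(features=table.features, labels=pd.Series("HC", index=table.features.index), feature_set="t")
        with pytest.raises(ValueError):
            train_and_evaluate(bad, n_repeats=1, k=3, n_holdout_splits=2)


def test_power_at_published_group_mean_differences():
    """Features drawn at the default generating group means (drift-reward
    0.701 vs 0.577, starting point 0.536 vs 0.497, plus noise dimensions)
    at 100 subjects/group: held-out AUC exceeds chance in >= 95% of 50
    seeds."""
    n = 100
    wins = 0
    for s in range(50):
        rng = np.random.default_rng(1000 + s)
        idx = pd.Index([f"s{i:03d}" for i in range(2 * n)], name="subject_id")
        feats = pd.DataFrame(
            {
                "drift.reward": np.r_[rng.normal(0.701, 0.15, n), rng.normal(0.577, 0.15, n)],
                "start.intercept": np.r_[rng.normal(0.536, 0.05, n), rng.normal(0.497, 0.05, n)],
                "drift.aversiveness": rng.normal(-0.57, 0.15, 2 * n),
                "ndt.intercept": rng.normal(0.7, 0.2, 2 * n),
            },
            index=idx,
        )
        labels = pd.Series(["HC"] * n + ["MDD"] * n, index=idx, name="label")
        table = FeatureTable(features=feats, labels=labels, feature_set="test")
        rep = train_and_evaluate(table, n_repeats=1, k=5, n_holdout_splits=1, seed=s)
        wins += rep.auc > 0.5
    assert wins / 50 >= 0.95


class TestTransfer:
    def test_frozen_model_reproduces_training_predictions(self):
        table = _gaussian_table(n_per_class=15, effect=2.0, seed=7)
        report = train_and_evaluate(table, n_repeats=2, k=5, n_holdout_splits=3, seed=3)
        out = transfer_evaluate(report, table)
        expected = report.model.predict(table.features.to_numpy())
        assert out["accuracy"] == pytest.approx(float((expected == table.labels).mean()))

    def test_remitter_relabeling(self):
        table = _gaussian_table(n_per_class=15, effect=2.0, seed=8)
        report = train_and_evaluate(table, n_repeats=2, k=5, n_holdout_splits=3, seed=4)
        no_remitters = FeatureTable(
            features=table.features,
            labels=table.labels,
            feature_set="test",
            extra=pd.DataFrame({"hamd": 20.0}, index=table.features.index),
        )
        assert transfer_evaluate(report, no_remitters, relabel_remitters=True) == transfer_evaluate(
            report, no_remitters, relabel_remitters=False
        )
        scores = pd.Series(20.0, index=table.features.index)
        mdd_ids = table.labels[table.labels == "MDD"].index[:5]
        scores.loc[mdd_ids] = 5.0  # below remission threshold
        with_remitters = FeatureTable(
            features=table.features,
            labels=table.labels,
            feature_set="test",
            extra=pd.DataFrame({"hamd": scores}),
        )
        on = transfer_evaluate(report, with_remitters, relabel_remitters=True)
        off = transfer_evaluate(report, with_remitters, relabel_remitters=False)
        assert on["accuracy"] != off["accuracy"]

    def test_schema_mismatch(self):
        table = _gaussian_table(n_per_class=10, seed=9)
        report = train_and_evaluate(table, n_repeats=1, k=3, n_holdout_splits=2, seed=5)
        renamed = FeatureTable(
            features=table.features.rename(columns={"f0": "other"}),
            labels=table.labels,
            feature_set="test",
        )
        with pytest.raises(SchemaError, match="missing"):
            transfer_evaluate(report, renamed)


class TestLeaveOneSubjectOut:
    def test_separable_two_per_class(self):
        idx = pd.Index(["a", "b", "c", "d"], name="subject_id")
        feats = pd.DataFrame({"f0": [5.0, 5.5, -5.0, -5.5], "f1": [1.0, 1.1, -1.0, -1.1]}, index=idx)
        labels = pd.Series(["MDD", "MDD", "HC", "HC"], index=idx, name="label")
        table = FeatureTable(features=feats, labels=labels, feature_set="test")
        out = leave_one_subject_out(table, table, c=1.0)
        assert out["accuracy"] == 1.0
        assert out["n_iterations"] == 4

    def test_noise_near_chance_and_iteration_count(self):
        base = _gaussian_table(n_per_class=12, effect=0.0, seed=10)
        out = leave_one_subject_out(base, base, c=1.0)
        assert out["n_iterations"] == 24
        assert 0.1 <= out["accuracy"] <= 0.9

    def test_unknown_followup_subject(self):
        base = _gaussian_table(n_per_class=5, seed=11)
        follow = _gaussian_table(n_per_class=6, seed=12)
        with pytest.raises(SchemaError, match="missing from baseline"):
            leave_one_subject_out(base, follow, c=1.0)
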