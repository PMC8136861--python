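"""Shared fixtures: session-scoped synthetic datasets and fits.

The recovery dataset/fit pair reproduces the main estimation setting
(12 subjects x 105 trials generated at the healthy-control group means,
fitted with the desk-scale chain profile) and is reused by several
tests to keep the suite within a desk-scale runtime.
"""

import numpy as np
import pandas as pd
import pytest

from aacddm import FINAL_MODEL, ModelSpec, fit_model, synthetic


@pytest.fixture(scope="session")
def hc_dataset():
    """12 healthy-control-like subjects generated from the full model."""
    return synthetic.generate_dataset(
        [synthetic.GroupSpec("HC", synthetic.HC_COEFFS)], n_subjects_per_group=12, seed=42
    )


@pytest.fixture(scope="session")
def recovery_fit(hc_dataset):
    """Fast-profile hierarchical fit of the recovery dataset."""
    samples, diag = fit_model(hc_dataset.trials, spec=FINAL_MODEL, profile="fast", seed=1)
    return samples, diag


@pytest.fixture(scope="session")
def two_group_dataset():
    """Small two-group dataset (labels HC/MDD) with the default group means."""
    return synthetic.generate_dataset(
        [
            synthetic.GroupSpec("HC", synthetic.HC_COEFFS),
            synthetic.GroupSpec("MDD", synthetic.MDD_COEFFS),
        ],
        n_subjects_per_group=6,
        seed=10,
    )


@pytest.fixture(scope="session")
def single_population_fit(two_group_dataset):
    """Classification-variant fit: single population, subject-level coefficients."""
    spec = FINAL_MODEL.replace(grouping="single", subject_level_slopes=True)
    samples, diag = fit_model(
        two_group_dataset.trials, spec=spec, n_chains=2, n_samples=700, burn_in=300, seed=3
    )
    return samples, diag
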