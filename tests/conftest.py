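"""Shared fixtures: small synthetic subjects and the regression cohort.

Expensive artefacts (trial sets, cohort features) are session-scoped so
several tests can reuse one simulation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import mieff
from mieff.drn import moment_features


@pytest.fixture(scope="session")
def mid_profile() -> mieff.SubjectProfile:
    """A subject with erd_depth exactly 0.5 (efficiency 0.625)."""
    return mieff.make_cohort(1, seed=2, efficiency_spec=[0.625])[0]


@pytest.fixture(scope="session")
def strong_profile() -> mieff.SubjectProfile:
    """A maximal-efficiency subject (erd_depth 0.8)."""
    return mieff.make_cohort(1, seed=3, efficiency_spec=[1.0])[0]


@pytest.fixture(scope="session")
def null_profile() -> mieff.SubjectProfile:
    """A subject with no ERD at all."""
    prof = mieff.make_cohort(1, seed=4, efficiency_spec=[0.5])[0]
    return dataclasses.replace(prof, erd_depth=0.0)


@pytest.fixture(scope="session")
def mid_trials(mid_profile) -> mieff.TrialSet:
    return mieff.simulate_trial_set(mid_profile, n_trials=100)


@pytest.fixture(scope="session")
def strong_trials(strong_profile) -> mieff.TrialSet:
    return mieff.simulate_trial_set(strong_profile, n_trials=50)


@pytest.fixture(scope="session")
def small_trials(mid_profile) -> mieff.TrialSet:
    return mieff.simulate_trial_set(mid_profile, n_trials=12)


@pytest.fixture(scope="session")
def regression_cohort():
    return mieff.make_regression_cohort(50, seed=0)


@pytest.fixture(scope="session")
def cohort_features(regression_cohort):
    coh = regression_cohort
    return np.stack([[moment_features(ch, coh.fs) for ch in subj]
                     for subj in coh.signals])
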