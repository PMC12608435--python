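"""Shared fixtures: generated cohorts and their feature tables.

The heavy end-to-end fixtures (full cohorts run through decomposition
and feature extraction) are session-scoped so the cost is paid once per
test run.  Fixture seeds are fixed constants so every run exercises the
same cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wearstress.features import build_feature_table
from wearstress.synth import SessionConfig, generate_cohort, generate_session

#: seeds of the repeated end-to-end cohorts (10 for the confusion check)
COHORT_SEEDS = tuple(range(100, 110))


def make_table(seed: int, n_subjects: int = 23) -> pd.DataFrame:
    """Default-configuration cohort run through the full feature pipeline."""
    sessions, _ = generate_cohort(SessionConfig(n_subjects=n_subjects, seed=seed))
    return build_feature_table(sessions)


@pytest.fixture(scope="session")
def cohort_tables() -> dict[int, pd.DataFrame]:
    """Feature tables of ten independent 23-subject cohorts, keyed by seed."""
    return {seed: make_table(seed) for seed in COHORT_SEEDS}


@pytest.fixture(scope="session")
def primary_table(cohort_tables) -> pd.DataFrame:
    """The first of the end-to-end cohorts, used for single-cohort checks."""
    return cohort_tables[COHORT_SEEDS[0]]


@pytest.fixture(scope="session")
def small_session():
    """One default-configuration session for signal-level tests."""
    return generate_session(SessionConfig(seed=5), "S01")


@pytest.fixture(scope="session")
def deformed_session():
    """Same subject and seed but with the deformed pulse morphology."""
    return generate_session(SessionConfig(seed=5, waveform_deformed=True), "S01")


def separable_table(
    n_subjects: int = 23, noise_sd: float = 0.01, seed: int = 0
) -> pd.DataFrame:
    """A feature table whose three features encode the level almost noiselessly."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for level in range(1, 5):
            rows.append(
                {
                    "subject_id": f"S{i + 1:02d}",
                    "level": level,
                    "f1": level + noise_sd * rng.standard_normal(),
                    "f2": -level + noise_sd * rng.standard_normal(),
                    "f3": level**2 + noise_sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
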