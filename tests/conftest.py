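"""Shared fixtures: analytic contours and synthetic cohorts.

Everything is generated programmatically; the heavier cohort-level objects
are session-scoped so the expensive stages (measure extraction, per-speaker
MDS) run once.
"""

import warnings

import pytest

from tonguespace import (
    MEASURE_COLUMNS,
    CohortConfig,
    extract_measures_table,
    generate_cohort,
    ordinate_dataset,
    reference_fixtures,
    scale_within_speaker,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def fixtures():
    return reference_fixtures()


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort (40 speakers, fixed seed)."""
    dataset, truth = generate_cohort(CohortConfig(seed=COHORT_SEED))
    return dataset, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for orchestration tests (6 speakers)."""
    cfg = CohortConfig(n_speakers=6, reps_min=4, reps_max=4, seed=7)
    dataset, truth = generate_cohort(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def measures_table(cohort):
    dataset, _ = cohort
    return extract_measures_table(dataset)


@pytest.fixture(scope="session")
def scaled_measures(measures_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scale_within_speaker(measures_table, MEASURE_COLUMNS)


@pytest.fixture(scope="session")
def ordinations(cohort):
    dataset, _ = cohort
    return ordinate_dataset(dataset, random_state=11, n_init=2)
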