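"""Shared fixtures: standards and a small fitted cohort reused across tests."""

import pytest

import dietqual as dq


@pytest.fixture(scope="session")
def standards():
    return dq.load_standards()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-person cohort with default (noisy, zero-inflated) settings."""
    return dq.generate_cohort(dq.CohortConfig(n=400, seed=7))


@pytest.fixture(scope="session")
def small_recalls(small_cohort):
    return dq.generate_recalls(small_cohort)


@pytest.fixture(scope="session")
def small_model(small_cohort, small_recalls):
    return dq.fit(small_recalls, small_cohort.covariates)
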