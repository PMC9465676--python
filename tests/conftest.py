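"""Shared fixtures: simulated subjects and cohorts, generated at session scope."""

import warnings

import pytest

from vo2wear import SimParams, SubjectInfo, simulate_cohort, simulate_subject
from vo2wear.features import build_feature_frame


@pytest.fixture(scope="session")
def subject():
    return SubjectInfo("S001", 25, "male", 175.0, 70.0)


@pytest.fixture(scope="session")
def sim_pair(subject):
    """One full-protocol recording plus its generative truth."""
    return simulate_subject(subject, SimParams(), seed=3)


@pytest.fixture(scope="session")
def cohort12():
    """12-subject cohort at the default (high-SNR) study conditions."""
    return simulate_cohort(12, SimParams(), seed=1)


@pytest.fixture(scope="session")
def frames12(cohort12):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [build_feature_frame(rec) for rec, _ in cohort12]


@pytest.fixture(scope="session")
def small_recording():
    """A short rest-only recording for fast I/O and contract tests."""
    subj = SubjectInfo("S900", 30, "female", 165.0, 60.0)
    rec, _ = simulate_subject(subj, SimParams(rest_only=True), seed=9)
    return rec
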