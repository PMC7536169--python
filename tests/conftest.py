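import pytest

from timbretest import protocol, scoring, simulate


@pytest.fixture(scope="session")
def full_session():
    return protocol.build_full_session(seed=1)


@pytest.fixture(scope="session")
def short_session():
    return protocol.build_short_session()


@pytest.fixture(scope="session")
def cohort(full_session):
    """A 95-respondent synthetic cohort with the default noise model."""
    return simulate.simulate_cohort(simulate.CohortSpec(seed=7), full_session)


@pytest.fixture(scope="session")
def scored_cohort(cohort, full_session):
    report, bins = scoring.score_session(cohort.responses, full_session)
    return report, bins
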