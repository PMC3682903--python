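import datetime as dt

import pytest

from phenovalid import (
    ChartReviewOutcome,
    ContactEvent,
    EpisodeRecord,
    PatientRecord,
    PrescriptionEvent,
    extract_profiles,
    load_table1_marginals,
    materialize_fixture,
    reconstruct_joint,
)


def make_patient(
    patient_id="P1",
    sex="female",
    birth="1950-06-01",
    contacts=(),
    episodes=(),
    prescriptions=(),
    terms=(),
):
    """Terse patient factory: events given as plain tuples.

    contacts: (date, icpc); episodes: (icpc, start, end);
    prescriptions: (date, atc, linked_icpc_or_None, is_repeat).
    """
    return PatientRecord(
        patient_id=patient_id,
        sex=sex,
        birth_date=dt.date.fromisoformat(birth),
        contacts=tuple(
            ContactEvent(date=dt.date.fromisoformat(d), icpc_code=c) for d, c in contacts
        ),
        episodes=tuple(
            EpisodeRecord(
                icpc_code=c,
                start_date=dt.date.fromisoformat(s),
                end_date=dt.date.fromisoformat(e),
            )
            for c, s, e in episodes
        ),
        prescriptions=tuple(
            PrescriptionEvent(
                date=dt.date.fromisoformat(d),
                atc_code=a,
                linked_icpc_code=l,
                is_repeat=r,
            )
            for d, a, l, r in prescriptions
        ),
        chart_review=ChartReviewOutcome(specialist_terms=frozenset(terms)),
    )


@pytest.fixture(scope="session")
def table1_marginals():
    return load_table1_marginals()


@pytest.fixture(scope="session")
def table1_joint(table1_marginals):
    return reconstruct_joint(table1_marginals)


@pytest.fixture(scope="session")
def table1_fixture(table1_joint):
    return materialize_fixture(table1_joint, seed=1)


@pytest.fixture(scope="session")
def table1_profiles(table1_fixture):
    return extract_profiles(table1_fixture)
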