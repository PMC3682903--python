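"""Construct a synthetic patient record realizing a given criterion pattern.

Shared by the marginal-table fixture materializer and the stochastic cohort
generator: given the target booleans (c1, c2, c3), confirmation status, sex
and age at first index contact, emit a :class:`PatientRecord` whose extracted
:class:`CriterionProfile` reproduces exactly that pattern.

Event scaffolding, per flag:

* every patient gets an index-coded contact (so cohort selection keeps them);
* c1 true  -> one repeat prescription for methotrexate (ATC ``L04AX03``);
* c2 true  -> either four index-coded contacts (variant 0) or one contact
  plus an index-coded episode (variant 1), plus two index-linked NSAID
  prescriptions (ATC ``M01AE01``, naproxen-class, outside the DMARD catalog);
* c3 is realized through the age at the index date (30-61 true, above false).

Confirmed patients carry the specialist term "rheumatoid arthritis";
unconfirmed ones carry "osteoarthritis" — the miscoding channel the
validation study is about.
"""

from __future__ import annotations

import datetime as dt

from .records import (
    ChartReviewOutcome,
    ContactEvent,
    EpisodeRecord,
    PatientRecord,
    PrescriptionEvent,
)

__all__ = ["build_patient", "BASE_INDEX_DATE"]

#: All index dates fall in one (non-leap) calendar year so birth dates derived
#: by shifting the year back never hit Feb 29.
BASE_INDEX_DATE = dt.date(2005, 1, 10)

_DMARD_ATC = "L04AX03"  # methotrexate (immunosuppressant classification)
_NSAID_ATC = "M01AE01"  # propionic-acid NSAID; outside the DMARD catalog

CONFIRMED_TERM = "rheumatoid arthritis"
NOT_CONFIRMED_TERM = "osteoarthritis"


def build_patient(
    patient_id: str,
    pattern: tuple[bool, bool, bool],
    confirmed: bool,
    sex: str,
    age_at_index: int,
    index_code: str = "L88",
    index_day_offset: int = 0,
    episode_variant: bool = False,
) -> PatientRecord:
    """One synthetic patient whose profile realizes ``pattern``.

    ``age_at_index`` must already be consistent with the c3 flag (30-61 for
    true, 62+ for false); the caller owns that invariant because the age band
    is a configuration concern.
    """
    c1, c2, _c3 = pattern
    index_date = BASE_INDEX_DATE + dt.timedelta(days=int(index_day_offset))
    birth_date = index_date.replace(year=index_date.year - int(age_at_index))

    contacts = [ContactEvent(date=index_date, icpc_code=index_code)]
    episodes: list[EpisodeRecord] = []
    prescriptions: list[PrescriptionEvent] = []

    if c2:
        if episode_variant:
            episodes.append(
                EpisodeRecord(
                    icpc_code=index_code,
                    start_date=index_date,
                    end_date=index_date + dt.timedelta(days=180),
                )
            )
        else:
            contacts += [
                ContactEvent(date=index_date + dt.timedelta(days=d), icpc_code=index_code)
                for d in (30, 60, 90)
            ]
        prescriptions += [
            PrescriptionEvent(
                date=index_date + dt.timedelta(days=d),
                atc_code=_NSAID_ATC,
                linked_icpc_code=index_code,
                is_repeat=False,
            )
            for d in (7, 37)
        ]

    if c1:
        prescriptions.append(
            PrescriptionEvent(
                date=index_date + dt.timedelta(days=14),
                atc_code=_DMARD_ATC,
                linked_icpc_code=None,
                is_repeat=True,
            )
        )

    terms = frozenset({CONFIRMED_TERM if confirmed else NOT_CONFIRMED_TERM})
    return PatientRecord(
        patient_id=patient_id,
        sex=sex,
        birth_date=birth_date,
        contacts=tuple(contacts),
        episodes=tuple(episodes),
        prescriptions=tuple(prescriptions),
        chart_review=ChartReviewOutcome(specialist_terms=terms),
    )
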