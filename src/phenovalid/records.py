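"""EMR record types and cohort selection.

The data model mirrors what a Dutch general-practice registration database
exports per patient: dated contacts carrying an ICPC-1 diagnosis code,
disease episodes (the span between first and last contact for one health
problem), prescriptions with an ATC drug code and optionally the ICPC code
of the indication, and the chart-review outcome as a set of specialist
diagnosis terms found in free-text correspondence.

ICPC rubric matching is exact on the rubric, case-insensitive and
whitespace-tolerant; a sub-rubric such as ``L88.01`` matches the parent
rubric ``L88`` (granularity varies between source systems).
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import DomainError

__all__ = [
    "ContactEvent",
    "EpisodeRecord",
    "PrescriptionEvent",
    "ChartReviewOutcome",
    "PatientRecord",
    "normalize_icpc",
    "icpc_matches",
    "age_at",
    "first_index_event",
    "select_cohort",
]


def normalize_icpc(code: str) -> str:
    return code.strip().upper()


def icpc_matches(code: str, rubric: str) -> bool:
    """True if an event's ICPC code falls under ``rubric``.

    Exact match after normalization, or prefix-before-the-dot match when the
    rubric is a bare rubric (``L88.01`` matches ``L88`` but not vice versa).
    """
    c = normalize_icpc(code)
    r = normalize_icpc(rubric)
    if c == r:
        return True
    return "." not in r and c.split(".", 1)[0] == r


class ContactEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: dt.date
    icpc_code: str

    @field_validator("icpc_code")
    @classmethod
    def _code_non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("icpc_code must be non-empty")
        return v


class EpisodeRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    icpc_code: str
    start_date: dt.date
    end_date: dt.date

    @field_validator("icpc_code")
    @classmethod
    def _code_non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("icpc_code must be non-empty")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "EpisodeRecord":
        if self.end_date < self.start_date:
            raise ValueError(
                f"episode end_date {self.end_date} precedes start_date {self.start_date}"
            )
        return self


class PrescriptionEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: dt.date
    atc_code: str
    linked_icpc_code: Optional[str] = None
    is_repeat: bool = False

    @field_validator("atc_code")
    @classmethod
    def _atc_non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("atc_code must be non-empty")
        return v

    @field_validator("linked_icpc_code", mode="before")
    @classmethod
    def _empty_is_absent(cls, v):
        if v is not None and not str(v).strip():
            return None
        return v


class ChartReviewOutcome(BaseModel):
    """Specialist diagnosis terms found during manual chart review.

    Only the term set is stored; whether the diagnosis is *confirmed* is
    always recomputed against a :class:`~phenovalid.chart_review.ConfirmationVocabulary`
    so the reference standard stays auditable.
    """

    model_config = ConfigDict(frozen=True)

    specialist_terms: frozenset[str] = frozenset()


class PatientRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    sex: Literal["female", "male"]
    birth_date: dt.date
    contacts: tuple[ContactEvent, ...] = ()
    episodes: tuple[EpisodeRecord, ...] = ()
    prescriptions: tuple[PrescriptionEvent, ...] = ()
    chart_review: ChartReviewOutcome = ChartReviewOutcome()

    @field_validator("patient_id")
    @classmethod
    def _id_non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("patient_id must be non-empty")
        return v

    @model_validator(mode="after")
    def _events_after_birth(self) -> "PatientRecord":
        dates = [c.date for c in self.contacts]
        dates += [e.start_date for e in self.episodes]
        dates += [p.date for p in self.prescriptions]
        for d in dates:
            if d < self.birth_date:
                raise ValueError(
                    f"event date {d} precedes birth_date {self.birth_date} "
                    f"for patient {self.patient_id}"
                )
        return self


def age_at(patient: PatientRecord, date: dt.date) -> int:
    """Age in completed years at ``date`` (standard epidemiological floor)."""
    b = patient.birth_date
    if date < b:
        raise DomainError(
            f"date {date} precedes birth_date {b} for patient {patient.patient_id}"
        )
    return date.year - b.year - ((date.month, date.day) < (b.month, b.day))


def first_index_event(patient: PatientRecord, index_code: str) -> Optional[dt.date]:
    """Earliest date the index rubric was recorded, via contact or episode start.

    Returns ``None`` if the patient never carried the code. Both recording
    routes count: "ever registered with a diagnostic code" covers an episode
    opened without a same-coded contact.
    """
    dates = [c.date for c in patient.contacts if icpc_matches(c.icpc_code, index_code)]
    dates += [
        e.start_date for e in patient.episodes if icpc_matches(e.icpc_code, index_code)
    ]
    return min(dates) if dates else None


def select_cohort(
    patients: list[PatientRecord], index_code: str = "L88", min_age: int = 30
) -> list[PatientRecord]:
    """Keep patients ever coded with ``index_code`` and aged ``min_age``+ at that
    first coding (the juvenile-arthritis exclusion when the defaults are used)."""
    if min_age < 0:
        raise DomainError("min_age must be non-negative")
    kept = []
    for p in patients:
        d = first_index_event(p, index_code)
        if d is not None and age_at(p, d) >= min_age:
            kept.append(p)
    return kept
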