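"""Per-patient feature extraction and the three case-finding criteria.

For a patient carrying the index diagnosis code (ICPC L88 by default) the
engine derives:

* **Criterion 1** — a repeat prescription (issued without a consultation) for
  a DMARD or biological agent. Specialists initiate these drugs, so a GP
  repeat prescription is a strong proxy for specialist-managed disease. No
  ICPC linkage is required on the prescription.
* **Criterion 2** — at least four index-coded contacts or one index-coded
  episode, combined with at least two prescriptions linked to the index code
  that are *not* DMARDs/biologicals.
* **Criterion 3** — age 30–61 (inclusive) at the first index-coded event;
  older first diagnoses are more often osteoarthritis or gout miscoded.

Algorithms are "at least k of a chosen subset" combinators over the three
criterion booleans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .chart_review import ConfirmationVocabulary, confirm_ia
from .errors import DomainError
from .records import PatientRecord, age_at, first_index_event, icpc_matches

__all__ = [
    "DEFAULT_DMARD_ATC_PREFIXES",
    "MedicationCatalog",
    "CriterionProfile",
    "AlgorithmSpec",
    "extract_profile",
    "criterion1",
    "criterion2",
    "criterion3",
    "apply_algorithm",
]

#: ATC prefixes identifying DMARDs and biological agents: L04A covers
#: immunosuppressants including biologicals; the rest are the classic
#: synthetic DMARDs (hydroxychloroquine, sulfasalazine, gold salts,
#: penicillamine, methotrexate).
DEFAULT_DMARD_ATC_PREFIXES = frozenset(
    {"L04A", "P01BA02", "A07EC01", "M01CB", "M01CC01", "L01BA01"}
)


class MedicationCatalog(BaseModel):
    model_config = ConfigDict(frozen=True)

    dmard_biologic_atc_prefixes: frozenset[str] = DEFAULT_DMARD_ATC_PREFIXES

    @field_validator("dmard_biologic_atc_prefixes")
    @classmethod
    def _valid_prefixes(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("catalog must contain at least one ATC prefix")
        out = frozenset(p.strip().upper() for p in v)
        if any(not p or not p[0].isalpha() for p in out):
            raise ValueError("ATC prefixes must start with an anatomical group letter")
        return out

    def contains(self, atc_code: str) -> bool:
        code = atc_code.strip().upper()
        return any(code.startswith(p) for p in self.dmard_biologic_atc_prefixes)


@dataclass(frozen=True)
class CriterionProfile:
    """Extracted features plus criterion outcomes for one cohort patient.

    ``c1``/``c2``/``c3`` are stored for convenience but are pure functions of
    the feature fields; :func:`criterion1`–:func:`criterion3` re-derive them.
    """

    patient_id: str
    n_l88_contacts: int
    has_l88_episode: bool
    n_l88_linked_rx_non_dmard: int
    has_repeat_dmard: bool
    age_at_first_l88: int
    c1: bool
    c2: bool
    c3: bool
    confirmed: bool

    def flags(self) -> tuple[bool, bool, bool]:
        return (self.c1, self.c2, self.c3)


def criterion1(profile: CriterionProfile) -> bool:
    """Repeat prescription for a DMARD or biological agent."""
    return profile.has_repeat_dmard


def criterion2(profile: CriterionProfile) -> bool:
    """(≥4 index-coded contacts OR ≥1 index-coded episode) AND ≥2 index-linked
    non-DMARD prescriptions."""
    return (
        profile.n_l88_contacts >= 4 or profile.has_l88_episode
    ) and profile.n_l88_linked_rx_non_dmard >= 2


def criterion3(profile: CriterionProfile, age_cutoff: int = 61, min_age: int = 30) -> bool:
    """Age at first index-coded event within [min_age, age_cutoff], inclusive."""
    return min_age <= profile.age_at_first_l88 <= age_cutoff


def extract_profile(
    patient: PatientRecord,
    index_code: str = "L88",
    catalog: Optional[MedicationCatalog] = None,
    age_cutoff: int = 61,
    min_age: int = 30,
    vocabulary: Optional[ConfirmationVocabulary] = None,
) -> CriterionProfile:
    catalog = catalog or MedicationCatalog()
    index_date = first_index_event(patient, index_code)
    if index_date is None:
        raise DomainError(
            f"patient {patient.patient_id} has no {index_code}-coded event; "
            "extract_profile requires a cohort-selected patient"
        )

    n_contacts = sum(icpc_matches(c.icpc_code, index_code) for c in patient.contacts)
    has_episode = any(icpc_matches(e.icpc_code, index_code) for e in patient.episodes)
    n_linked_non_dmard = sum(
        1
        for rx in patient.prescriptions
        if rx.linked_icpc_code is not None
        and icpc_matches(rx.linked_icpc_code, index_code)
        and not catalog.contains(rx.atc_code)
    )
    has_repeat_dmard = any(
        rx.is_repeat and catalog.contains(rx.atc_code) for rx in patient.prescriptions
    )
    age = age_at(patient, index_date)

    # assemble features first, then the criterion flags from them
    stub = CriterionProfile(
        patient_id=patient.patient_id,
        n_l88_contacts=n_contacts,
        has_l88_episode=has_episode,
        n_l88_linked_rx_non_dmard=n_linked_non_dmard,
        has_repeat_dmard=has_repeat_dmard,
        age_at_first_l88=age,
        c1=False,
        c2=False,
        c3=False,
        confirmed=confirm_ia(patient.chart_review.specialist_terms, vocabulary),
    )
    return CriterionProfile(
        **{
            **stub.__dict__,
            "c1": criterion1(stub),
            "c2": criterion2(stub),
            "c3": criterion3(stub, age_cutoff=age_cutoff, min_age=min_age),
        }
    )


class AlgorithmSpec(BaseModel):
    """Select patients satisfying at least ``min_satisfied`` of ``criteria_used``."""

    model_config = ConfigDict(frozen=True)

    criteria_used: frozenset[int]
    min_satisfied: int = 1

    @field_validator("criteria_used")
    @classmethod
    def _valid_criteria(cls, v: frozenset[int]) -> frozenset[int]:
        if not v:
            raise ValueError("criteria_used must be non-empty")
        if not v <= {1, 2, 3}:
            raise ValueError(f"unknown criteria: {sorted(v - {1, 2, 3})}")
        return v

    @model_validator(mode="after")
    def _k_in_range(self) -> "AlgorithmSpec":
        if not 1 <= self.min_satisfied <= len(self.criteria_used):
            raise ValueError(
                f"min_satisfied must be in [1, {len(self.criteria_used)}], "
                f"got {self.min_satisfied}"
            )
        return self

    def selects(self, profile: CriterionProfile) -> bool:
        flags = profile.flags()
        return sum(flags[i - 1] for i in self.criteria_used) >= self.min_satisfied

    @property
    def label(self) -> str:
        crits = sorted(self.criteria_used)
        if len(crits) == 1:
            return f"Criterion {crits[0]}"
        if self.min_satisfied == 1 and len(crits) == 2:
            return f"Criterion {crits[0]} or {crits[1]}"
        if len(crits) == 3 and self.min_satisfied == 3:
            return "All 3 criteria"
        return f"{self.min_satisfied} out of {len(crits)} criteria"


def apply_algorithm(
    profiles: list[CriterionProfile], spec: AlgorithmSpec
) -> set[str]:
    """Patient ids selected by the at-least-k combinator ``spec``."""
    return {p.patient_id for p in profiles if spec.selects(p)}
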