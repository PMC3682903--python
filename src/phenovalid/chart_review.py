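"""Reference-standard confirmation of the inflammatory-arthritis diagnosis.

Chart review is modelled as a controlled vocabulary: each patient carries the
set of specialist diagnosis terms found in their record, and the diagnosis is
confirmed when that set intersects the confirmatory vocabulary
(oligoarthritis, polyarthritis, rheumatoid arthritis, spondyloarthropathy by
default). Matching is exact on normalized terms — lower-cased, whitespace
collapsed — never substring matching; synonyms such as "RA" belong in the
vocabulary configuration, not in the matcher.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .errors import DomainError
from .records import PatientRecord

__all__ = [
    "DEFAULT_CONFIRMATORY_TERMS",
    "ConfirmationVocabulary",
    "normalize_term",
    "confirm_ia",
    "raw_validity",
    "ValidityResult",
]

DEFAULT_CONFIRMATORY_TERMS = frozenset(
    {
        "oligoarthritis",
        "polyarthritis",
        "rheumatoid arthritis",
        "spondyloarthropathy",
    }
)


def normalize_term(term: str) -> str:
    return re.sub(r"\s+", " ", term.strip().lower())


class ConfirmationVocabulary(BaseModel):
    model_config = ConfigDict(frozen=True)

    confirmatory_terms: frozenset[str] = DEFAULT_CONFIRMATORY_TERMS

    @field_validator("confirmatory_terms")
    @classmethod
    def _normalized_non_empty(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("confirmatory_terms must be non-empty")
        return frozenset(normalize_term(t) for t in v)


def confirm_ia(
    terms: Iterable[str], vocab: Optional[ConfirmationVocabulary] = None
) -> bool:
    """True iff any normalized chart-review term is in the confirmatory set."""
    vocab = vocab or ConfirmationVocabulary()
    return any(normalize_term(t) in vocab.confirmatory_terms for t in terms)


class ValidityResult(NamedTuple):
    fraction: float
    n_confirmed: int
    n_total: int


def raw_validity(
    cohort: list[PatientRecord], vocab: Optional[ConfirmationVocabulary] = None
) -> ValidityResult:
    """Fraction of the coded cohort whose diagnosis chart review confirms.

    This is the positive predictive value of the diagnosis code itself, i.e.
    of the trivial "select everyone" algorithm.
    """
    if not cohort:
        raise DomainError("raw_validity is undefined on an empty cohort")
    n_confirmed = sum(
        confirm_ia(p.chart_review.specialist_terms, vocab) for p in cohort
    )
    return ValidityResult(n_confirmed / len(cohort), n_confirmed, len(cohort))
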