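"""Validation metrics and the standard algorithm-comparison report.

For each candidate algorithm the report gives the number and percentage of
cohort patients selected, how many of those chart review confirms, and the
positive predictive value (PPV, "validity") among the selected. Percentages
are displayed rounded half-away-from-zero to one decimal; raw counts are kept
so nothing is lost to rounding. The PPV of an empty selection is undefined
and reported as absent, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .criteria import AlgorithmSpec, CriterionProfile, apply_algorithm
from .errors import DomainError

__all__ = [
    "round_half_up",
    "ppv",
    "coverage",
    "exclusion",
    "ValidationRow",
    "ValidationReport",
    "TABLE1_SPECS",
    "evaluate_algorithms",
    "table1_report",
    "report_to_frame",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ppv(selected: set[str], profiles: Sequence[CriterionProfile]) -> Optional[float]:
    """Fraction of selected patients whose diagnosis is confirmed; ``None`` for
    an empty selection (0/0 is undefined, not zero)."""
    ids = {p.patient_id for p in profiles}
    if not selected <= ids:
        raise DomainError(f"selected ids not in cohort: {sorted(selected - ids)[:5]}")
    if not selected:
        return None
    n_conf = sum(p.confirmed for p in profiles if p.patient_id in selected)
    return n_conf / len(selected)


def coverage(selected: set[str], n_total: int) -> float:
    """Fraction of the coded cohort the algorithm retains."""
    if n_total <= 0:
        raise DomainError("n_total must be positive")
    return len(selected) / n_total


def exclusion(selected: set[str], n_total: int) -> float:
    return 1.0 - coverage(selected, n_total)


@dataclass(frozen=True)
class ValidationRow:
    label: str
    n_selected: int
    pct_selected: float  # percent of cohort, one-decimal display rounding
    n_confirmed: int
    ppv: Optional[float]  # percent among selected, one-decimal; None if empty
    n_not_confirmed: int


@dataclass(frozen=True)
class ValidationReport:
    n_total: int
    baseline: ValidationRow
    rows: tuple[ValidationRow, ...]


#: The nine algorithms of the standard comparison, in report order:
#: singles, pairwise unions, then the three k-of-3 combinators.
TABLE1_SPECS: tuple[AlgorithmSpec, ...] = (
    AlgorithmSpec(criteria_used=frozenset({1}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({2}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({3}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({1, 2}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({1, 3}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({2, 3}), min_satisfied=1),
    AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=3),
    AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=2),
    AlgorithmSpec(criteria_used=frozenset({1, 2, 3}), min_satisfied=1),
)


def _row(
    label: str, selected: set[str], profiles: Sequence[CriterionProfile], n_total: int
) -> ValidationRow:
    n_sel = len(selected)
    n_conf = sum(p.confirmed for p in profiles if p.patient_id in selected)
    return ValidationRow(
        label=label,
        n_selected=n_sel,
        pct_selected=round_half_up(100.0 * n_sel / n_total),
        n_confirmed=n_conf,
        ppv=round_half_up(100.0 * n_conf / n_sel) if n_sel else None,
        n_not_confirmed=n_sel - n_conf,
    )


def evaluate_algorithms(
    profiles: Sequence[CriterionProfile],
    specs: Sequence[AlgorithmSpec],
    labels: Optional[Sequence[str]] = None,
) -> ValidationReport:
    if not profiles:
        raise DomainError("cannot evaluate algorithms on an empty cohort")
    profiles = list(profiles)
    n_total = len(profiles)
    labels = list(labels) if labels is not None else [s.label for s in specs]
    if len(labels) != len(specs):
        raise DomainError("labels and specs must have equal length")

    baseline = _row(
        "Without using an algorithm", {p.patient_id for p in profiles}, profiles, n_total
    )
    rows = tuple(
        _row(lab, apply_algorithm(profiles, spec), profiles, n_total)
        for lab, spec in zip(labels, specs)
    )
    return ValidationReport(n_total=n_total, baseline=baseline, rows=rows)


def table1_report(profiles: Sequence[CriterionProfile]) -> ValidationReport:
    """The standard report: baseline plus the nine criterion combinations."""
    labels = [
        "Criterion 1: Repeat prescription DMARDs/biological agents",
        "Criterion 2: Contact with GP and IA-related prescription",
        "Criterion 3: Age 30-61 years at first diagnosis",
        "Criterion 1 or 2",
        "Criterion 1 or 3",
        "Criterion 2 or 3",
        "All 3 criteria",
        "2 out of 3 criteria",
        "1 out of 3 criteria",
    ]
    return evaluate_algorithms(profiles, TABLE1_SPECS, labels)


def report_to_frame(report: ValidationReport) -> pd.DataFrame:
    records = []
    for row in (report.baseline, *report.rows):
        records.append(
            {
                "algorithm": row.label,
                "n_selected": row.n_selected,
                "pct_selected": row.pct_selected,
                "n_confirmed": row.n_confirmed,
                "ppv_pct": row.ppv,
                "n_not_confirmed": row.n_not_confirmed,
            }
        )
    return pd.DataFrame.from_records(records)
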