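"""Reconstruct the criterion-pattern joint distribution from marginal counts.

The published validation table reports, per confirmation class, only marginal
set sizes: the three single-criterion counts, the three pairwise unions, the
triple intersection, the class total, and the at-least-1 / at-least-2 rows.
Ten constraints per class over eight pattern counts — an overdetermined
system. Inclusion–exclusion recovers the pairwise intersections

    |Ci ∩ Cj| = |Ci| + |Cj| − |Ci ∪ Cj|

and Möbius inversion then yields all eight pattern counts
(c1,c2,c3) ∈ {0,1}³. The reconstruction deliberately uses only the singles,
pairwise unions, triple intersection and totals; the two at-least-k rows are
held out and serve as an internal consistency proof — for the shipped table
every residual is exactly zero.

A negative reconstructed count means the printed marginals admit no joint
distribution; that is an error, not a fitting problem.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .builders import build_patient
from .errors import InconsistencyError, SchemaError
from .records import PatientRecord

__all__ = [
    "CLASSES",
    "PATTERNS",
    "ClassMarginals",
    "MarginalTable",
    "JointDistribution",
    "load_marginals",
    "load_table1_marginals",
    "reconstruct_joint",
    "compute_marginals",
    "verify_consistency",
    "materialize_fixture",
]

CLASSES = ("confirmed", "not_confirmed")
#: Patterns ordered as binary (c1, c2, c3): 000, 001, ..., 111.
PATTERNS: tuple[tuple[bool, bool, bool], ...] = tuple(
    itertools.product((False, True), repeat=3)
)

_MARGINAL_FIELDS = (
    "n_total", "c1", "c2", "c3",
    "c1_or_c2", "c1_or_c3", "c2_or_c3",
    "all_three", "at_least_two", "at_least_one",
)


class ClassMarginals(BaseModel):
    """Marginal counts for one confirmation class."""

    model_config = ConfigDict(frozen=True)

    n_total: int
    c1: int
    c2: int
    c3: int
    c1_or_c2: int
    c1_or_c3: int
    c2_or_c3: int
    all_three: int
    at_least_two: int
    at_least_one: int

    @model_validator(mode="after")
    def _sane(self) -> "ClassMarginals":
        for name in _MARGINAL_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"marginal count {name} is negative")
        for single in ("c1", "c2", "c3"):
            if getattr(self, single) > self.n_total:
                raise ValueError(f"{single} exceeds n_total")
        for i, j in ((1, 2), (1, 3), (2, 3)):
            union = getattr(self, f"c{i}_or_c{j}")
            if union < max(getattr(self, f"c{i}"), getattr(self, f"c{j}")):
                raise ValueError(f"c{i}_or_c{j} smaller than one of its members")
        return self


class MarginalTable(BaseModel):
    model_config = ConfigDict(frozen=True)

    confirmed: ClassMarginals
    not_confirmed: ClassMarginals

    def for_class(self, class_label: str) -> ClassMarginals:
        return getattr(self, class_label)


def load_marginals(path: str | Path) -> MarginalTable:
    """Read a marginal table from a YAML file (two classes, ten counts each)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return MarginalTable.model_validate(raw)
    except Exception as exc:
        raise SchemaError(f"{path}: invalid marginal table: {exc}") from exc


def load_table1_marginals() -> MarginalTable:
    """The marginal table shipped with the package (published cohort, n=219)."""
    ref = resources.files("phenovalid").joinpath("data/table1.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return MarginalTable.model_validate(raw)


@dataclass(frozen=True)
class JointDistribution:
    """Counts over the 16 cells (confirmation class × criterion pattern)."""

    counts: dict[tuple[str, tuple[bool, bool, bool]], int] = field(default_factory=dict)

    def __post_init__(self):
        full = {
            (cls, pat): int(self.counts.get((cls, pat), 0))
            for cls in CLASSES
            for pat in PATTERNS
        }
        if any(v < 0 for v in full.values()):
            raise InconsistencyError("joint distribution has a negative cell")
        object.__setattr__(self, "counts", full)

    def class_total(self, class_label: str) -> int:
        return sum(self.counts[(class_label, pat)] for pat in PATTERNS)

    def total(self) -> int:
        return sum(self.counts.values())

    def cell(self, class_label: str, pattern: tuple[bool, bool, bool]) -> int:
        return self.counts[(class_label, pattern)]

    @staticmethod
    def _key(pattern: tuple[bool, bool, bool]) -> str:
        return "".join("1" if b else "0" for b in pattern)

    def to_dict(self) -> dict:
        return {
            cls: {self._key(pat): self.counts[(cls, pat)] for pat in PATTERNS}
            for cls in CLASSES
        }

    @classmethod
    def from_dict(cls, data: dict) -> "JointDistribution":
        counts = {}
        for class_label, cells in data.items():
            for key, v in cells.items():
                pattern = tuple(ch == "1" for ch in key)
                counts[(class_label, pattern)] = int(v)
        return cls(counts)


def _reconstruct_class(m: ClassMarginals, class_label: str) -> dict:
    n12 = m.c1 + m.c2 - m.c1_or_c2
    n13 = m.c1 + m.c3 - m.c1_or_c3
    n23 = m.c2 + m.c3 - m.c2_or_c3
    t = m.all_three

    cells = {
        (True, True, True): t,
        (True, True, False): n12 - t,
        (True, False, True): n13 - t,
        (False, True, True): n23 - t,
        (True, False, False): m.c1 - n12 - n13 + t,
        (False, True, False): m.c2 - n12 - n23 + t,
        (False, False, True): m.c3 - n13 - n23 + t,
    }
    cells[(False, False, False)] = m.n_total - sum(cells.values())

    for pattern, v in cells.items():
        if v < 0:
            raise InconsistencyError(
                f"marginals for class {class_label!r} force a negative count "
                f"({v}) for pattern {JointDistribution._key(pattern)}",
                pattern=pattern,
                class_label=class_label,
            )
    return cells


def reconstruct_joint(m: MarginalTable) -> JointDistribution:
    """Invert the marginal system to the 16-cell joint; the at-least-k rows
    are not consulted (use :func:`verify_consistency` to check them)."""
    counts = {}
    for cls in CLASSES:
        for pattern, v in _reconstruct_class(m.for_class(cls), cls).items():
            counts[(cls, pattern)] = v
    return JointDistribution(counts)


def _marginals_of_class(j: JointDistribution, cls: str) -> ClassMarginals:
    def total(pred) -> int:
        return sum(j.cell(cls, p) for p in PATTERNS if pred(p))

    return ClassMarginals(
        n_total=total(lambda p: True),
        c1=total(lambda p: p[0]),
        c2=total(lambda p: p[1]),
        c3=total(lambda p: p[2]),
        c1_or_c2=total(lambda p: p[0] or p[1]),
        c1_or_c3=total(lambda p: p[0] or p[2]),
        c2_or_c3=total(lambda p: p[1] or p[2]),
        all_three=total(lambda p: all(p)),
        at_least_two=total(lambda p: sum(p) >= 2),
        at_least_one=total(lambda p: sum(p) >= 1),
    )


def compute_marginals(j: JointDistribution) -> MarginalTable:
    """Forward map: marginal counts (including the at-least-k rows) of a joint."""
    return MarginalTable(
        confirmed=_marginals_of_class(j, "confirmed"),
        not_confirmed=_marginals_of_class(j, "not_confirmed"),
    )


def verify_consistency(j: JointDistribution, m: MarginalTable) -> dict[tuple[str, str], int]:
    """Residuals (recomputed − stated) for every marginal of both classes.

    For an internally consistent table all residuals are zero, including the
    at-least-k rows that the reconstruction never used.
    """
    recomputed = compute_marginals(j)
    residuals: dict[tuple[str, str], int] = {}
    for cls in CLASSES:
        rec, ref = recomputed.for_class(cls), m.for_class(cls)
        for name in _MARGINAL_FIELDS:
            residuals[(cls, name)] = getattr(rec, name) - getattr(ref, name)
    return residuals


def materialize_fixture(
    j: JointDistribution,
    seed: int = 0,
    index_code: str = "L88",
    pct_female: float = 0.64,
) -> list[PatientRecord]:
    """One patient record per unit count of the joint, deterministic in ``seed``.

    Ages are drawn uniformly inside the band the patient's c3 flag dictates
    (30–61 if true, 62–85 if false); sex is apportioned to the target female
    fraction and shuffled; event scaffolding follows :func:`build_patient`.
    Running the criterion engine over the output reproduces ``j`` exactly.
    """
    rng = np.random.default_rng(seed)
    n = j.total()

    sexes = np.array(["male"] * n, dtype=object)
    n_female = int(round(pct_female * n))
    sexes[rng.permutation(n)[:n_female]] = "female"

    cohort: list[PatientRecord] = []
    idx = 0
    for cls in CLASSES:
        confirmed = cls == "confirmed"
        for pattern in PATTERNS:
            for _ in range(j.cell(cls, pattern)):
                age = int(rng.integers(30, 62) if pattern[2] else rng.integers(62, 86))
                offset = int(rng.integers(0, 340))
                cohort.append(
                    build_patient(
                        patient_id=f"T{idx:04d}",
                        pattern=pattern,
                        confirmed=confirmed,
                        sex=str(sexes[idx]),
                        age_at_index=age,
                        index_code=index_code,
                        index_day_offset=offset,
                        episode_variant=bool(idx % 2),
                    )
                )
                idx += 1
    return cohort
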