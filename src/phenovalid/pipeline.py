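"""End-to-end run configuration and the cohort -> report pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict

from .chart_review import DEFAULT_CONFIRMATORY_TERMS, ConfirmationVocabulary
from .criteria import (
    DEFAULT_DMARD_ATC_PREFIXES,
    AlgorithmSpec,
    CriterionProfile,
    MedicationCatalog,
    extract_profile,
)
from .errors import ConfigError
from .evaluation import ValidationReport, evaluate_algorithms, table1_report
from .records import PatientRecord, select_cohort

__all__ = ["RunConfig", "extract_profiles", "run_validation"]


class RunConfig(BaseModel):
    """All knobs of the validation analysis; defaults reproduce the published
    study design (L88 cohort, age 30+, cutoff 61, standard DMARD catalog)."""

    model_config = ConfigDict(frozen=True)

    index_code: str = "L88"
    min_age: int = 30
    age_cutoff: int = 61
    dmard_biologic_atc_prefixes: frozenset[str] = DEFAULT_DMARD_ATC_PREFIXES
    confirmatory_terms: frozenset[str] = DEFAULT_CONFIRMATORY_TERMS
    algorithms: Optional[tuple[AlgorithmSpec, ...]] = None  # None -> standard table
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "algorithms" in raw and raw["algorithms"] is not None:
            raw["algorithms"] = tuple(
                AlgorithmSpec(
                    criteria_used=frozenset(a["criteria"]),
                    min_satisfied=a.get("min_satisfied", 1),
                )
                for a in raw["algorithms"]
            )
        try:
            return cls.model_validate(raw)
        except Exception as exc:
            raise ConfigError(f"{path}: invalid run config: {exc}") from exc

    @property
    def catalog(self) -> MedicationCatalog:
        return MedicationCatalog(
            dmard_biologic_atc_prefixes=self.dmard_biologic_atc_prefixes
        )

    @property
    def vocabulary(self) -> ConfirmationVocabulary:
        return ConfirmationVocabulary(confirmatory_terms=self.confirmatory_terms)


def extract_profiles(
    cohort: Sequence[PatientRecord], config: Optional[RunConfig] = None
) -> list[CriterionProfile]:
    """Select the cohort per the configuration and extract criterion profiles."""
    config = config or RunConfig()
    selected = select_cohort(list(cohort), config.index_code, config.min_age)
    return [
        extract_profile(
            p,
            index_code=config.index_code,
            catalog=config.catalog,
            age_cutoff=config.age_cutoff,
            min_age=config.min_age,
            vocabulary=config.vocabulary,
        )
        for p in selected
    ]


def run_validation(
    cohort: Sequence[PatientRecord], config: Optional[RunConfig] = None
) -> ValidationReport:
    """Cohort in, validation report out: selection, profile extraction, and
    evaluation of the configured algorithms (or the standard nine)."""
    config = config or RunConfig()
    profiles = extract_profiles(cohort, config)
    if config.algorithms is None:
        return table1_report(profiles)
    return evaluate_algorithms(profiles, list(config.algorithms))
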