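"""Cohort serialization: JSON-lines record stream and four-table CSV layout.

Two equivalent on-disk layouts are supported:

* a record stream — one JSON-serialized :class:`PatientRecord` per line;
* a directory of four CSV tables — ``patients``, ``contacts``, ``episodes``,
  ``prescriptions`` — keyed by ``patient_id``.

Dates are ISO-8601, booleans ``true``/``false``, an empty string means an
absent ``linked_icpc_code``, and specialist terms in the tabular layout are
``|``-joined. Both layouts round-trip field-by-field.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .errors import IntegrityError, SchemaError
from .records import (
    ChartReviewOutcome,
    ContactEvent,
    EpisodeRecord,
    PatientRecord,
    PrescriptionEvent,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_cohort_jsonl",
    "write_cohort_jsonl",
    "read_cohort_tables",
    "write_cohort_tables",
]

_TERM_SEP = "|"

_TABLE_COLUMNS = {
    "patients": ["patient_id", "sex", "birth_date", "specialist_terms"],
    "contacts": ["patient_id", "date", "icpc_code"],
    "episodes": ["patient_id", "icpc_code", "start_date", "end_date"],
    "prescriptions": ["patient_id", "date", "atc_code", "linked_icpc_code", "is_repeat"],
}


def _check_unique_ids(cohort: list[PatientRecord]) -> None:
    seen: set[str] = set()
    for p in cohort:
        if p.patient_id in seen:
            raise IntegrityError(f"duplicate patient_id: {p.patient_id!r}")
        seen.add(p.patient_id)


# ---------------------------------------------------------------- JSON lines

def write_cohort_jsonl(cohort: list[PatientRecord], path: str | Path) -> None:
    _check_unique_ids(cohort)
    with open(path, "w", encoding="utf-8") as fh:
        for p in cohort:
            payload = p.model_dump(mode="json")
            payload["chart_review"]["specialist_terms"] = sorted(
                payload["chart_review"]["specialist_terms"]
            )
            fh.write(json.dumps(payload, sort_keys=True) + "\n")


def read_cohort_jsonl(path: str | Path) -> list[PatientRecord]:
    cohort: list[PatientRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                cohort.append(PatientRecord.model_validate(json.loads(line)))
            except (json.JSONDecodeError, ValidationError) as exc:
                raise SchemaError(f"{path}: malformed record at line {lineno}: {exc}") from exc
    _check_unique_ids(cohort)
    return cohort


# ------------------------------------------------------------- tabular (CSV)

def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / f"{name}.csv"
    if not path.exists():
        raise SchemaError(f"missing table file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _TABLE_COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _parse_bool(value: str, path_hint: str, lineno: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise SchemaError(f"{path_hint}: line {lineno}: invalid boolean {value!r}")


def read_cohort_tables(directory: str | Path) -> list[PatientRecord]:
    directory = Path(directory)
    patients = _read_table(directory, "patients")
    contacts = _read_table(directory, "contacts")
    episodes = _read_table(directory, "episodes")
    prescriptions = _read_table(directory, "prescriptions")

    ids = list(patients["patient_id"])
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise IntegrityError(f"duplicate patient_id: {dup!r}")
    known = set(ids)

    by_patient: dict[str, dict[str, list]] = {
        pid: {"contacts": [], "episodes": [], "prescriptions": []} for pid in ids
    }

    def _collect(df: pd.DataFrame, name: str, build):
        # CSV line numbers: header is line 1.
        for i, row in enumerate(df.itertuples(index=False), start=2):
            pid = row.patient_id
            if pid not in known:
                raise IntegrityError(
                    f"{directory / (name + '.csv')}: line {i}: "
                    f"unknown patient_id {pid!r}"
                )
            try:
                by_patient[pid][name].append(build(row))
            except ValidationError as exc:
                raise SchemaError(
                    f"{directory / (name + '.csv')}: malformed row at line {i}: {exc}"
                ) from exc

    _collect(
        contacts, "contacts",
        lambda r: ContactEvent(date=r.date, icpc_code=r.icpc_code),
    )
    _collect(
        episodes, "episodes",
        lambda r: EpisodeRecord(
            icpc_code=r.icpc_code, start_date=r.start_date, end_date=r.end_date
        ),
    )

    for i, row in enumerate(prescriptions.itertuples(index=False), start=2):
        pid = row.patient_id
        if pid not in known:
            raise IntegrityError(
                f"{directory / 'prescriptions.csv'}: line {i}: unknown patient_id {pid!r}"
            )
        try:
            by_patient[pid]["prescriptions"].append(
                PrescriptionEvent(
                    date=row.date,
                    atc_code=row.atc_code,
                    linked_icpc_code=row.linked_icpc_code or None,
                    is_repeat=_parse_bool(
                        row.is_repeat, str(directory / "prescriptions.csv"), i
                    ),
                )
            )
        except ValidationError as exc:
            raise SchemaError(
                f"{directory / 'prescriptions.csv'}: malformed row at line {i}: {exc}"
            ) from exc

    cohort: list[PatientRecord] = []
    for i, row in enumerate(patients.itertuples(index=False), start=2):
        terms = frozenset(t for t in row.specialist_terms.split(_TERM_SEP) if t)
        try:
            cohort.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    sex=row.sex,
                    birth_date=row.birth_date,
                    contacts=tuple(by_patient[row.patient_id]["contacts"]),
                    episodes=tuple(by_patient[row.patient_id]["episodes"]),
                    prescriptions=tuple(by_patient[row.patient_id]["prescriptions"]),
                    chart_review=ChartReviewOutcome(specialist_terms=terms),
                )
            )
        except ValidationError as exc:
            raise SchemaError(
                f"{directory / 'patients.csv'}: malformed row at line {i}: {exc}"
            ) from exc
    return cohort


def write_cohort_tables(cohort: list[PatientRecord], directory: str | Path) -> None:
    _check_unique_ids(cohort)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    patients_rows, contact_rows, episode_rows, rx_rows = [], [], [], []
    for p in cohort:
        patients_rows.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_date": p.birth_date.isoformat(),
                "specialist_terms": _TERM_SEP.join(
                    sorted(p.chart_review.specialist_terms)
                ),
            }
        )
        for c in p.contacts:
            contact_rows.append(
                {"patient_id": p.patient_id, "date": c.date.isoformat(),
                 "icpc_code": c.icpc_code}
            )
        for e in p.episodes:
            episode_rows.append(
                {"patient_id": p.patient_id, "icpc_code": e.icpc_code,
                 "start_date": e.start_date.isoformat(),
                 "end_date": e.end_date.isoformat()}
            )
        for rx in p.prescriptions:
            rx_rows.append(
                {"patient_id": p.patient_id, "date": rx.date.isoformat(),
                 "atc_code": rx.atc_code,
                 "linked_icpc_code": rx.linked_icpc_code or "",
                 "is_repeat": "true" if rx.is_repeat else "false"}
            )

    for name, rows in (
        ("patients", patients_rows),
        ("contacts", contact_rows),
        ("episodes", episode_rows),
        ("prescriptions", rx_rows),
    ):
        pd.DataFrame(rows, columns=_TABLE_COLUMNS[name]).to_csv(
            directory / f"{name}.csv", index=False
        )


# ------------------------------------------------------------------ frontend

def read_cohort(source: str | Path) -> list[PatientRecord]:
    """Read a cohort from a JSONL file or a four-table CSV directory."""
    source = Path(source)
    if source.is_dir():
        return read_cohort_tables(source)
    return read_cohort_jsonl(source)


def write_cohort(cohort: list[PatientRecord], target: str | Path) -> None:
    """Write a cohort; a path ending in ``.jsonl`` gets the record stream,
    anything else is treated as a table directory."""
    target = Path(target)
    if target.suffix == ".jsonl":
        write_cohort_jsonl(cohort, target)
    else:
        write_cohort_tables(cohort, target)
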