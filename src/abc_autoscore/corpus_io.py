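"""Reading and validation of note, diagnosis and label tables, plus cohort construction.

The study population is a chronic-pain cohort defined from diagnosis codes: a
patient qualifies when a chronic-pain ICD code appears on at least two distinct
calendar days (guarding against a single spurious billing code) and the patient
is at least 13 years old at the earliest qualifying code date.

File formats are deliberately plain: notes arrive as CSV or JSONL with
configurable column names, diagnoses and adjudication labels as CSV.  All
parsers fail loudly — a missing column raises :class:`SchemaError` naming the
column, a bad value raises :class:`RowError` carrying the row index — and never
return partial output.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Chronic-pain ICD-9/10 codes shipped as the default cohort definition.  This
#: is the printed example set, user-extensible via the CLI / CohortSpec.
DEFAULT_CHRONIC_PAIN_CODES = frozenset({"338.2", "338.21", "G89.2", "G89.21"})

DEFAULT_NOTE_COLUMNS = {
    "patient_id": "patient_id",
    "note_id": "note_id",
    "note_datetime": "note_datetime",
    "note_type": "note_type",
    "text": "text",
}
DEFAULT_DIAGNOSIS_COLUMNS = {"patient_id": "patient_id", "code": "code", "date": "date"}
DEFAULT_LABEL_COLUMNS = {"patient_id": "patient_id", "category": "category"}

LABEL_CATEGORIES = ("no", "some", "high")


class SchemaError(ValueError):
    """A table is missing a required column or violates a corpus invariant."""


class RowError(ValueError):
    """A single row holds an unparseable or invalid value."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclasses.dataclass(frozen=True)
class Note:
    """One clinical document tied to a patient and timestamp."""

    patient_id: str
    note_id: str
    note_datetime: dt.datetime
    note_type: str
    text: str


@dataclasses.dataclass(frozen=True)
class DiagnosisRecord:
    """One billed ICD-9/10 code on one calendar date."""

    patient_id: str
    code: str
    date: dt.date


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Cohort rule: codes on >= ``min_distinct_days`` days, age >= ``min_age_years``."""

    code_set: frozenset[str] = DEFAULT_CHRONIC_PAIN_CODES
    min_distinct_days: int = 2
    min_age_years: int = 13

    def __post_init__(self) -> None:
        if not self.code_set:
            raise ValueError("code_set must be non-empty")
        if self.min_distinct_days < 1:
            raise ValueError("min_distinct_days must be >= 1")
        if self.min_age_years < 0:
            raise ValueError("min_age_years must be >= 0")


@dataclasses.dataclass(frozen=True)
class AdjudicationLabel:
    """Manual-review outcome: no / some / high evidence, binarized as some+high."""

    patient_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in LABEL_CATEGORIES:
            raise ValueError(
                f"category must be one of {LABEL_CATEGORIES}, got {self.category!r}"
            )

    @property
    def binary_label(self) -> bool:
        return self.category != "no"


def normalize_code(code: str) -> str:
    return code.strip().upper()


def _parse_timestamp(value: object, row_index: int) -> dt.datetime:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise RowError(row_index, "missing note_datetime")
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise RowError(row_index, f"unparseable timestamp {value!r}") from exc
    if pd.isna(ts):
        raise RowError(row_index, f"unparseable timestamp {value!r}")
    if ts.tz is not None:
        ts = ts.tz_localize(None)  # timezone-naive by convention
    return ts.to_pydatetime()


def _parse_date(value: object, row_index: int) -> dt.date:
    return _parse_timestamp(value, row_index).date()


def _load_rows(path: Path, format: str) -> tuple[list[dict], list[str]]:
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return [dict(rec) for rec in df.to_dict("records")], list(df.columns)
    if format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        cols = sorted({k for r in rows for k in r})
        return rows, cols
    raise ValueError(f"unknown format {format!r}")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "jsonl" if path.suffix.lower() in {".jsonl", ".json", ".ndjson"} else "csv"


def parse_notes(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[Note]:
    """Read a note table (CSV or JSONL) into :class:`Note` records.

    ``column_map`` maps canonical field names to the file's column names;
    unmapped fields use the defaults.  ``note_type`` is optional and defaults
    to an empty string.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_NOTE_COLUMNS)
    cmap.update(column_map or {})
    rows, columns = _load_rows(path, _infer_format(path, format))
    if rows:
        for field in ("patient_id", "note_id", "note_datetime", "text"):
            if cmap[field] not in columns:
                raise SchemaError(f"missing required column {cmap[field]!r} for {field}")
    notes: list[Note] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(rows):
        pid = str(row.get(cmap["patient_id"], "") or "").strip()
        nid = str(row.get(cmap["note_id"], "") or "").strip()
        if not pid:
            raise RowError(i, "missing patient_id")
        if not nid:
            raise RowError(i, "missing note_id")
        if nid in seen_ids:
            raise SchemaError(f"duplicate note_id {nid!r} at row {i}")
        seen_ids.add(nid)
        when = _parse_timestamp(row.get(cmap["note_datetime"]), i)
        raw_text = row.get(cmap["text"], "")
        text = "" if raw_text is None else str(raw_text)
        note_type = str(row.get(cmap["note_type"], "") or "")
        notes.append(Note(pid, nid, when, note_type, text))
    logger.info("parsed %d notes from %s", len(notes), path)
    return notes


def write_notes_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    """Write notes as one JSON object per line (round-trips with parse_notes)."""
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "note_datetime": n.note_datetime.isoformat(),
                        "note_type": n.note_type,
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def parse_diagnoses(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[DiagnosisRecord]:
    """Read a diagnosis CSV; codes are uppercased and whitespace-stripped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_DIAGNOSIS_COLUMNS)
    cmap.update(column_map or {})
    rows, columns = _load_rows(path, "csv")
    if rows:
        for field in ("patient_id", "code", "date"):
            if cmap[field] not in columns:
                raise SchemaError(f"missing required column {cmap[field]!r} for {field}")
    records: list[DiagnosisRecord] = []
    for i, row in enumerate(rows):
        pid = str(row.get(cmap["patient_id"], "") or "").strip()
        if not pid:
            raise RowError(i, "missing patient_id")
        code = normalize_code(str(row.get(cmap["code"], "") or ""))
        if not code:
            raise RowError(i, "empty diagnosis code")
        records.append(DiagnosisRecord(pid, code, _parse_date(row.get(cmap["date"]), i)))
    logger.info("parsed %d diagnosis records from %s", len(records), path)
    return records


def parse_labels(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[AdjudicationLabel]:
    """Read a manual-review label CSV with category in {no, some, high}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_LABEL_COLUMNS)
    cmap.update(column_map or {})
    rows, columns = _load_rows(path, "csv")
    if rows:
        for field in ("patient_id", "category"):
            if cmap[field] not in columns:
                raise SchemaError(f"missing required column {cmap[field]!r} for {field}")
    labels: list[AdjudicationLabel] = []
    for i, row in enumerate(rows):
        pid = str(row.get(cmap["patient_id"], "") or "").strip()
        if not pid:
            raise RowError(i, "missing patient_id")
        cat = str(row.get(cmap["category"], "") or "").strip().lower()
        if cat not in LABEL_CATEGORIES:
            raise RowError(i, f"category must be one of {LABEL_CATEGORIES}, got {cat!r}")
        labels.append(AdjudicationLabel(pid, cat))
    return labels


def _age_in_years(birth: dt.date, on: dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def build_cohort(
    records: Iterable[DiagnosisRecord],
    birth_dates: Mapping[str, dt.date],
    spec: CohortSpec | None = None,
) -> dict[str, dt.date]:
    """Apply the cohort rule and return {patient_id: first qualifying code date}.

    A patient is included iff codes from ``spec.code_set`` occur on at least
    ``spec.min_distinct_days`` distinct calendar dates, and the patient's age at
    the earliest qualifying date is at least ``spec.min_age_years``.  Patients
    with qualifying codes but no birth date are excluded with a warning rather
    than assumed adult.
    """
    spec = spec or CohortSpec()
    codes = {normalize_code(c) for c in spec.code_set}
    days_by_patient: dict[str, set[dt.date]] = defaultdict(set)
    for rec in records:
        if normalize_code(rec.code) in codes:
            days_by_patient[rec.patient_id].add(rec.date)
    cohort: dict[str, dt.date] = {}
    for pid in sorted(days_by_patient):
        days = days_by_patient[pid]
        if len(days) < spec.min_distinct_days:
            continue
        first = min(days)
        birth = birth_dates.get(pid)
        if birth is None:
            logger.warning("patient %s qualifies but has no birth date; excluded", pid)
            continue
        if _age_in_years(birth, first) >= spec.min_age_years:
            cohort[pid] = first
    return cohort


def distinct_code_days(
    records: Iterable[DiagnosisRecord], code_set: Iterable[str]
) -> dict[str, int]:
    """Number of distinct calendar dates per patient carrying a code from ``code_set``."""
    codes = {normalize_code(c) for c in code_set}
    days: dict[str, set[dt.date]] = defaultdict(set)
    for rec in records:
        if normalize_code(rec.code) in codes:
            days[rec.patient_id].add(rec.date)
    return {pid: len(d) for pid, d in days.items()}
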