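"""Patient-level checklist scoring: item vectors, totals, thresholds.

Scoring is deliberately coarse: if one or more surviving matches for a given
item exist in any of a patient's in-window notes, the patient receives one
point for that item, regardless of how often it was mentioned.  The total
score (0-20) is the count of endorsed items, and a patient is classified
positive when the total reaches a threshold.  The operating threshold is
site-dependent; :func:`select_threshold` sweeps all 21 candidates and picks
the one maximizing F1 against adjudicated labels.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import Note
from .pattern_engine import Match, N_ITEMS


@dataclasses.dataclass(frozen=True)
class TimeWindow:
    """Optional cutoff: only notes dated on or before ``cutoff_date`` are scored.

    Mirrors the external-validation design where record review stopped at each
    patient's consent date, so the automated instrument must see the same notes.
    """

    cutoff_date: dt.date | None = None

    def contains(self, when: dt.datetime) -> bool:
        if self.cutoff_date is None:
            return True
        return when.date() <= self.cutoff_date


@dataclasses.dataclass(frozen=True)
class PatientItemVector:
    """Per-patient 20-item flag vector with total score and note coverage."""

    patient_id: str
    item_flags: tuple[bool, ...]
    n_notes_scanned: int

    def __post_init__(self) -> None:
        if len(self.item_flags) != N_ITEMS:
            raise ValueError(f"item_flags must have {N_ITEMS} entries")

    @property
    def total_score(self) -> int:
        return sum(self.item_flags)

    @property
    def no_notes_flag(self) -> bool:
        return self.n_notes_scanned == 0


@dataclasses.dataclass(frozen=True)
class Classification:
    patient_id: str
    threshold: int
    label: bool


def score_patients(
    matches: Iterable[Match],
    notes: Sequence[Note],
    window: TimeWindow | None = None,
    all_patients: Iterable[str] | None = None,
) -> list[PatientItemVector]:
    """Aggregate surviving matches into per-patient item vectors.

    Item flag *i* is set iff at least one match for item *i* occurs in an
    in-window note; match multiplicity is ignored.  Patients appearing in
    ``notes`` (or listed in ``all_patients``) but without matches receive
    all-false vectors; patients with zero notes carry ``no_notes_flag``.
    A match referencing an unknown note_id is a hard error.
    """
    window = window or TimeWindow()
    note_by_id: dict[str, Note] = {}
    for n in notes:
        note_by_id[n.note_id] = n
    n_notes: dict[str, int] = defaultdict(int)
    for n in notes:
        if window.contains(n.note_datetime):
            n_notes[n.patient_id] += 1
        else:
            n_notes.setdefault(n.patient_id, 0)
    patients = set(n_notes)
    if all_patients is not None:
        patients.update(all_patients)
    flags: dict[str, set[int]] = defaultdict(set)
    for m in matches:
        note = note_by_id.get(m.note_id)
        if note is None:
            raise ValueError(f"match references unknown note_id {m.note_id!r}")
        if not window.contains(note.note_datetime):
            continue
        flags[m.patient_id].add(m.item_id)
    vectors = []
    for pid in sorted(patients):
        item_flags = tuple(i + 1 in flags[pid] for i in range(N_ITEMS))
        vectors.append(PatientItemVector(pid, item_flags, n_notes.get(pid, 0)))
    return vectors


def classify(vector: PatientItemVector, threshold: int) -> Classification:
    """Positive iff ``total_score >= threshold`` (threshold 0 is always positive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return Classification(vector.patient_id, threshold, vector.total_score >= threshold)


def _f1(tp: int, fp: int, fn: int) -> float:
    if tp + fp == 0 or tp + fn == 0:
        return math.nan
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def threshold_sweep(
    vectors: Sequence[PatientItemVector], labels: Mapping[str, bool]
) -> pd.DataFrame:
    """Confusion counts and F1 for every threshold 0..20 (transparency table)."""
    scored = [(v.total_score, bool(labels[v.patient_id])) for v in vectors]
    rows = []
    for tau in range(N_ITEMS + 1):
        tp = sum(1 for s, y in scored if s >= tau and y)
        fp = sum(1 for s, y in scored if s >= tau and not y)
        fn = sum(1 for s, y in scored if s < tau and y)
        tn = sum(1 for s, y in scored if s < tau and not y)
        sens = tp / (tp + fn) if tp + fn else math.nan
        ppv = tp / (tp + fp) if tp + fp else math.nan
        rows.append(
            {
                "threshold": tau,
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "sensitivity": sens,
                "ppv": ppv,
                "f1": _f1(tp, fp, fn),
            }
        )
    return pd.DataFrame(rows)


def select_threshold(
    vectors: Sequence[PatientItemVector],
    labels: Mapping[str, bool],
    criterion: str = "max_f1",
) -> tuple[int, pd.DataFrame]:
    """Pick the score threshold maximizing F1; ties go to the smallest threshold.

    Returns the chosen threshold and the full 21-row sweep table.  Requires at
    least one positive and one negative label among the scored patients.
    """
    if criterion != "max_f1":
        raise ValueError(f"unknown criterion {criterion!r}")
    missing = [v.patient_id for v in vectors if v.patient_id not in labels]
    if missing:
        raise ValueError(f"no label for patients: {sorted(missing)[:5]}")
    ys = {bool(labels[v.patient_id]) for v in vectors}
    if ys != {True, False}:
        raise ValueError("labels must include at least one positive and one negative")
    table = threshold_sweep(vectors, labels)
    defined = table.dropna(subset=["f1"])
    best = defined["f1"].max()
    # mathematically equal F1 values can differ by an ulp; tie to smallest tau
    tau = int(defined.loc[defined["f1"] >= best - 1e-12, "threshold"].min())
    return tau, table


def vectors_to_frame(vectors: Sequence[PatientItemVector]) -> pd.DataFrame:
    """Flat per-patient score table (item_01..item_20 as 0/1 columns)."""
    rows = []
    for v in vectors:
        row: dict[str, object] = {"patient_id": v.patient_id}
        for i, flag in enumerate(v.item_flags, start=1):
            row[f"item_{i:02d}"] = int(flag)
        row["total_score"] = v.total_score
        row["n_notes_scanned"] = v.n_notes_scanned
        row["no_notes_flag"] = int(v.no_notes_flag)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_vectors(df: pd.DataFrame) -> list[PatientItemVector]:
    """Inverse of :func:`vectors_to_frame` (used by the CLI evaluate stage)."""
    out = []
    for _, row in df.iterrows():
        flags = tuple(bool(int(row[f"item_{i:02d}"])) for i in range(1, N_ITEMS + 1))
        out.append(
            PatientItemVector(
                str(row["patient_id"]), flags, int(row["n_notes_scanned"])
            )
        )
    return out
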