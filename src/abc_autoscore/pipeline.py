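"""End-to-end orchestration: match -> score -> (optional) evaluate.

Used by both the command-line interface and programmatic callers.  Every run
writes a manifest with input digests, the pattern-config hash and seeds so an
output directory is self-describing; re-running with identical inputs and
seeds reproduces byte-identical CSV/JSON payloads.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .config import PatternConfig
from .corpus_io import AdjudicationLabel, DiagnosisRecord, Note
from .evaluation import (
    binary_predictor_auc,
    confusion,
    metrics,
    phi_matrix,
    precision_recall_curve,
    roc_auc,
    stratify_by_score,
    icd_baseline,
)
from .pattern_engine import Match, match_corpus
from .scoring import (
    PatientItemVector,
    TimeWindow,
    score_patients,
    vectors_to_frame,
)

logger = logging.getLogger(__name__)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    subcommand: str
    timestamp: str
    input_digests: dict[str, str]
    pattern_config_hash: str | None
    seeds: dict[str, int]
    tool_version: str = __version__

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def matches_to_frame(matches: Sequence[Match]) -> pd.DataFrame:
    rows = []
    for m in matches:
        rows.append(
            {
                "patient_id": m.patient_id,
                "note_id": m.note_id,
                "item_id": m.item_id,
                "start": m.start,
                "end": m.end,
                "matched_text": m.matched_text,
                "sentence_text": m.sentence_text,
                "filters_passed": ";".join(f"{k}={v}" for k, v in m.filter_trail),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "note_id",
            "item_id",
            "start",
            "end",
            "matched_text",
            "sentence_text",
            "filters_passed",
        ],
    )


def evaluate_scores(
    vectors: Sequence[PatientItemVector],
    labels: Sequence[AdjudicationLabel],
    threshold: int,
    diagnoses: Sequence[DiagnosisRecord] | None = None,
    oud_codes: Sequence[str] | None = None,
    n_boot: int = 2000,
    seed: int = 7,
    include_no_notes: bool = False,
) -> dict[str, object]:
    """Full evaluation payload for scored patients with adjudicated labels.

    Patients without notes are excluded by default (they were never scanned);
    ``include_no_notes`` retains them as score 0.
    """
    if not include_no_notes:
        vectors = [v for v in vectors if not v.no_notes_flag]
    label_map = {l.patient_id: l.binary_label for l in labels}
    eval_vectors = [v for v in vectors if v.patient_id in label_map]
    if not eval_vectors:
        raise ValueError("no scored patients carry labels")
    y = {v.patient_id: label_map[v.patient_id] for v in eval_vectors}
    pred = {v.patient_id: v.total_score >= threshold for v in eval_vectors}
    c = confusion(pred, y)
    mset = metrics(c, ci="bootstrap", n_boot=n_boot, seed=seed)
    scores = [float(v.total_score) for v in eval_vectors]
    ys = [y[v.patient_id] for v in eval_vectors]
    roc = roc_auc(scores, ys, ci="bootstrap", n_boot=n_boot, seed=seed)
    pr = precision_recall_curve(scores, ys)
    payload: dict[str, object] = {
        "n_evaluated": c.n,
        "threshold": threshold,
        "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
        "metrics": mset.as_dict(),
        "roc_auc": roc.auc,
        "roc_auc_ci": list(roc.ci) if roc.ci else None,
        "roc_points": [list(p) for p in roc.points],
        "pr_points": [list(p) for p in pr.points],
        "bootstrap": {"B": n_boot, "seed": seed},
    }
    if diagnoses is not None and oud_codes:
        flags = icd_baseline(
            diagnoses, oud_codes, patients=[v.patient_id for v in eval_vectors]
        )
        c_icd = confusion(flags, y)
        payload["icd_baseline"] = {
            "confusion": {
                "tp": c_icd.tp,
                "fp": c_icd.fp,
                "tn": c_icd.tn,
                "fn": c_icd.fn,
            },
            "metrics": metrics(c_icd, ci="bootstrap", n_boot=n_boot, seed=seed).as_dict(),
            "auc": binary_predictor_auc(c_icd),
        }
    return payload


def run_pipeline(
    notes: Sequence[Note],
    pattern_config: PatternConfig,
    outdir: str | Path,
    labels: Sequence[AdjudicationLabel] | None = None,
    diagnoses: Sequence[DiagnosisRecord] | None = None,
    oud_codes: Sequence[str] | None = None,
    threshold: int = 2,
    window: TimeWindow | None = None,
    n_boot: int = 2000,
    seed: int = 7,
    manifest: RunManifest | None = None,
) -> Path:
    """Execute match -> score -> (evaluate if labels given); write outputs.

    Any stage failure removes partial outputs before re-raising so a run
    directory is either complete or absent.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        matchers = pattern_config.compile()
        matches = match_corpus(matchers, notes)
        logger.info("matched %d hits over %d notes", len(matches), len(notes))
        p = outdir / "matches.csv"
        matches_to_frame(matches).to_csv(p, index=False)
        written.append(p)

        vectors = score_patients(matches, notes, window=window)
        logger.info("scored %d patients", len(vectors))
        p = outdir / "scores.csv"
        vectors_to_frame(vectors).to_csv(p, index=False)
        written.append(p)

        if len(vectors) >= 2:
            pm = phi_matrix(vectors)
            p = outdir / "phi_matrix.csv"
            pm.to_frame().to_csv(p)
            written.append(p)

        if diagnoses is not None and oud_codes:
            p = outdir / "score_stratification.csv"
            stratify_by_score(vectors, diagnoses, oud_codes).to_csv(p, index=False)
            written.append(p)

        if labels is not None:
            payload = evaluate_scores(
                vectors,
                labels,
                threshold=threshold,
                diagnoses=diagnoses,
                oud_codes=oud_codes,
                n_boot=n_boot,
                seed=seed,
            )
            payload["pattern_config_hash"] = pattern_config.config_hash()
            p = outdir / "metrics.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written.append(p)
        else:
            logger.info("no labels supplied; evaluation skipped")

        manifest = manifest or RunManifest(
            subcommand="run",
            timestamp=dt.datetime.now().isoformat(timespec="seconds"),
            input_digests={},
            pattern_config_hash=pattern_config.config_hash(),
            seeds={"bootstrap": seed},
        )
        manifest.pattern_config_hash = pattern_config.config_hash()
        manifest.write(outdir / "manifest.json")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return outdir
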