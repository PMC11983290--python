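"""Synthetic multi-note patient corpora with planted checklist-item mentions.

The generator is the package's download-free test substrate.  It emulates the
*structure* of a chronic-pain EHR cohort — heavy-tailed per-patient note
counts, per-item mention prevalence, negated mentions, non-opioid decoys,
discharge-instruction boilerplate, score-dependent diagnosis-code prevalence —
while making no attempt at clinical-text realism (templates are intentionally
disjoint from any real patient text).

Every planted sentence is drawn from a fixed template bank aligned with the
default pattern configuration, so the match pipeline recovers the planted
ground truth exactly: a patient's true item flag is set iff at least one
surviving (non-negated, non-decoy) sentence was planted for that item.  A
``hard_mode`` switch adds paraphrase templates outside the pattern vocabulary
to create known false negatives for benchmarking; it breaks exact recovery by
design.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import AdjudicationLabel, DiagnosisRecord, Note
from .pattern_engine import N_ITEMS, match_corpus
from .scoring import score_patients, vectors_to_frame

#: Planted-sentence bank, aligned with data/default_patterns.yaml.
#: positive -> must survive the full filter chain for exactly its own item;
#: negated  -> hits the core expression but is vetoed by the negation filter;
#: decoy    -> hits the core expression but fails the opioid-context filter
#:             (only items that require opioid context have decoys).
ITEM_TEMPLATES: dict[int, dict[str, tuple[str, ...]]] = {
    1: {
        "positive": (
            "Patient admitted to illicit drug use over the weekend.",
            "Patient has a history of problem drinking.",
        ),
        "negated": ("Patient denies any illicit drug use.",),
        "decoy": (),
    },
    2: {
        "positive": (
            "Patient admits to hoarding pain medication at home.",
            "He has been stockpiling opioid pills in a drawer.",
        ),
        "negated": ("Patient denies hoarding pain medication.",),
        "decoy": ("Patient has been hoarding newspapers and magazines.",),
    },
    3: {
        "positive": ("She has been taking more oxycodone than prescribed.",),
        "negated": ("Patient denies taking more tramadol than prescribed.",),
        "decoy": ("He has been taking more vitamins than directed.",),
    },
    4: {
        "positive": (
            "Patient ran out of hydrocodone early again this month.",
            "Patient called requesting an early refill of percocet.",
        ),
        "negated": ("Patient denies running out of pain medication early.",),
        "decoy": ("We are running out of appointment slots early in the day.",),
    },
    5: {
        "positive": ("Patient has increased use of narcotics since the last visit.",),
        "negated": ("Patient has not increased use of opioid medication.",),
        "decoy": ("Patient increased use of her home exercise program.",),
    },
    6: {
        "positive": (
            "Patient took oxycodone prn instead of scheduled dosing.",
            "Patient used tramadol prn despite the time-contingent prescription.",
        ),
        "negated": ("Patient denies taking hydrocodone prn instead of scheduled dosing.",),
        "decoy": (),
    },
    7: {
        "positive": ("Patient obtained opioid prescriptions from multiple providers.",),
        "negated": ("Patient denies receiving narcotics from other providers.",),
        "decoy": ("Records were sent from multiple providers for review.",),
    },
    8: {
        "positive": ("Patient admitted he bought pain pills on the street.",),
        "negated": ("Patient denies buying narcotics on the street.",),
        "decoy": ("Patient bought a scooter on the street market.",),
    },
    9: {
        "positive": ("Patient appeared sedated with slurred speech during the visit.",),
        "negated": ("Patient was not sedated at today's visit.",),
        "decoy": (),
    },
    10: {
        "positive": ("Patient expressed worry about addiction to these medications.",),
        "negated": ("Patient denies worry about addiction or dependence.",),
        "decoy": (),
    },
    11: {
        "positive": (
            "Patient expressed concern about future availability of opioid medication.",
            "She asked whether she would have enough pain medication to last until her next visit.",
        ),
        "negated": ("Patient denies concern about future availability of narcotics.",),
        "decoy": ("Patient asked about future availability of clinic parking.",),
    },
    12: {
        "positive": ("Patient reported that her oxycodone was stolen from her car.",),
        "negated": ("Patient denies that any opioid medication was lost or stolen.",),
        "decoy": ("Patient reported that her umbrella was lost at the clinic.",),
    },
    13: {
        "positive": (
            "Patient states she needs her pain medication refilled today.",
            "Patient insists he must have opioids for the coming week.",
        ),
        "negated": ("Patient denies that she needs opioid medication at this time.",),
        "decoy": ("Patient needs a walker for safe ambulation.",),
    },
    14: {
        "positive": (
            "Discussion of analgesic medication was the predominant issue of the visit.",
            "Pain medication dosing was the main topic of the visit.",
        ),
        "negated": ("Analgesic medication was not the predominant issue of the visit.",),
        "decoy": ("Scheduling was the main topic of the visit.",),
    },
    15: {
        "positive": ("Patient was noncompliant with the recommended physical therapy.",),
        "negated": ("Patient denies noncompliance with the treatment plan.",),
        "decoy": (),
    },
    16: {
        "positive": ("Patient became angry when discussing her oxycodone refill.",),
        "negated": ("Patient was not angry when the opioid taper was discussed.",),
        "decoy": ("Patient was angry about the long wait time.",),
    },
    17: {
        "positive": ("Patient's wife expressed concern about his opioid use.",),
        "negated": (
            "Patient denies that his wife has concern about his pain medication use.",
        ),
        "decoy": ("Patient's daughter expressed concern about parking arrangements.",),
    },
    18: {
        "positive": (
            "Patient violated the terms of the pain contract.",
            "Patient had difficulty adhering to the medication agreement.",
        ),
        "negated": ("Patient has not violated the medication agreement.",),
        "decoy": (),
    },
    19: {
        "positive": (
            "Patient requested oxycodone by name at today's visit.",
            "Patient requested a specific narcotic at each visit.",
        ),
        "negated": ("Patient did not request any opioid by name.",),
        "decoy": ("Patient requested a specific appointment time.",),
    },
    20: {
        "positive": ("Urine drug screen was positive for unexpected substances.",),
        "negated": ("He denies that his urine drug screen was abnormal.",),
        "decoy": (),
    },
}

#: Paraphrases outside the pattern vocabulary: planted only in hard mode to
#: create documented false negatives.
HARD_MODE_TEMPLATES: dict[int, tuple[str, ...]] = {
    2: ("Patient keeps extra tablets hidden around the house.",),
    4: ("Patient exhausted her tablet supply well ahead of schedule.",),
    13: ("Patient was adamant about getting her tablets today.",),
}

#: Neutral clinical boilerplate giving notes realistic bulk; matches no item.
FILLER_SENTENCES: tuple[str, ...] = (
    "Vital signs were stable at today's visit.",
    "Reviewed laboratory results with the patient.",
    "Follow-up appointment scheduled in three months.",
    "Blood pressure was 128/76 and heart rate 72.",
    "Patient ambulating independently.",
    "Influenza vaccination administered during the visit.",
    "Diet and exercise counseling provided.",
    "Patient tolerated the procedure well.",
    "Imaging of the lumbar spine was reviewed.",
    "Continue current home exercise program.",
    "Sleep quality reported as fair.",
    "Patient will return to clinic as scheduled.",
)

#: Discharge-instruction boilerplate: the sentence after the header would
#: match an item but must be vetoed by the prefix-exclusion filter.
DISCHARGE_NOTE_BODIES: tuple[str, ...] = (
    (
        "Patient discharged home in stable condition.\n"
        "Discharge instructions: increase dose of oxycodone only as directed "
        "by the pain clinic.\nCall the office with any questions."
    ),
    (
        "Procedure completed without complication.\n"
        "Discharge instructions: patient must have analgesic medication "
        "available at home.\nReturn precautions were reviewed."
    ),
)

#: Default per-item mention probabilities.  Items 1 (general substance use)
#: and 14 (analgesics dominating the visit) are the most frequently
#: documented behaviors; the rest sit at low single-digit prevalence.
DEFAULT_ITEM_PROBS: tuple[float, ...] = (
    0.22, 0.06, 0.08, 0.10, 0.09, 0.03, 0.07, 0.03, 0.08, 0.06,
    0.04, 0.07, 0.10, 0.18, 0.08, 0.06, 0.05, 0.09, 0.07, 0.05,
)

CHRONIC_PAIN_CODE = "G89.21"
OUD_CODE = "F11.20"


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions.

    ``label_model`` is a logistic link from the true total score to the
    probability of being an adjudicated case; ``icd_*`` give the probability
    of carrying the OUD code on two distinct days given case/control status,
    producing the score-dependent code-prevalence gradient.
    """

    n_patients: int = 200
    seed: int = 0
    notes_per_patient_mean: float = 5.0
    notes_per_patient_dispersion: float = 1.2
    item_probs: tuple[float, ...] = DEFAULT_ITEM_PROBS
    negated_mention_rate: float = 0.15
    non_opioid_decoy_rate: float = 0.10
    discharge_decoy_rate: float = 0.15
    label_intercept: float = -1.6
    label_slope: float = 0.9
    icd_given_case: float = 0.30
    icd_given_control: float = 0.02
    icd_single_day_rate: float = 0.05
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.item_probs) != N_ITEMS:
            raise ValueError(f"item_probs must have {N_ITEMS} entries")
        probs = list(self.item_probs) + [
            self.negated_mention_rate,
            self.non_opioid_decoy_rate,
            self.discharge_decoy_rate,
            self.icd_given_case,
            self.icd_given_control,
            self.icd_single_day_rate,
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.notes_per_patient_mean < 1.0:
            raise ValueError("notes_per_patient_mean must be >= 1")
        if self.notes_per_patient_dispersion <= 0:
            raise ValueError("notes_per_patient_dispersion must be > 0")
        if self.label_slope < 0:
            raise ValueError("label_slope must be >= 0 (monotone link)")


@dataclasses.dataclass(frozen=True)
class SyntheticCorpus:
    """Generated corpus plus the exact planted ground truth."""

    notes: list[Note]
    diagnoses: list[DiagnosisRecord]
    labels: list[AdjudicationLabel]
    truth: pd.DataFrame
    birth_dates: dict[str, dt.date]
    config: SimulationConfig


def _n_notes(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # negative-binomial-shaped counts emulate heavy-tailed real note volumes
    r = dispersion
    p = r / (r + mean - 1.0)
    return 1 + int(rng.negative_binomial(r, p))


def generate_corpus(config: SimulationConfig) -> SyntheticCorpus:
    """Deterministically generate notes, diagnoses, labels and ground truth."""
    rng = np.random.default_rng(config.seed)
    base = dt.date(2020, 1, 1)
    notes: list[Note] = []
    diagnoses: list[DiagnosisRecord] = []
    labels: list[AdjudicationLabel] = []
    truth_rows: list[dict] = []
    birth_dates: dict[str, dt.date] = {}

    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:04d}"
        birth_dates[pid] = dt.date(int(rng.integers(1945, 1995)), int(rng.integers(1, 13)), 15)

        # chronic-pain qualifying codes on two distinct days for everyone
        d0 = base + dt.timedelta(days=int(rng.integers(0, 200)))
        diagnoses.append(DiagnosisRecord(pid, CHRONIC_PAIN_CODE, d0))
        diagnoses.append(
            DiagnosisRecord(pid, CHRONIC_PAIN_CODE, d0 + dt.timedelta(days=int(rng.integers(1, 90))))
        )

        flags = rng.random(N_ITEMS) < np.asarray(config.item_probs)
        planted: list[str] = []
        for item_id in range(1, N_ITEMS + 1):
            bank = ITEM_TEMPLATES[item_id]
            if flags[item_id - 1]:
                if (
                    config.hard_mode
                    and item_id in HARD_MODE_TEMPLATES
                    and rng.random() < 0.5
                ):
                    pool: Sequence[str] = HARD_MODE_TEMPLATES[item_id]
                else:
                    pool = bank["positive"]
                planted.append(pool[int(rng.integers(0, len(pool)))])
            if bank["negated"] and rng.random() < config.negated_mention_rate:
                planted.append(bank["negated"][int(rng.integers(0, len(bank["negated"])))])
            if bank["decoy"] and rng.random() < config.non_opioid_decoy_rate:
                planted.append(bank["decoy"][int(rng.integers(0, len(bank["decoy"])))])

        n_regular = _n_notes(
            rng, config.notes_per_patient_mean, config.notes_per_patient_dispersion
        )
        note_sentences: list[list[str]] = []
        for _ in range(n_regular):
            k = int(rng.integers(2, 5))
            note_sentences.append(
                [FILLER_SENTENCES[int(rng.integers(0, len(FILLER_SENTENCES)))] for _ in range(k)]
            )
        for sentence in planted:
            target = int(rng.integers(0, n_regular))
            pos = int(rng.integers(0, len(note_sentences[target]) + 1))
            note_sentences[target].insert(pos, sentence)

        bodies = [" ".join(s) for s in note_sentences]
        if rng.random() < config.discharge_decoy_rate:
            bodies.append(
                DISCHARGE_NOTE_BODIES[int(rng.integers(0, len(DISCHARGE_NOTE_BODIES)))]
            )
        for k, body in enumerate(bodies):
            when = dt.datetime.combine(
                base + dt.timedelta(days=int(rng.integers(0, 730))),
                dt.time(int(rng.integers(7, 19)), int(rng.integers(0, 60))),
            )
            notes.append(Note(pid, f"{pid}_N{k:03d}", when, "progress note", body))

        total = int(flags.sum())
        p_case = 1.0 / (1.0 + math.exp(-(config.label_intercept + config.label_slope * total)))
        is_case = bool(rng.random() < p_case)
        if is_case:
            category = "high" if rng.random() < 0.35 else "some"
        else:
            category = "no"
        labels.append(AdjudicationLabel(pid, category))

        p_icd = config.icd_given_case if is_case else config.icd_given_control
        has_icd = bool(rng.random() < p_icd)
        if has_icd:
            di = base + dt.timedelta(days=int(rng.integers(0, 400)))
            diagnoses.append(DiagnosisRecord(pid, OUD_CODE, di))
            diagnoses.append(
                DiagnosisRecord(pid, OUD_CODE, di + dt.timedelta(days=int(rng.integers(1, 120))))
            )
        elif rng.random() < config.icd_single_day_rate:
            # single spurious code day: stays negative under the >=2-day rule
            diagnoses.append(
                DiagnosisRecord(pid, OUD_CODE, base + dt.timedelta(days=int(rng.integers(0, 400))))
            )

        row: dict[str, object] = {"patient_id": pid}
        for i in range(N_ITEMS):
            row[f"item_{i + 1:02d}"] = int(flags[i])
        row["total_score"] = total
        row["is_case"] = int(is_case)
        row["category"] = category
        row["has_icd"] = int(has_icd)
        truth_rows.append(row)

    return SyntheticCorpus(
        notes=notes,
        diagnoses=diagnoses,
        labels=labels,
        truth=pd.DataFrame(truth_rows),
        birth_dates=birth_dates,
        config=config,
    )


def write_corpus(corpus: SyntheticCorpus, outdir) -> None:
    """Write notes.jsonl, diagnoses.csv, labels.csv, truth.csv to a directory."""
    from pathlib import Path

    from .corpus_io import write_notes_jsonl

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_notes_jsonl(corpus.notes, outdir / "notes.jsonl")
    pd.DataFrame(
        [
            {"patient_id": d.patient_id, "code": d.code, "date": d.date.isoformat()}
            for d in corpus.diagnoses
        ]
    ).to_csv(outdir / "diagnoses.csv", index=False)
    pd.DataFrame(
        [{"patient_id": l.patient_id, "category": l.category} for l in corpus.labels]
    ).to_csv(outdir / "labels.csv", index=False)
    corpus.truth.to_csv(outdir / "truth.csv", index=False)


def end_to_end_check(
    config: SimulationConfig, pattern_config=None
) -> dict[str, object]:
    """Generate a corpus, run match -> score, and report ground-truth recovery.

    Returns per-item exact-agreement rates between recovered and planted item
    flags, the overall flag-agreement rate, and the fraction of patients whose
    full 20-item vector (hence total score) is recovered exactly.  With the
    default template bank (hard_mode off) recovery is exact by construction.
    """
    from .config import default_pattern_config

    cfg = pattern_config or default_pattern_config()
    corpus = generate_corpus(config)
    matches = match_corpus(cfg.compile(), corpus.notes)
    vectors = score_patients(matches, corpus.notes)
    recovered = vectors_to_frame(vectors).set_index("patient_id")
    truth = corpus.truth.set_index("patient_id")
    item_cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    recovered = recovered.loc[truth.index]
    agree = recovered[item_cols].values == truth[item_cols].values
    per_item = {col: float(agree[:, j].mean()) for j, col in enumerate(item_cols)}
    return {
        "n_patients": len(truth),
        "per_item_recovery": per_item,
        "flag_recovery_rate": float(agree.mean()),
        "exact_vector_rate": float(agree.all(axis=1).mean()),
        "score_recovery_rate": float(
            (recovered["total_score"].values == truth["total_score"].values).mean()
        ),
    }
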