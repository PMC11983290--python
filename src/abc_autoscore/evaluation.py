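"""Validation battery for automated checklist scores against manual review.

Implements the metrics used to judge computational phenotypes: sensitivity,
specificity, PPV, NPV and F1 from a 2x2 confusion table; rank (Mann-Whitney)
ROC-AUC with explicit integer-threshold curves; recall-precision curves;
pairwise phi coefficients between the 20 binary items; the diagnosis-code
baseline (a code on at least two distinct days); score-stratified code
prevalence; and nonparametric patient-level bootstrap confidence intervals.

Undefined quantities (zero denominators) propagate as NaN, never as silent
zeros — this matters at extreme thresholds of the recall-precision curve and
for zero-variance items in the phi matrix.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corpus_io import DiagnosisRecord, distinct_code_days
from .pattern_engine import N_ITEMS
from .scoring import PatientItemVector

logger = logging.getLogger(__name__)

#: Default reconstructed OUD diagnosis codes for the synthetic baseline
#: (ICD-9 304.0x / ICD-10 F11.xx families are site-configurable).
DEFAULT_OUD_CODES = frozenset({"304.00", "304.01", "304.02", "F11.10", "F11.20", "F11.21"})


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class MetricSet:
    """Point estimates (NaN where undefined) with optional bootstrap CIs."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    ci: dict[str, tuple[float, float]] | None = None
    ci_method: str = "none"

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "ci_method": self.ci_method,
        }
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


@dataclasses.dataclass(frozen=True)
class CurveResult:
    points: tuple[tuple[float, float], ...]
    auc: float
    kind: str
    ci: tuple[float, float] | None = None


@dataclasses.dataclass(frozen=True)
class PhiMatrix:
    """Symmetric item-agreement matrix; NaN marks zero-variance (undefined) cells."""

    values: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        names = [f"item_{i:02d}" for i in range(1, self.values.shape[0] + 1)]
        return pd.DataFrame(self.values, index=names, columns=names)


def confusion(
    predicted: Mapping[str, bool], labels: Mapping[str, bool]
) -> ConfusionCounts:
    """Build the 2x2 table; prediction and label patient sets must coincide."""
    pset, lset = set(predicted), set(labels)
    if pset != lset:
        diff = sorted(pset.symmetric_difference(lset))
        raise ValueError(f"patient sets differ; symmetric difference: {diff[:10]}")
    if not pset:
        raise ValueError("no patients to evaluate")
    tp = fp = tn = fn = 0
    for pid in pset:
        p, y = bool(predicted[pid]), bool(labels[pid])
        if p and y:
            tp += 1
        elif p and not y:
            fp += 1
        elif not p and y:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _metric_values(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    npv = tn / (tn + fn) if tn + fn else math.nan
    if not math.isnan(ppv) and not math.isnan(sens):
        f1 = 0.0 if ppv + sens == 0 else 2 * ppv * sens / (ppv + sens)
    else:
        f1 = math.nan
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv, "f1": f1}


def metrics(
    c: ConfusionCounts,
    ci: str = "none",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MetricSet:
    """Confusion metrics with optional percentile-bootstrap CIs.

    With ``ci="bootstrap"``, patient-level resampling reduces to multinomial
    resampling of the four cells; resamples where a metric is undefined are
    skipped for that metric (logged).
    """
    if c.n == 0:
        raise ValueError("empty confusion table")
    vals = _metric_values(c.tp, c.fp, c.tn, c.fn)
    if ci == "none":
        return MetricSet(**vals)
    if ci != "bootstrap":
        raise ValueError(f"unknown ci method {ci!r}")
    rng = np.random.default_rng(seed)
    probs = np.array([c.tp, c.fp, c.tn, c.fn], dtype=float) / c.n
    draws = rng.multinomial(c.n, probs, size=n_boot)
    samples: dict[str, list[float]] = {k: [] for k in vals}
    n_undefined = 0
    for tp_b, fp_b, tn_b, fn_b in draws:
        vb = _metric_values(int(tp_b), int(fp_b), int(tn_b), int(fn_b))
        for k, v in vb.items():
            if math.isnan(v):
                n_undefined += 1
            else:
                samples[k].append(v)
    if n_undefined:
        logger.info("bootstrap: %d undefined metric resamples skipped", n_undefined)
    ci_bounds = {
        k: (
            float(np.percentile(s, 100 * alpha / 2)),
            float(np.percentile(s, 100 * (1 - alpha / 2))),
        )
        for k, s in samples.items()
        if s
    }
    return MetricSet(
        **vals, ci=ci_bounds, ci_method=f"percentile bootstrap B={n_boot} seed={seed}"
    )


def binary_predictor_auc(c: ConfusionCounts) -> float:
    """Exact rank-AUC of a binary predictor: (sensitivity + specificity) / 2."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("AUC requires at least one case and one control")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return (sens + spec) / 2


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(scores)  # average ranks handle ties (+1/2 per tie pair)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci: str = "none",
    n_boot: int = 2000,
    seed: int = 0,
) -> CurveResult:
    """Tie-corrected rank ROC-AUC with an integer-threshold operating curve.

    The AUC is the Mann-Whitney statistic P(score_case > score_control) +
    0.5 P(equal).  Curve points are (FPR, TPR) at every threshold in
    {0, ..., max_score + 1} for the rule "positive iff score >= threshold",
    ordered by increasing FPR; no interpolation is applied.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores and labels length mismatch")
    auc = _rank_auc(s, y)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    max_t = int(np.ceil(s.max())) + 1 if len(s) else 1
    pts = []
    for tau in range(0, max_t + 1):
        pred = s >= tau
        tpr = float((pred & y).sum() / n_pos)
        fpr = float((pred & ~y).sum() / n_neg)
        pts.append((fpr, tpr))
    pts.sort(key=lambda p: (p[0], p[1]))
    bounds = None
    if ci == "bootstrap":
        lo, hi = bootstrap_ci(
            lambda sv, yv: _rank_auc(np.asarray(sv, float), np.asarray(yv, bool)),
            s,
            y,
            n_boot=n_boot,
            seed=seed,
        )
        bounds = (lo, hi)
    return CurveResult(points=tuple(pts), auc=auc, kind="roc", ci=bounds)


def precision_recall_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> CurveResult:
    """Recall-precision points at every achievable integer threshold.

    Thresholds with no positive predictions have undefined precision and are
    omitted.  The reported area is the average precision over the retained
    points (a summary, not an interpolated integral).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("precision-recall requires at least one case")
    max_t = int(np.ceil(s.max())) + 1 if len(s) else 1
    pts = []
    for tau in range(0, max_t + 1):
        pred = s >= tau
        n_pred = int(pred.sum())
        if n_pred == 0:
            continue  # precision undefined at this threshold
        tp = int((pred & y).sum())
        pts.append((tp / n_pos, tp / n_pred))
    area = float(np.mean([p for _, p in pts])) if pts else math.nan
    return CurveResult(points=tuple(pts), auc=area, kind="precision_recall")


def phi_coefficient(a: Sequence[bool], b: Sequence[bool]) -> float:
    """Phi for two binary vectors; NaN when either has zero variance."""
    av = np.asarray(a, dtype=bool)
    bv = np.asarray(b, dtype=bool)
    n11 = int((av & bv).sum())
    n10 = int((av & ~bv).sum())
    n01 = int((~av & bv).sum())
    n00 = int((~av & ~bv).sum())
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return math.nan
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def phi_matrix(vectors: Sequence[PatientItemVector]) -> PhiMatrix:
    """Pairwise phi between all 20 items across patients (agreement structure)."""
    if len(vectors) < 2:
        raise ValueError("phi matrix requires at least 2 patients")
    flags = np.array([v.item_flags for v in vectors], dtype=bool)
    k = N_ITEMS
    values = np.full((k, k), math.nan)
    for i in range(k):
        for j in range(i, k):
            phi = phi_coefficient(flags[:, i], flags[:, j])
            values[i, j] = values[j, i] = phi
    defined = ~np.isnan(values)
    return PhiMatrix(values=values, defined=defined)


def icd_baseline(
    diagnoses: Iterable[DiagnosisRecord],
    code_set: Iterable[str],
    patients: Iterable[str] | None = None,
    min_distinct_days: int = 2,
) -> dict[str, bool]:
    """Diagnosis-code comparator: positive iff codes on >= ``min_distinct_days`` days.

    ``patients`` fixes the evaluation universe so patients without any code
    are explicit negatives.
    """
    code_set = set(code_set)
    if not code_set:
        raise ValueError("code_set must be non-empty")
    days = distinct_code_days(diagnoses, code_set)
    universe = set(patients) if patients is not None else set(days)
    return {pid: days.get(pid, 0) >= min_distinct_days for pid in sorted(universe)}


def stratify_by_score(
    vectors: Sequence[PatientItemVector],
    diagnoses: Iterable[DiagnosisRecord] | None = None,
    code_set: Iterable[str] | None = None,
    icd_flags: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Code prevalence by total score: one row per observed score level.

    Columns: score, n, icd_positive, pct_icd_positive (1 decimal place).
    Provide either precomputed ``icd_flags`` or ``diagnoses`` + ``code_set``.
    """
    if icd_flags is None:
        if diagnoses is None or code_set is None:
            raise ValueError("provide icd_flags or diagnoses + code_set")
        icd_flags = icd_baseline(
            diagnoses, code_set, patients=[v.patient_id for v in vectors]
        )
    rows = []
    by_score: dict[int, list[PatientItemVector]] = {}
    for v in vectors:
        by_score.setdefault(v.total_score, []).append(v)
    for score in sorted(by_score):
        group = by_score[score]
        pos = sum(1 for v in group if icd_flags.get(v.patient_id, False))
        rows.append(
            {
                "score": score,
                "n": len(group),
                "icd_positive": pos,
                "pct_icd_positive": round(100 * pos / len(group), 1),
            }
        )
    return pd.DataFrame(rows, columns=["score", "n", "icd_positive", "pct_icd_positive"])


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    values: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap over patient-level resamples; deterministic per seed.

    Resamples on which the statistic is undefined (NaN or raises on degenerate
    composition, e.g. no cases drawn) are redrawn, with the count logged; after
    ``100 * n_boot`` failed attempts a ValueError is raised.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    v = np.asarray(values)
    y = np.asarray(labels, dtype=bool)
    if len(v) != len(y) or len(v) == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    rng = np.random.default_rng(seed)
    stats: list[float] = []
    redrawn = 0
    attempts = 0
    max_attempts = 100 * n_boot
    while len(stats) < n_boot:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("bootstrap: statistic undefined on too many resamples")
        idx = rng.integers(0, len(v), size=len(v))
        try:
            val = statistic(v[idx], y[idx])
        except ValueError:
            redrawn += 1
            continue
        if val is None or (isinstance(val, float) and math.isnan(val)):
            redrawn += 1
            continue
        stats.append(float(val))
    if redrawn:
        logger.info("bootstrap: %d degenerate resamples redrawn", redrawn)
    return (
        float(np.percentile(stats, 100 * alpha / 2)),
        float(np.percentile(stats, 100 * (1 - alpha / 2))),
    )
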