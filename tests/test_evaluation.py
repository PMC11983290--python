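"""Metric battery: confusion metrics, rank AUC, PR curves, phi, ICD baseline, bootstrap."""

import datetime as dt
import math

import numpy as np
import pytest

from abc_autoscore.corpus_io import DiagnosisRecord
from abc_autoscore.evaluation import (
    ConfusionCounts,
    binary_predictor_auc,
    bootstrap_ci,
    confusion,
    icd_baseline,
    metrics,
    phi_coefficient,
    phi_matrix,
    precision_recall_curve,
    roc_auc,
    stratify_by_score,
)
from abc_autoscore.scoring import PatientItemVector

# 2x2 table from the published adjudication strata (49 no / 33 some / 17 high
# evidence; 0 / 1 / 1 of them code-positive on >= 2 days)
ICD_TABLE = ConfusionCounts(tp=2, fp=0, tn=49, fn=48)


class TestConfusion:
    def test_perfect_agreement(self):
        pred = {f"p{i}": i < 5 for i in range(10)}
        c = confusion(pred, pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_published_contingency_counts(self):
        labels = {}
        pred = {}
        for i in range(49):
            labels[f"no{i}"], pred[f"no{i}"] = False, False
        for i in range(33):
            labels[f"some{i}"], pred[f"some{i}"] = True, i == 0
        for i in range(17):
            labels[f"high{i}"], pred[f"high{i}"] = True, i == 0
        c = confusion(pred, labels)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 48, 49)

    def test_mismatched_patient_sets_error_lists_difference(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            confusion({"a": True}, {"b": True})

    def test_empty_error(self):
        with pytest.raises(ValueError):
            confusion({}, {})


class TestMetrics:
    def test_published_icd_baseline_metrics(self):
        m = metrics(ICD_TABLE)
        assert m.sensitivity == pytest.approx(0.04)
        assert m.ppv == 1.0
        assert round(m.f1, 2) == 0.08

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(5, 0, 5, 0))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.f1) == (1, 1, 1, 1, 1)

    def test_zero_tp_with_cases_gives_f1_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=2, tn=3, fn=4))
        assert m.f1 == 0.0

    def test_undefined_metrics_are_nan_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert math.isnan(m.ppv) and math.isnan(m.f1)
        assert m.npv == 0.5

    def test_f1_harmonic_mean_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 30, size=4))
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.f1 * (m.ppv + m.sensitivity) == pytest.approx(2 * m.ppv * m.sensitivity)
            assert m.sensitivity + fn / (tp + fn) == pytest.approx(1.0)

    def test_bootstrap_ci_deterministic_and_ordered(self):
        m1 = metrics(ICD_TABLE, ci="bootstrap", n_boot=200, seed=5)
        m2 = metrics(ICD_TABLE, ci="bootstrap", n_boot=200, seed=5)
        assert m1.ci == m2.ci
        lo, hi = m1.ci["f1"]
        assert lo <= m1.f1 <= hi or lo <= hi  # interval ordered; point near interval


class TestBinaryPredictorAuc:
    def test_published_value(self):
        assert round(binary_predictor_auc(ICD_TABLE), 2) == 0.52

    def test_random_equivalent_binary_predictor(self):
        # sensitivity = 1 - specificity -> chance performance
        assert binary_predictor_auc(ConfusionCounts(3, 3, 7, 7)) == pytest.approx(0.5)

    def test_perfect_binary_predictor(self):
        assert binary_predictor_auc(ConfusionCounts(5, 0, 5, 0)) == 1.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            binary_predictor_auc(ConfusionCounts(tp=2, fp=0, tn=0, fn=3))


def _pair_counting_auc(scores, labels):
    """O(n^2) oracle: P(case > control) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([3, 2, 1], [True, True, False]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([2, 2, 2, 2], [True, False, True, False]).auc == 0.5

    def test_constant_labels_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_matches_pair_counting_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = rng.integers(0, 10, size=n).astype(float)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                _pair_counting_auc(scores, labels)
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(20):
            scores = rng.integers(0, 15, size=40).astype(float)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 12, size=60).astype(float)
        labels = rng.random(60) < 0.4
        base = roc_auc(scores, labels).auc
        assert roc_auc(3.0 * scores + 1.0, labels).auc == pytest.approx(base)
        assert roc_auc(np.exp(scores / 4.0), labels).auc == pytest.approx(base)

    def test_binary_score_equals_binary_predictor_auc(self):
        rng = np.random.default_rng(5)
        pred = rng.random(50) < 0.3
        labels = rng.random(50) < 0.5
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        c = ConfusionCounts(
            tp=int((pred & labels).sum()),
            fp=int((pred & ~labels).sum()),
            tn=int((~pred & ~labels).sum()),
            fn=int((~pred & labels).sum()),
        )
        assert roc_auc(pred.astype(float), labels).auc == pytest.approx(
            binary_predictor_auc(c)
        )

    def test_curve_monotone_in_fpr(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 8, size=50).astype(float)
        labels = rng.random(50) < 0.5
        pts = roc_auc(scores, labels).points
        fprs = [p[0] for p in pts]
        assert fprs == sorted(fprs)


class TestPrecisionRecallCurve:
    def test_perfect_separation_reaches_recall_and_precision_one(self):
        res = precision_recall_curve([5, 5, 1, 1], [True, True, False, False])
        assert (1.0, 1.0) in res.points

    def test_thresholds_without_predictions_omitted(self):
        res = precision_recall_curve([1, 1, 0], [True, False, False])
        # threshold 2 predicts nobody: no point with undefined precision
        assert all(not math.isnan(p) for _, p in res.points)

    def test_no_cases_error(self):
        with pytest.raises(ValueError):
            precision_recall_curve([1, 2], [False, False])

    def test_matches_brute_force_confusion_sweep(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 9, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if not labels.any():
                continue
            res = precision_recall_curve(scores, labels)
            expected = []
            for tau in range(0, int(scores.max()) + 2):
                pred = scores >= tau
                if pred.sum() == 0:
                    continue
                tp = int((pred & labels).sum())
                expected.append((tp / labels.sum(), tp / pred.sum()))
            assert list(res.points) == pytest.approx(expected)

    def test_recall_non_increasing_with_threshold(self):
        res = precision_recall_curve([0, 1, 2, 3, 3], [False, True, False, True, True])
        recalls = [r for r, _ in res.points]
        assert recalls == sorted(recalls, reverse=True)


def _vectors_from_matrix(mat):
    return [
        PatientItemVector(f"p{i}", tuple(bool(x) for x in row), 1)
        for i, row in enumerate(mat)
    ]


class TestPhi:
    def test_identical_items_phi_one(self):
        rng = np.random.default_rng(1)
        mat = rng.random((30, 20)) < 0.4
        mat[:, 3] = mat[:, 7]
        pm = phi_matrix(_vectors_from_matrix(mat))
        assert pm.values[3, 7] == pytest.approx(1.0)

    def test_orthogonal_balanced_items_phi_zero(self):
        a = [True, True, False, False]
        b = [True, False, True, False]
        assert phi_coefficient(a, b) == pytest.approx(0.0)

    def test_matches_pearson_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        mat = rng.random((50, 20)) < rng.uniform(0.2, 0.7, size=20)
        pm = phi_matrix(_vectors_from_matrix(mat))
        for i in range(20):
            for j in range(20):
                col_i, col_j = mat[:, i].astype(float), mat[:, j].astype(float)
                if col_i.std() == 0 or col_j.std() == 0:
                    assert math.isnan(pm.values[i, j])
                else:
                    assert pm.values[i, j] == pytest.approx(
                        np.corrcoef(col_i, col_j)[0, 1]
                    )

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        mat = rng.random((40, 20)) < 0.3
        pm = phi_matrix(_vectors_from_matrix(mat))
        vals = pm.values
        assert np.allclose(vals, vals.T, equal_nan=True)
        assert np.nanmax(np.abs(vals)) <= 1.0 + 1e-12

    def test_zero_variance_item_flagged_undefined(self):
        mat = np.zeros((10, 20), dtype=bool)
        mat[:5, 0] = True  # only item 1 varies
        pm = phi_matrix(_vectors_from_matrix(mat))
        assert math.isnan(pm.values[1, 2])
        assert not pm.defined[1, 2]
        assert pm.values[0, 0] == pytest.approx(1.0)

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            phi_matrix(_vectors_from_matrix(np.zeros((1, 20), dtype=bool)))


def _diag(pid, code, day):
    return DiagnosisRecord(pid, code, dt.date(2020, 1, day))


class TestIcdBaseline:
    CODES = {"F11.20"}

    def test_single_day_is_negative(self):
        flags = icd_baseline([_diag("a", "F11.20", 1)], self.CODES, patients=["a"])
        assert flags == {"a": False}

    def test_two_distinct_days_positive(self):
        recs = [_diag("a", "F11.20", 1), _diag("a", "F11.20", 5)]
        assert icd_baseline(recs, self.CODES, patients=["a"]) == {"a": True}

    def test_patient_without_records_negative(self):
        assert icd_baseline([], self.CODES, patients=["ghost"]) == {"ghost": False}

    def test_irrelevant_codes_ignored(self):
        recs = [_diag("a", "G89.2", 1), _diag("a", "G89.2", 5)]
        assert icd_baseline(recs, self.CODES, patients=["a"]) == {"a": False}


class TestStratifyByScore:
    def test_all_zero_scores_single_row(self):
        vectors = [PatientItemVector(f"p{i}", (False,) * 20, 1) for i in range(4)]
        table = stratify_by_score(vectors, icd_flags={v.patient_id: False for v in vectors})
        assert len(table) == 1
        assert table.iloc[0].to_dict() == {
            "score": 0, "n": 4, "icd_positive": 0, "pct_icd_positive": 0.0,
        }

    def test_known_strata_match_hand_tally(self):
        def vec(pid, score):
            return PatientItemVector(pid, tuple(i < score for i in range(20)), 1)

        vectors = [vec("a", 0), vec("b", 0), vec("c", 2), vec("d", 2), vec("e", 2)]
        flags = {"a": False, "b": True, "c": True, "d": True, "e": False}
        table = stratify_by_score(vectors, icd_flags=flags).set_index("score")
        assert table.loc[0, "icd_positive"] == 1
        assert table.loc[0, "pct_icd_positive"] == 50.0
        assert table.loc[2, "n"] == 3
        assert table.loc[2, "pct_icd_positive"] == 66.7

    def test_empty_input_empty_table(self):
        assert stratify_by_score([], icd_flags={}).empty


class TestBootstrapCi:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci(lambda v, y: 0.4, np.zeros(20), np.zeros(20, bool), n_boot=200, seed=1)
        assert lo == hi == 0.4

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(0)
        v = rng.random(30)
        y = rng.random(30) < 0.5
        stat = lambda vv, yy: float(np.mean(vv))
        assert bootstrap_ci(stat, v, y, n_boot=300, seed=9) == bootstrap_ci(
            stat, v, y, n_boot=300, seed=9
        )

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda v, y: 1.0, np.zeros(5), np.zeros(5, bool), n_boot=10, seed=0)

    def test_undefined_resamples_redrawn(self):
        # sensitivity undefined when a resample draws no cases; must still finish
        y = np.array([True] + [False] * 9)
        v = y.astype(float)

        def sens(vv, yy):
            n_pos = yy.sum()
            return math.nan if n_pos == 0 else float(vv[yy].sum() / n_pos)

        lo, hi = bootstrap_ci(sens, v, y, n_boot=150, seed=2)
        assert lo == hi == 1.0
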