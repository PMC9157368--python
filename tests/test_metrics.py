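"""Segmentation measures against a brute-force oracle and worked cases."""

import numpy as np
import pytest

from plantseg3d.inference import assign_instance_class
from plantseg3d.metrics import (evaluate_cloud, instance_metrics, report,
                                semantic_metrics)

# ---------------------------------------------------------------------------
# Independent brute-force oracle (pure python double loops, no shared code)
# ---------------------------------------------------------------------------

def oracle_semantic(pred, gt, n_classes):
    out = {}
    for c in range(n_classes):
        tp = sum(1 for p, g in zip(pred, gt) if p == c and g == c)
        fp = sum(1 for p, g in zip(pred, gt) if p == c and g != c)
        fn = sum(1 for p, g in zip(pred, gt) if p != c and g == c)
        if tp + fp + fn == 0:
            continue
        prec = 100 * tp / (tp + fp) if tp + fp else float("nan")
        rec = 100 * tp / (tp + fn) if tp + fn else float("nan")
        f1 = (0.0 if (prec == 0 or rec == 0)
              else (float("nan") if (np.isnan(prec) or np.isnan(rec))
                    else 2 * prec * rec / (prec + rec)))
        out[c] = {"Prec": prec, "Rec": rec, "F1": f1,
                  "IoU": 100 * tp / (tp + fp + fn)}
    return out


def oracle_instance(ins_pred, cls_pred, ins_gt, cls_gt, classes):
    def sets_of(ins, cls, c):
        return [set(np.flatnonzero(ins == i).tolist())
                for i in sorted(set(ins.tolist())) if cls[i] == c]

    def iou(a, b):
        return len(a & b) / len(a | b) if a | b else 0.0

    out = {}
    for c in classes:
        gts = sets_of(ins_gt, cls_gt, c)
        preds = sets_of(ins_pred, cls_pred, c)
        if not gts:
            continue
        best = [max((iou(g, p) for p in preds), default=0.0) for g in gts]
        # IoU > 0.5 pairs are automatically one-to-one (each side's overlap
        # majority is unique), so counting pairs equals the maximum matching
        tp = sum(1 for g in gts for p in preds if iou(g, p) > 0.5)
        total_size = sum(len(g) for g in gts)
        out[c] = {
            "mPrec": 100 * tp / len(preds) if preds else float("nan"),
            "mRec": 100 * tp / len(gts),
            "mCov": 100 * sum(best) / len(gts),
            "mWCov": 100 * sum(len(g) / total_size * b for g, b in zip(gts, best)),
        }
    return out


def random_labeling(r, n=200):
    ins_gt = r.integers(0, 5, size=n)
    cls_of_gt = {i: int(r.integers(0, 3)) for i in range(5)}
    sem_gt = np.array([cls_of_gt[i] for i in ins_gt])
    ins_pred = r.integers(0, 5, size=n)
    cls_of_pred = {i: int(r.integers(0, 3)) for i in range(5)}
    sem_pred = np.array([cls_of_pred[i] for i in ins_pred])
    return sem_pred, sem_gt, ins_pred, cls_of_pred, ins_gt, cls_of_gt


class TestSemanticMetrics:
    def test_worked_confusion_case(self):
        # TP=50, FP=10, FN=40 for class 0
        gt = np.array([0] * 90 + [1] * 10)
        pred = np.array([0] * 50 + [1] * 40 + [0] * 10)
        m = semantic_metrics(pred, gt, 2)[0]
        assert m["Prec"] == pytest.approx(83.33, abs=0.01)
        assert m["Rec"] == pytest.approx(55.56, abs=0.01)
        assert m["F1"] == pytest.approx(66.67, abs=0.01)
        assert m["IoU"] == pytest.approx(50.00, abs=0.01)

    def test_perfect_prediction_scores_100(self, rng):
        gt = rng.integers(0, 4, size=100)
        for c, m in semantic_metrics(gt, gt, 6).items():
            assert all(v == pytest.approx(100.0) for v in m.values())

    def test_disjoint_prediction_scores_0(self):
        m = semantic_metrics(np.ones(10, int), np.zeros(10, int), 2)
        assert m[0]["Rec"] == 0.0 and m[0]["IoU"] == 0.0

    def test_f1_is_harmonic_mean(self, rng):
        pred, gt = rng.integers(0, 3, 150), rng.integers(0, 3, 150)
        for m in semantic_metrics(pred, gt, 3).values():
            expect = 2 * m["Prec"] * m["Rec"] / (m["Prec"] + m["Rec"])
            assert m["F1"] == pytest.approx(expect)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            semantic_metrics(np.zeros(3, int), np.zeros(4, int), 2)


class TestInstanceMetrics:
    def test_perfect_prediction_scores_100(self):
        ins = np.array([0] * 30 + [1] * 20)
        cls = {0: 1, 1: 1}
        m = instance_metrics(ins, cls, ins, cls, [1])[1]
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_split_instance_against_oracle(self):
        # GT sizes 60/40; prediction splits the 60 into 30+30, keeps the 40
        ins_gt = np.array([0] * 60 + [1] * 40)
        ins_pred = np.array([0] * 30 + [1] * 30 + [2] * 40)
        cls = {0: 1, 1: 1, 2: 1}
        got = instance_metrics(ins_pred, cls, ins_gt, {0: 1, 1: 1}, [1])
        want = oracle_instance(ins_pred, cls, ins_gt, {0: 1, 1: 1}, [1])
        for k in ("mPrec", "mRec", "mCov", "mWCov"):
            assert got[1][k] == pytest.approx(want[1][k], abs=1e-9)

    def test_iou_040_is_not_a_true_positive(self):
        # lone prediction covering 40 of a 100-point GT instance: IoU = 0.4
        ins_gt = np.zeros(100, int)
        ins_pred = np.array([0] * 40 + [1] * 60)
        got = instance_metrics(ins_pred, {0: 1, 1: 2}, ins_gt, {0: 1}, [1])[1]
        assert got["mPrec"] == 0.0 and got["mRec"] == 0.0
        assert got["mCov"] == pytest.approx(40.0)

    def test_exact_half_iou_is_not_counted(self):
        # two predictions each covering half of one GT instance: IoU = 0.5
        # exactly, and the threshold is strict (> 0.5)
        ins_gt = np.zeros(30, int)
        ins_pred = np.array([0] * 15 + [1] * 15)
        got = instance_metrics(ins_pred, {0: 1, 1: 1}, ins_gt, {0: 1}, [1])[1]
        assert got["mRec"] == 0.0

    def test_oracle_equivalence_on_random_labelings(self):
        r = np.random.default_rng(77)
        for _ in range(30):
            sp, sg, ip_, cp, ig, cg = random_labeling(r)
            got_sem = semantic_metrics(sp, sg, 3)
            want_sem = oracle_semantic(sp, sg, 3)
            for c in want_sem:
                for k, v in want_sem[c].items():
                    if np.isnan(v):
                        assert np.isnan(got_sem[c][k])
                    else:
                        assert got_sem[c][k] == pytest.approx(v, abs=1e-9)
            got = instance_metrics(ip_, cp, ig, cg, [0, 1, 2])
            want = oracle_instance(ip_, cp, ig, cg, [0, 1, 2])
            assert set(got) == set(want)
            for c in want:
                for k, v in want[c].items():
                    if np.isnan(v):
                        assert np.isnan(got[c][k])
                    else:
                        assert got[c][k] == pytest.approx(v, abs=1e-9)

    def test_wcov_equals_cov_for_equal_sizes(self):
        ins_gt = np.array([0] * 25 + [1] * 25)
        ins_pred = np.array([0] * 20 + [2] * 5 + [1] * 20 + [2] * 5)
        m = instance_metrics(ins_pred, {0: 1, 1: 1, 2: 1}, ins_gt,
                             {0: 1, 1: 1}, [1])[1]
        assert m["mCov"] == pytest.approx(m["mWCov"])


class TestReport:
    def _eval(self, sem_pred, ins_pred, sem_gt, ins_gt):
        cls = assign_instance_class(sem_pred, ins_pred)
        return evaluate_cloud(sem_pred, ins_pred, cls, sem_gt, ins_gt, 3, [1, 2])

    def test_single_cloud_report_equals_cloud_metrics(self, rng):
        sem = rng.integers(1, 3, 120)
        ins = rng.integers(0, 4, 120)
        sem_gt = np.array([int(1 + i % 2) for i in ins])
        e = self._eval(sem, ins, sem_gt, ins)
        rep = report([e], 3, [1, 2])
        single = instance_metrics(ins, assign_instance_class(sem, ins), ins,
                                  {i: int(1 + i % 2) for i in range(4)}, [1, 2])
        for c in single:
            for k, v in single[c].items():
                got = rep.per_leafclass[c][k]
                assert (np.isnan(v) and np.isnan(got)) or got == pytest.approx(v)

    def test_duplicating_clouds_leaves_report_unchanged(self, rng):
        sem = rng.integers(1, 3, 80)
        ins = rng.integers(0, 3, 80)
        sem_gt = np.array([int(1 + i % 2) for i in ins])
        e = self._eval(sem, ins, sem_gt, ins)
        r1 = report([e], 3, [1, 2])
        r2 = report([e, e, e], 3, [1, 2])
        for c in r1.per_leafclass:
            for k in r1.per_leafclass[c]:
                a, b = r1.per_leafclass[c][k], r2.per_leafclass[c][k]
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
        for c in r1.per_class:
            for k in r1.per_class[c]:
                a, b = r1.per_class[c][k], r2.per_class[c][k]
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_all_correct_test_set_scores_100(self):
        ins = np.array([0] * 40 + [1] * 40 + [2] * 40)
        sem = np.array([1] * 80 + [2] * 40)
        evals = [self._eval(sem, ins, sem, ins) for _ in range(3)]
        rep = report(evals, 3, [1, 2])
        assert all(v == pytest.approx(100.0)
                   for m in rep.per_leafclass.values() for v in m.values())
        assert rep.means["IoU"] == pytest.approx(100.0)

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            report([], 3, [1])

    def test_format_table_mentions_all_measures(self, rng):
        sem = rng.integers(1, 3, 60)
        ins = rng.integers(0, 3, 60)
        sem_gt = np.array([int(1 + i % 2) for i in ins])
        rep = report([self._eval(sem, ins, sem_gt, ins)], 3, [1, 2])
        table = rep.format_table()
        for token in ("Prec", "Rec", "F1", "IoU", "mCov", "mWCov"):
            assert token in table
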