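"""Joint semantic / instance segmentation measures and test-set reports.

Semantic, per class (percent): Prec = TP/(TP+FP), Rec = TP/(TP+FN),
F1 = harmonic mean of the two, IoU = TP/(TP+FP+FN).

Instance, per semantic class (percent): mCov is the mean best-IoU coverage of
ground-truth instances, mWCov the size-weighted variant (weights are each GT
instance's point share within its class), and mPrec / mRec count a predicted
instance as a true positive when its IoU against a *distinct* GT instance of
the same class exceeds 0.5 (one-to-one greedy matching in descending IoU, so
one GT instance can never validate two predictions).

Conventions: a class absent from both prediction and ground truth is excluded
from means; ratios with an empty denominator are undefined (NaN) and likewise
excluded rather than counted as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentationReport", "semantic_confusion", "semantic_metrics",
    "instance_metrics", "evaluate_cloud", "report",
]

SEM_MEASURES = ("Prec", "Rec", "F1", "IoU")
INS_MEASURES = ("mPrec", "mRec", "mCov", "mWCov")


def semantic_confusion(sem_pred: np.ndarray, sem_gt: np.ndarray,
                       n_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (TP, FP, FN) point counts."""
    sem_pred, sem_gt = np.asarray(sem_pred), np.asarray(sem_gt)
    if sem_pred.shape != sem_gt.shape:
        raise ValueError("prediction and ground truth must have equal length")
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        p, g = sem_pred == c, sem_gt == c
        tp[c] = np.sum(p & g)
        fp[c] = np.sum(p & ~g)
        fn[c] = np.sum(~p & g)
    return tp, fp, fn


def _ratios(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> dict[int, dict[str, float]]:
    out: dict[int, dict[str, float]] = {}
    for c in range(len(tp)):
        if tp[c] + fp[c] + fn[c] == 0:
            continue  # class absent on both sides
        prec = 100.0 * tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else np.nan
        rec = 100.0 * tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else np.nan
        if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
            f1 = 0.0 if prec == 0 or rec == 0 else np.nan
        else:
            f1 = 2.0 * prec * rec / (prec + rec)
        iou = 100.0 * tp[c] / (tp[c] + fp[c] + fn[c])
        out[c] = {"Prec": prec, "Rec": rec, "F1": f1, "IoU": iou}
    return out


def semantic_metrics(sem_pred: np.ndarray, sem_gt: np.ndarray,
                     n_classes: int) -> dict[int, dict[str, float]]:
    """Per-class Prec/Rec/F1/IoU in percent."""
    return _ratios(*semantic_confusion(sem_pred, sem_gt, n_classes))


def _instance_sets(ins: np.ndarray, ins_class: dict[int, int], sem_class: int):
    """Point-index sets of the instances assigned to one semantic class."""
    ins = np.asarray(ins)
    return [np.flatnonzero(ins == i) for i, c in sorted(ins_class.items())
            if c == sem_class]


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = len(np.intersect1d(a, b, assume_unique=True))
    union = len(a) + len(b) - inter
    return inter / union if union else 0.0


def _greedy_match(iou: np.ndarray, threshold: float = 0.5) -> int:
    """One-to-one matches with IoU strictly above threshold, greedy by IoU."""
    iou = iou.copy()
    tp = 0
    while iou.size and iou.max() > threshold:
        m, n = np.unravel_index(np.argmax(iou), iou.shape)
        tp += 1
        iou[m, :] = -1.0
        iou[:, n] = -1.0
    return tp


def _instance_stats(ins_pred, ins_class_pred, ins_gt, ins_class_gt,
                    classes) -> dict[int, dict[str, float]]:
    """Raw per-class instance counts used by both metrics and aggregation."""
    stats: dict[int, dict[str, float]] = {}
    for c in classes:
        gt_sets = _instance_sets(ins_gt, ins_class_gt, c)
        pred_sets = _instance_sets(ins_pred, ins_class_pred, c)
        if not gt_sets and not pred_sets:
            continue
        iou = np.array([[_iou(g, p) for p in pred_sets] for g in gt_sets]
                       ).reshape(len(gt_sets), len(pred_sets))
        best = iou.max(axis=1) if pred_sets and gt_sets else np.zeros(len(gt_sets))
        sizes = np.array([len(g) for g in gt_sets], dtype=np.float64)
        stats[c] = {
            "n_gt": len(gt_sets),
            "n_pred": len(pred_sets),
            "tp": _greedy_match(iou) if gt_sets and pred_sets else 0,
            "sum_best_iou": float(best.sum()),
            "wcov": float((sizes / sizes.sum() * best).sum()) if gt_sets else np.nan,
        }
    return stats


def _instance_ratios(stats: dict[int, dict[str, float]]) -> dict[int, dict[str, float]]:
    out: dict[int, dict[str, float]] = {}
    for c, s in stats.items():
        if s["n_gt"] == 0:
            warnings.warn(f"class {c} has no ground-truth instances; excluded from means")
            continue
        out[c] = {
            "mPrec": 100.0 * s["tp"] / s["n_pred"] if s["n_pred"] else np.nan,
            "mRec": 100.0 * s["tp"] / s["n_gt"],
            "mCov": 100.0 * s["sum_best_iou"] / s["n_gt"],
            "mWCov": 100.0 * s["wcov"],
        }
    return out


def instance_metrics(ins_pred: np.ndarray, ins_class_pred: dict[int, int],
                     ins_gt: np.ndarray, ins_class_gt: dict[int, int],
                     classes) -> dict[int, dict[str, float]]:
    """Per-class mPrec/mRec/mCov/mWCov in percent, for the given classes."""
    return _instance_ratios(
        _instance_stats(ins_pred, ins_class_pred, ins_gt, ins_class_gt, classes))


# ---------------------------------------------------------------------------
# Test-set reports
# ---------------------------------------------------------------------------

@dataclass
class SegmentationReport:
    per_class: dict[int, dict[str, float]]        # semantic measures
    per_leafclass: dict[int, dict[str, float]]    # instance measures
    means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.means:
            self.means = {
                **{m: _nanmean([v[m] for v in self.per_class.values()])
                   for m in SEM_MEASURES},
                **{m: _nanmean([v[m] for v in self.per_leafclass.values()])
                   for m in INS_MEASURES},
            }

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "per_leafclass": self.per_leafclass,
                "means": self.means}

    def format_table(self, class_names: dict[int, str] | None = None) -> str:
        def name(c):
            return (class_names or {}).get(c, f"class {c}")

        lines = ["Semantic segmentation", "-" * 60,
                 f"{'class':<22}" + "".join(f"{m:>10}" for m in SEM_MEASURES)]
        for c, v in sorted(self.per_class.items()):
            lines.append(f"{name(c):<22}" + "".join(f"{v[m]:>10.2f}" for m in SEM_MEASURES))
        lines += ["", "Instance segmentation (leaf classes)", "-" * 60,
                  f"{'class':<22}" + "".join(f"{m:>10}" for m in INS_MEASURES)]
        for c, v in sorted(self.per_leafclass.items()):
            lines.append(f"{name(c):<22}" + "".join(f"{v[m]:>10.2f}" for m in INS_MEASURES))
        lines += ["", "Means: " + "  ".join(f"{k}={v:.2f}" for k, v in self.means.items())]
        return "\n".join(lines)


def _nanmean(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def evaluate_cloud(sem_pred, ins_pred, ins_class_pred, sem_gt, ins_gt,
                   n_classes: int, leaf_classes) -> dict:
    """Raw per-cloud tallies, ready for cross-cloud aggregation."""
    ins_gt = np.asarray(ins_gt)
    sem_gt = np.asarray(sem_gt)
    gt_class = {int(i): int(np.argmax(np.bincount(sem_gt[ins_gt == i])))
                for i in np.unique(ins_gt)}
    tp, fp, fn = semantic_confusion(sem_pred, sem_gt, n_classes)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "instances": _instance_stats(ins_pred, ins_class_pred, ins_gt,
                                     gt_class, leaf_classes),
    }


def report(cloud_evals: list[dict], n_classes: int, leaf_classes) -> SegmentationReport:
    """Aggregate per-cloud tallies into one report.

    Semantic counts are summed over clouds before taking ratios (micro).
    Instance measures are averaged over clouds weighted by each cloud's GT
    instance count in the class, so duplicating a cloud leaves the report
    unchanged.
    """
    if not cloud_evals:
        raise ValueError("cannot build a report from an empty evaluation set")
    tp = sum(e["tp"] for e in cloud_evals)
    fp = sum(e["fp"] for e in cloud_evals)
    fn = sum(e["fn"] for e in cloud_evals)

    per_leaf: dict[int, dict[str, float]] = {}
    for c in leaf_classes:
        rows = [e["instances"][c] for e in cloud_evals if c in e["instances"]]
        n_gt = sum(r["n_gt"] for r in rows)
        n_pred = sum(r["n_pred"] for r in rows)
        if n_gt == 0:
            if rows:
                warnings.warn(f"class {c} has no ground-truth instances; excluded")
            continue
        tp_i = sum(r["tp"] for r in rows)
        wcov_rows = [(r["n_gt"], r["wcov"]) for r in rows if r["n_gt"] > 0]
        per_leaf[c] = {
            "mPrec": 100.0 * tp_i / n_pred if n_pred else np.nan,
            "mRec": 100.0 * tp_i / n_gt,
            "mCov": 100.0 * sum(r["sum_best_iou"] for r in rows) / n_gt,
            "mWCov": 100.0 * sum(w * v for w, v in wcov_rows) / sum(w for w, _ in wcov_rows),
        }
    return SegmentationReport(per_class=_ratios(tp, fp, fn), per_leafclass=per_leaf)
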