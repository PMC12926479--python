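"""Detection metrics: precision, recall, AP and mAP.

Matching is greedy in descending confidence: each detection claims the
highest-IoU unmatched ground truth of its class in its image, provided the
IoU clears the threshold; every ground truth can be used once.  AP is the
area under the interpolated precision–recall curve sampled at 101 recall
points (the COCO convention); mAP@50 evaluates at IoU 0.5 and mAP@50–95
averages thresholds 0.50:0.05:0.95.  Reported P/R are taken at the
maximum-F1 point of the IoU-0.5 curve.  Classes absent from the ground
truth are excluded from the mean; with no detections precision is defined
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assign import pairwise_iou

__all__ = ["Detection", "GroundTruth", "EvalReport", "evaluate", "average_precision"]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """One predicted instance: xyxy pixel box, class id, confidence."""

    box: tuple
    cls: int
    conf: float
    image_id: int = 0

    def __post_init__(self):
        if not 0.0 <= self.conf <= 1.0:
            raise ValueError(f"confidence {self.conf} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    box: tuple
    cls: int
    image_id: int = 0


@dataclass
class EvalReport:
    precision: float
    recall: float
    ap50: dict  # class id -> AP@0.5
    map50: float
    map50_95: float
    per_class_ap: dict  # class id -> mean AP over thresholds
    confusion: dict  # {"tp": int, "fp": int, "fn": int} at IoU 0.5


def average_precision(recall: np.ndarray, precision: np.ndarray) -> float:
    """101-point interpolated area under the P–R curve."""
    if len(recall) == 0:
        return 0.0
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    # precision envelope (monotone non-increasing from the right)
    p = np.maximum.accumulate(p[::-1])[::-1]
    samples = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(r, samples, side="left")
    return float(p[np.minimum(idx, len(p) - 1)].mean())


def _match_class(dets, gts, iou_thr: float):
    """Greedy confidence-descending matching; returns tp flags (per det)."""
    tp = np.zeros(len(dets), dtype=bool)
    used: dict[int, set] = {}
    gt_by_img: dict[int, list] = {}
    for gi, g in enumerate(gts):
        gt_by_img.setdefault(g.image_id, []).append(gi)
    boxes = np.array([g.box for g in gts], dtype=np.float64).reshape(-1, 4)
    for di, det in enumerate(dets):
        cand = gt_by_img.get(det.image_id, [])
        if not cand:
            continue
        ious = pairwise_iou(np.array(det.box, dtype=np.float64).reshape(1, 4),
                            boxes[cand])[0]
        order = np.argsort(-ious, kind="stable")
        taken = used.setdefault(det.image_id, set())
        for o in order:
            gi = cand[o]
            if ious[o] >= iou_thr and gi not in taken:
                taken.add(gi)
                tp[di] = True
                break
    return tp


def evaluate(detections: list, ground_truths: list,
             iou_thresholds=IOU_THRESHOLDS, nc: int | None = None) -> EvalReport:
    """Score a detection set against ground truth."""
    gts = list(ground_truths)
    classes_gt = sorted({g.cls for g in gts})
    if nc is not None:
        bad = [d.cls for d in detections if not 0 <= d.cls < nc]
        if bad:
            raise ValueError(f"unknown class ids in detections: {sorted(set(bad))}")

    # stable global ordering: confidence desc, then insertion order
    order = np.argsort([-d.conf for d in detections], kind="stable")
    dets_sorted = [detections[i] for i in order]

    ap_per_thr: dict[int, list] = {c: [] for c in classes_gt}
    ap50: dict[int, float] = {}
    pr_counts = {"tp": 0, "fp": 0, "fn": 0}
    p50s: list[float] = []
    r50s: list[float] = []

    for thr in iou_thresholds:
        for c in classes_gt:
            dets_c = [d for d in dets_sorted if d.cls == c]
            gts_c = [g for g in gts if g.cls == c]
            tp = _match_class(dets_c, gts_c, thr)
            n_gt = len(gts_c)
            tps = np.cumsum(tp)
            fps = np.cumsum(~tp)
            rec = tps / n_gt
            prec = tps / np.maximum(tps + fps, 1)
            ap = average_precision(rec, prec)
            ap_per_thr[c].append(ap)
            if np.isclose(thr, 0.5):
                ap50[c] = ap
                pr_counts["tp"] += int(tp.sum())
                pr_counts["fp"] += int((~tp).sum())
                pr_counts["fn"] += n_gt - int(tp.sum())
                if len(rec):
                    f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
                    i = int(np.argmax(f1))
                    p50s.append(float(prec[i]))
                    r50s.append(float(rec[i]))
                else:  # no detections for this class: P = 0 by convention
                    p50s.append(0.0)
                    r50s.append(0.0)

    if classes_gt:
        map50 = float(np.mean([ap50[c] for c in classes_gt]))
        per_class = {c: float(np.mean(ap_per_thr[c])) for c in classes_gt}
        map5095 = float(np.mean(list(per_class.values())))
    else:
        map50 = map5095 = 0.0
        per_class = {}
    return EvalReport(
        precision=float(np.mean(p50s)) if p50s else 0.0,
        recall=float(np.mean(r50s)) if r50s else 0.0,
        ap50=ap50,
        map50=map50,
        map50_95=map5095,
        per_class_ap=per_class,
        confusion=pr_counts,
    )
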