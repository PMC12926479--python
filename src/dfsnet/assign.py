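"""Task-aligned target assignment.

Each ground-truth box is matched to the top-k anchor candidates whose
centres lie inside it, ranked by the alignment score
``s = p_cls^alpha * IoU^beta`` (classification probability of the gt class
times localisation quality).  Anchors claimed by several ground truths
keep the one with the highest IoU.  Target classification scores are the
alignment values rescaled per ground truth so their maximum equals that
gt's best IoU — the quality-weighted soft targets the classification
branch regresses to.  Everything is deterministic: ties are resolved by
stable sort order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AssignResult", "pairwise_iou", "assign_targets"]


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) xyxy boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = (br - tl).clip(min=0.0)
    inter = wh[..., 0] * wh[..., 1]
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    return inter / (area_a + area_b - inter + 1e-12)


@dataclass
class AssignResult:
    fg_mask: np.ndarray  # (N,) bool — anchor is matched
    gt_index: np.ndarray  # (N,) int — matched gt row (-1 on background)
    target_scores: np.ndarray  # (N, nc) soft classification targets
    target_boxes: np.ndarray  # (N, 4) matched gt boxes (zeros on background)


def assign_targets(cls_probs: np.ndarray, pred_boxes: np.ndarray,
                   anchor_centers: np.ndarray, gt_boxes: np.ndarray,
                   gt_classes: np.ndarray, nc: int, topk: int = 10,
                   alpha: float = 0.5, beta: float = 6.0) -> AssignResult:
    """Match anchors to ground truths by task alignment.

    cls_probs:      (N, nc) sigmoid classification probabilities.
    pred_boxes:     (N, 4) decoded boxes, image pixels.
    anchor_centers: (N, 2) anchor centre coordinates, image pixels.
    gt_boxes:       (M, 4) xyxy; gt_classes: (M,).
    """
    n = cls_probs.shape[0]
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    gt_classes = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
    m = len(gt_boxes)
    out = AssignResult(
        fg_mask=np.zeros(n, dtype=bool),
        gt_index=np.full(n, -1, dtype=np.int64),
        target_scores=np.zeros((n, nc), dtype=np.float64),
        target_boxes=np.zeros((n, 4), dtype=np.float64),
    )
    if m == 0:
        return out

    cx = anchor_centers[:, 0][:, None]
    cy = anchor_centers[:, 1][:, None]
    inside = (
        (cx > gt_boxes[None, :, 0]) & (cx < gt_boxes[None, :, 2])
        & (cy > gt_boxes[None, :, 1]) & (cy < gt_boxes[None, :, 3])
    )  # (N, M)

    iou = pairwise_iou(pred_boxes, gt_boxes)  # (N, M)
    score = cls_probs[:, gt_classes]  # (N, M)
    align = (score**alpha) * (iou**beta)
    align = np.where(inside, align, 0.0)

    # top-k per gt among inside candidates (stable ordering for ties)
    mask = np.zeros_like(align, dtype=bool)
    for j in range(m):
        col = align[:, j]
        cand = np.nonzero(inside[:, j])[0]
        if len(cand) == 0:
            continue
        order = cand[np.argsort(-col[cand], kind="stable")][:topk]
        order = order[col[order] > 0]
        mask[order, j] = True

    # resolve anchors matched to several gts: keep the highest-IoU gt
    multi = mask.sum(axis=1) > 1
    if multi.any():
        best = iou.argmax(axis=1)
        keep = np.zeros_like(mask)
        keep[np.arange(n), best] = True
        mask[multi] = mask[multi] & keep[multi]

    fg = mask.any(axis=1)
    gt_idx = mask.argmax(axis=1)
    out.fg_mask = fg
    out.gt_index = np.where(fg, gt_idx, -1)
    out.target_boxes[fg] = gt_boxes[gt_idx[fg]]

    # per-gt normalisation: max alignment -> max IoU of that gt's matches
    align_m = np.where(mask, align, 0.0)
    iou_m = np.where(mask, iou, 0.0)
    amax = align_m.max(axis=0)  # (M,)
    imax = iou_m.max(axis=0)
    norm = np.where(amax > 0, imax / (amax + 1e-12), 0.0)
    scores = align_m * norm[None, :]
    rows = np.nonzero(fg)[0]
    out.target_scores[rows, gt_classes[gt_idx[rows]]] = scores[rows, gt_idx[rows]]
    return out
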