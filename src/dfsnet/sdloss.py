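"""Scale-based Dynamic Loss (SDLoss).

IoU-style regression losses fluctuate strongly on small objects: a borer
hole a few pixels across can see its IoU collapse under a one-pixel shift,
while elongated thrips stripes are hypersensitive to centre offsets.  The
scale-based dynamic loss re-balances the two ingredients of box
supervision — a scale-consistency term L_BS = 1 − IoU + γ and a
centre-localisation term L_BL = d²(centres)/L² (L the diagonal of the
tightest rectangle enclosing both boxes) — with weights that shift with
ground-truth scale:

    L_SDB = β1·L_BS + β2·L_BL,
    β1 = 1 − δ + β3,   β2 = 1 + δ − β3,   β1 + β2 = 2,
    β3 = min(area(B_gt) / maxB_gt · θ · δ, δ),

δ = 0.5 caps the adjustment, maxB_gt = 81 px² is the 9×9 small-target
area bound borrowed from infrared small-target detection, and θ maps
between image and feature-map scale (θ = size_image / size_feature, i.e.
the stride of the pyramid level).  Small ground truths drive β3 → 0, so
β2 → 1.5: the centre term dominates and the model "pays attention" to
small targets whose IoU signal is unreliable.

A mirrored mask branch L_SDM = β1′·L_MS + β2′·L_ML (β1′ = 1 + δ − β3,
β2′ = 1 − δ + β3) scores mask overlap (L_MS = 1 − p·MIoU) and polar shape
statistics: mean radius ratio and squared circular-mean-angle gap,
L_ML = 1 − min(d̄)/max(d̄) + 4·Δθ̄²/π².

Scalar reference implementations operate on plain boxes/pixel sets; the
``*_batch`` variants run inside the autograd graph for training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "Box",
    "SDParams",
    "box_iou",
    "bbox_scale_loss",
    "bbox_loc_loss",
    "scale_factor",
    "dynamic_weights",
    "sdb_loss",
    "mask_iou",
    "mask_scale_loss",
    "polar_stats",
    "sdm_loss",
    "bce_with_logits",
    "sdb_loss_batch",
    "total_loss",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates, origin top-left."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass
class SDParams:
    """Knobs of the scale-based dynamic loss.

    delta:    upper limit of the scale adjustment (0 < delta <= 0.5).
    max_bgt:  small-target area cap in px² (9×9 by default).
    gamma:    offset added to the scale term L_BS.
    p:        mask-IoU weight in L_MS, in (0, 1].
    theta:    image-size / feature-size scale factor of the current level
              (equals the stride; per-level values come from the head).
    lam:      weight of the regression term in the total objective.
    invert_theta: use 1/theta instead (feature/image orientation).
    """

    delta: float = 0.5
    max_bgt: float = 81.0
    gamma: float = 0.0
    p: float = 1.0
    theta: float = 1.0
    lam: float = 7.5
    invert_theta: bool = False

    def __post_init__(self):
        if not 0.0 < self.delta <= 0.5:
            raise ValueError(f"delta must lie in (0, 0.5], got {self.delta}")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")

    def effective_theta(self, theta: float | None = None) -> float:
        th = self.theta if theta is None else theta
        return 1.0 / th if self.invert_theta else th


# -- bounding-box branch ------------------------------------------------------

def box_iou(bp: Box, bgt: Box) -> float:
    """Intersection over union of two boxes; symmetric, 1 iff identical."""
    ix = max(0.0, min(bp.x2, bgt.x2) - max(bp.x1, bgt.x1))
    iy = max(0.0, min(bp.y2, bgt.y2) - max(bp.y1, bgt.y1))
    inter = ix * iy
    union = bp.area + bgt.area - inter
    return inter / union


def bbox_scale_loss(bp: Box, bgt: Box, gamma: float = 0.0) -> float:
    """L_BS = 1 − IoU + γ, in [γ, 1 + γ]."""
    return 1.0 - box_iou(bp, bgt) + gamma


def bbox_loc_loss(bp: Box, bgt: Box) -> float:
    """L_BL: squared centre distance over squared enclosing-box diagonal."""
    (cxp, cyp), (cxg, cyg) = bp.center, bgt.center
    d2 = (cxp - cxg) ** 2 + (cyp - cyg) ** 2
    ex1, ey1 = min(bp.x1, bgt.x1), min(bp.y1, bgt.y1)
    ex2, ey2 = max(bp.x2, bgt.x2), max(bp.y2, bgt.y2)
    diag2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    return d2 / diag2


def scale_factor(bgt: Box | float, s: SDParams, theta: float | None = None) -> float:
    """β3 = min(area(B_gt)/maxB_gt · θ · δ, δ) — the scale influence factor."""
    area = bgt.area if isinstance(bgt, Box) else float(bgt)
    th = s.effective_theta(theta)
    return min(area / s.max_bgt * th * s.delta, s.delta)


def dynamic_weights(beta3: float, delta: float = 0.5) -> tuple[float, float]:
    """(β1, β2) = (1 − δ + β3, 1 + δ − β3); β1 + β2 = 2 identically."""
    if not 0.0 < beta3 <= delta:
        raise ValueError(f"beta3 must lie in (0, {delta}], got {beta3}")
    return 1.0 - delta + beta3, 1.0 + delta - beta3


def sdb_loss(bp: Box, bgt: Box, s: SDParams, theta: float | None = None) -> float:
    """Scale-based dynamic box loss L_SDB = β1·L_BS + β2·L_BL."""
    beta3 = scale_factor(bgt, s, theta)
    b1, b2 = dynamic_weights(beta3, s.delta)
    return b1 * bbox_scale_loss(bp, bgt, s.gamma) + b2 * bbox_loc_loss(bp, bgt)


# -- mask branch --------------------------------------------------------------

def mask_iou(mp: set, mgt: set) -> float:
    """Set IoU of two pixel sets."""
    mp, mgt = set(mp), set(mgt)
    if not mp and not mgt:
        raise ValueError("both masks are empty")
    return len(mp & mgt) / len(mp | mgt)


def mask_scale_loss(miou: float, p: float = 1.0) -> float:
    """L_MS = 1 − p·MIoU."""
    if not 0.0 <= miou <= 1.0:
        raise ValueError(f"mask IoU must lie in [0, 1], got {miou}")
    return 1.0 - p * miou


def polar_stats(m: set, pole: tuple[float, float]) -> tuple[float, float]:
    """Mean radius and circular-mean angle of mask pixels about ``pole``.

    The circular mean is atan2 of the averaged unit vectors; when the
    resultant vanishes (perfect symmetry, or a single pixel at the pole)
    the angle is 0 by convention.
    """
    if not m:
        raise ValueError("empty mask")
    px, py = pole
    pts = np.asarray(sorted(m), dtype=np.float64)
    dx = pts[:, 0] - px
    dy = pts[:, 1] - py
    r = np.hypot(dx, dy)
    rbar = float(r.mean())
    nz = r > 1e-12
    if not nz.any():
        return rbar, 0.0
    ux = (dx[nz] / r[nz]).mean()
    uy = (dy[nz] / r[nz]).mean()
    if math.hypot(ux, uy) < 1e-9:
        return rbar, 0.0
    return rbar, math.atan2(uy, ux)


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def sdm_loss(mp: set, mgt: set, s: SDParams, pole: tuple[float, float] | None = None,
             theta: float | None = None) -> float:
    """Scale-based dynamic mask loss L_SDM = β1′·L_MS + β2′·L_ML.

    The pole defaults to the centre of the ground-truth mask's bounding
    box, making the polar terms translation-insensitive shape statistics.
    β3 is computed from the ground-truth pixel count as the area proxy;
    the mask weights mirror the box ones: β1′ = 1 + δ − β3 ∈ [1.0, 1.5),
    β2′ = 1 − δ + β3 ∈ (0.5, 1.0].
    """
    mp, mgt = set(mp), set(mgt)
    if not mp or not mgt:
        raise ValueError("masks must be non-empty")
    if pole is None:
        pts = np.asarray(sorted(mgt), dtype=np.float64)
        pole = (
            0.5 * (pts[:, 0].min() + pts[:, 0].max()),
            0.5 * (pts[:, 1].min() + pts[:, 1].max()),
        )
    l_ms = mask_scale_loss(mask_iou(mp, mgt), s.p)
    dbar_p, ang_p = polar_stats(mp, pole)
    dbar_g, ang_g = polar_stats(mgt, pole)
    hi = max(dbar_p, dbar_g)
    ratio = 1.0 if hi < 1e-12 else min(dbar_p, dbar_g) / hi
    dang = _wrap_angle(ang_p - ang_g)
    l_ml = 1.0 - ratio + 4.0 * dang * dang / math.pi**2
    beta3 = scale_factor(float(len(mgt)), s, theta)
    b1m = 1.0 + s.delta - beta3
    b2m = 1.0 - s.delta + beta3
    return b1m * l_ms + b2m * l_ml


# -- batched / differentiable forms ------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits: softplus(x) − x·y."""
    return logits.softplus() - logits * Tensor(targets.astype(logits.dtype))


def _pairwise_iou_t(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Rowwise IoU of (N,4) predicted boxes (autograd) vs matching gt rows."""
    gx1, gy1, gx2, gy2 = (Tensor(gt[:, i].astype(pred.dtype)) for i in range(4))
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    iw = nn.minimum(px2, gx2) - nn.maximum(px1, gx1)
    ih = nn.minimum(py2, gy2) - nn.maximum(py1, gy1)
    iw = iw.relu()
    ih = ih.relu()
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    return inter / (area_p + area_g - inter + 1e-9)


def sdb_loss_batch(pred: Tensor, gt: np.ndarray, s: SDParams,
                   theta: np.ndarray | float = 1.0) -> Tensor:
    """Vectorised L_SDB over matched (pred, gt) box rows, inside autograd.

    ``theta`` may be a per-row array (the stride of the level each match
    came from).  Returns a length-N tensor of losses.
    """
    gt = np.asarray(gt, dtype=np.float64 if pred.dtype == np.float64 else np.float32)
    iou = _pairwise_iou_t(pred, gt)
    l_bs = 1.0 - iou + s.gamma

    pcx = (pred[:, 0] + pred[:, 2]) * 0.5
    pcy = (pred[:, 1] + pred[:, 3]) * 0.5
    gcx = Tensor((gt[:, 0] + gt[:, 2]) * 0.5)
    gcy = Tensor((gt[:, 1] + gt[:, 3]) * 0.5)
    d2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ex1 = nn.minimum(pred[:, 0], Tensor(gt[:, 0]))
    ey1 = nn.minimum(pred[:, 1], Tensor(gt[:, 1]))
    ex2 = nn.maximum(pred[:, 2], Tensor(gt[:, 2]))
    ey2 = nn.maximum(pred[:, 3], Tensor(gt[:, 3]))
    diag2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    l_bl = d2 / (diag2 + 1e-9)

    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    th = np.asarray(theta, dtype=np.float64)
    if s.invert_theta:
        th = 1.0 / th
    beta3 = np.minimum(area_g / s.max_bgt * th * s.delta, s.delta)
    b1 = 1.0 - s.delta + beta3
    b2 = 1.0 + s.delta - beta3
    return l_bs * Tensor(b1) + l_bl * Tensor(b2)


def total_loss(pred_cls: Tensor, pred_boxes: Tensor, target_scores: np.ndarray,
               target_boxes: np.ndarray, fg_mask: np.ndarray, s: SDParams,
               theta: np.ndarray | float = 1.0,
               mask_pairs: list[tuple[set, set]] | None = None) -> dict:
    """Detection objective: classification BCE + λ·scale-dynamic regression.

    pred_cls:      (N, nc) logits over all anchors.
    pred_boxes:    (N, 4) decoded boxes in image pixels.
    target_scores: (N, nc) soft classification targets from the assigner
                   (zeros on background rows) — the quality-weighted
                   objectness/classification term of the objective.
    fg_mask:       (N,) bool, rows matched to a ground truth.
    theta:         per-foreground-row scale factor (stride).
    mask_pairs:    optional matched (predicted, gt) pixel sets for L_SDM.

    Returns a dict with ``loss`` (scalar Tensor) and float components.
    """
    norm = max(float(target_scores.sum()), 1.0)
    cls_loss = bce_with_logits(pred_cls, target_scores).sum() / norm

    if fg_mask.any():
        weights = target_scores[fg_mask].sum(axis=1) / norm
        per_box = sdb_loss_batch(pred_boxes[np.nonzero(fg_mask)[0]],
                                 target_boxes[fg_mask], s, theta=theta)
        reg_loss = (per_box * Tensor(weights.astype(per_box.dtype))).sum()
    else:
        reg_loss = Tensor(np.zeros(()))

    loss = cls_loss + s.lam * reg_loss
    out = {
        "cls": float(cls_loss.data),
        "reg": float(reg_loss.data),
        "mask": 0.0,
    }
    if mask_pairs:
        msum = sum(sdm_loss(mp, mg, s) for mp, mg in mask_pairs) / len(mask_pairs)
        out["mask"] = float(msum)
        loss = loss + msum
    out["loss"] = loss
    return out
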