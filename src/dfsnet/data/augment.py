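"""Letterboxing and label-consistent augmentation.

Augmentations mirror the usual detection-training recipe: random
translation, horizontal/vertical flips, non-uniform (per-axis) scaling,
brightness adjustment, Gaussian noise injection, and 4-tile mosaic
composition.  Every geometric change is applied identically to pixels and
boxes; boxes are clipped to the frame and dropped once their visible area
falls under ``min_box_area`` px².  All randomness flows through a caller
supplied ``numpy.random.Generator``, so a seed fixes the output bit-forbit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .yolo import LabeledImage, boxes_cxcywh_to_xyxy, boxes_xyxy_to_cxcywh

__all__ = ["LetterboxTransform", "letterbox", "AugmentConfig", "augment", "mosaic"]


@dataclass(frozen=True)
class LetterboxTransform:
    """Invertible mapping from original to letterboxed pixel coordinates."""

    scale: float
    pad_x: float
    pad_y: float
    orig_size: tuple[int, int]  # (h, w)
    target: int

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) * self.scale + np.array([self.pad_x, self.pad_y])

    def invert_points(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=np.float64) - np.array([self.pad_x, self.pad_y])) / self.scale

    def apply_boxes(self, boxes_xyxy: np.ndarray) -> np.ndarray:
        b = np.asarray(boxes_xyxy, dtype=np.float64).reshape(-1, 4)
        out = b * self.scale
        out[:, [0, 2]] += self.pad_x
        out[:, [1, 3]] += self.pad_y
        return out

    def invert_boxes(self, boxes_xyxy: np.ndarray) -> np.ndarray:
        b = np.asarray(boxes_xyxy, dtype=np.float64).reshape(-1, 4).copy()
        b[:, [0, 2]] -= self.pad_x
        b[:, [1, 3]] -= self.pad_y
        return b / self.scale


def letterbox(image: np.ndarray, target: int = 640,
              fill: int = 114) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize plus symmetric padding to target×target."""
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    scale = target / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    out = np.full((target, target, image.shape[2]), fill, dtype=image.dtype)
    py, px = (target - nh) // 2, (target - nw) // 2
    out[py : py + nh, px : px + nw] = resized
    return out, LetterboxTransform(scale, float(px), float(py), (h, w), target)


@dataclass
class AugmentConfig:
    """Probabilities/ranges of the augmentation pipeline (identity when all zero)."""

    translate: float = 0.1  # max |shift| as a fraction of the side
    flip_h: float = 0.5
    flip_v: float = 0.1
    scale: float = 0.2  # per-axis factor drawn from [1-s, 1+s] (non-uniform)
    brightness: float = 0.2  # multiplicative range
    noise_std: float = 5.0  # Gaussian noise sigma, 8-bit units
    min_box_area: float = 4.0  # px², post-transform survival threshold

    def is_identity(self) -> bool:
        return not any([self.translate, self.flip_h, self.flip_v, self.scale,
                        self.brightness, self.noise_std])


def _affine_image(img: np.ndarray, sx: float, sy: float, tx: float, ty: float,
                  flip_h: bool, flip_v: bool, fill: int = 114) -> np.ndarray:
    """Apply x' = sx·x(+flip) + tx via PIL's inverse-map affine (bilinear)."""
    h, w = img.shape[:2]
    # forward: x' = sx * ((w - x) if flip_h else x) + tx ; same for y.
    # PIL wants the inverse map coefficients (a,b,c,d,e,f): x = a x' + b y' + c
    if flip_h:
        a, c = -1.0 / sx, w + tx / sx
    else:
        a, c = 1.0 / sx, -tx / sx
    if flip_v:
        e, f = -1.0 / sy, h + ty / sy
    else:
        e, f = 1.0 / sy, -ty / sy
    pil = Image.fromarray(img)
    out = pil.transform((w, h), Image.AFFINE, (a, 0.0, c, 0.0, e, f),
                        resample=Image.BILINEAR, fillcolor=(fill,) * 3)
    return np.asarray(out)


def augment(item: LabeledImage, cfg: AugmentConfig, rng: np.random.Generator) -> LabeledImage:
    """Photometric + geometric augmentation with consistent labels."""
    if cfg.is_identity():
        return item
    h, w = item.size
    img = item.image

    sx = 1.0 + (rng.uniform(-cfg.scale, cfg.scale) if cfg.scale else 0.0)
    sy = 1.0 + (rng.uniform(-cfg.scale, cfg.scale) if cfg.scale else 0.0)
    tx = rng.uniform(-cfg.translate, cfg.translate) * w if cfg.translate else 0.0
    ty = rng.uniform(-cfg.translate, cfg.translate) * h if cfg.translate else 0.0
    fh = rng.random() < cfg.flip_h
    fv = rng.random() < cfg.flip_v

    img = _affine_image(img, sx, sy, tx, ty, fh, fv)

    boxes = boxes_cxcywh_to_xyxy(item.boxes, w, h)
    xs = boxes[:, [0, 2]]
    ys = boxes[:, [1, 3]]
    if fh:
        xs = ((w - xs) * sx + tx)[:, ::-1]
    else:
        xs = xs * sx + tx
    if fv:
        ys = ((h - ys) * sy + ty)[:, ::-1]
    else:
        ys = ys * sy + ty
    boxes = np.stack([xs[:, 0], ys[:, 0], xs[:, 1], ys[:, 1]], axis=1)
    boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, w)
    boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, h)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    keep = areas >= cfg.min_box_area
    boxes, classes = boxes[keep], item.classes[keep]

    out = img.astype(np.float32)
    if cfg.brightness:
        out = out * (1.0 + rng.uniform(-cfg.brightness, cfg.brightness))
    if cfg.noise_std:
        out = out + rng.normal(0.0, cfg.noise_std, size=out.shape)
    out = out.clip(0, 255).astype(np.uint8)

    return LabeledImage(out, boxes_xyxy_to_cxcywh(boxes, w, h), classes)


def mosaic(items: list[LabeledImage], size: int,
           rng: np.random.Generator) -> tuple[LabeledImage, list[int]]:
    """Compose four labelled images into one size×size canvas.

    Tiles are letterboxed to size/2 and placed in quadrant order
    (top-left, top-right, bottom-left, bottom-right) after a seeded
    shuffle.  Returns the mosaic and the tile order (indices into
    ``items``) for provenance.
    """
    if len(items) != 4:
        raise ValueError("mosaic needs exactly 4 items")
    half = size // 2
    order = rng.permutation(4).tolist()
    canvas = np.full((size, size, 3), 114, dtype=np.uint8)
    all_boxes, all_classes = [], []
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]  # (y, x) per quadrant
    for quad, idx in enumerate(order):
        item = items[idx]
        tile, tf = letterbox(item.image, half)
        oy, ox = offsets[quad]
        canvas[oy : oy + half, ox : ox + half] = tile
        if len(item.boxes):
            h, w = item.size
            b = tf.apply_boxes(boxes_cxcywh_to_xyxy(item.boxes, w, h))
            b[:, [0, 2]] += ox
            b[:, [1, 3]] += oy
            all_boxes.append(b)
            all_classes.append(item.classes)
    if all_boxes:
        boxes = np.concatenate(all_boxes)
        classes = np.concatenate(all_classes)
        boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, size)
        boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, size)
        keep = ((boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])) >= 4.0
        boxes, classes = boxes[keep], classes[keep]
    else:
        boxes = np.zeros((0, 4))
        classes = np.zeros(0, dtype=np.int64)
    out = LabeledImage(canvas, boxes_xyxy_to_cxcywh(boxes, size, size), classes)
    return out, order
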