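"""Synthetic eggplant-fruit lesion scenes.

The study's field imagery is not redistributable, so this generator is the
canonical test input for the whole pipeline.  Each scene is a textured
greenhouse-green background with one or two glossy dark-purple fruit
ellipses, onto which the three lesion classes are rendered with their
characteristic geometry:

* **FruitBorer** — small near-circular dark cavities (4–14 px diameter by
  default, i.e. mostly under the 81 px² small-target cap, so they exercise
  the β3 regime of the scale-dynamic loss);
* **FruitRot**   — irregular mid-size brown blobs (randomised star-polygon
  radii, 15–60 px);
* **MelonThrips** — elongated near-vertical pale feeding stripes
  (30–120 px long, stripe aspect ≥ 4, drawn with a slight wiggle);
* **Healthy**    — an unlesioned fruit contributes one box covering the
  fruit itself.

Each lesion is clipped to its fruit's pixel mask, so every lesion box
centre lies inside the fruit ellipse.  One tight box is emitted per
lesion.  All randomness comes from the supplied generator: the same seed
reproduces the scene byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw as skdraw

from .split import split_dataset
from .yolo import (
    CLASS_NAMES,
    LabeledImage,
    boxes_xyxy_to_cxcywh,
    save_image,
    write_manifest,
    write_yolo_labels,
)

__all__ = ["SceneSpec", "synth_scene", "make_dataset", "easy_spec"]

FRUIT_BORER, FRUIT_ROT, MELON_THRIPS, HEALTHY = 0, 1, 2, 3


@dataclass
class SceneSpec:
    """Geometry and intensity ranges of one synthetic scene."""

    size: int = 640
    fruit_count: tuple[int, int] = (1, 2)
    fruit_axes: tuple[tuple[int, int], tuple[int, int]] = ((140, 240), (90, 170))
    borer_count: tuple[int, int] = (1, 3)
    rot_count: tuple[int, int] = (0, 2)
    thrips_count: tuple[int, int] = (0, 2)
    borer_diameter: tuple[float, float] = (4.0, 14.0)
    rot_size: tuple[float, float] = (15.0, 60.0)
    thrips_length: tuple[float, float] = (30.0, 120.0)
    thrips_aspect: tuple[float, float] = (6.0, 10.0)
    healthy_prob: float = 0.25  # chance a fruit stays lesion-free
    noise_std: float = 6.0
    emit_masks: bool = False

    def __post_init__(self):
        for name in ("borer_diameter", "rot_size", "thrips_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")
        if self.thrips_aspect[0] < 4.0:
            raise ValueError("thrips stripes must keep aspect >= 4")
        if self.thrips_length[1] > self.fruit_axes[0][0]:
            raise ValueError("thrips_length upper bound exceeds the smallest fruit height")
        if self.rot_size[1] > min(self.fruit_axes[0][0], self.fruit_axes[1][0]):
            raise ValueError("rot_size upper bound exceeds the smallest fruit axis")


def easy_spec(size: int = 128) -> SceneSpec:
    """Large, well-separated lesions on a small canvas — the smoke-training
    regime (one fruit filling most of the frame, one or two big lesions)."""
    return SceneSpec(
        size=size,
        fruit_count=(1, 1),
        fruit_axes=((int(size * 0.74), int(size * 0.88)), (int(size * 0.52), int(size * 0.64))),
        borer_count=(0, 1),
        rot_count=(0, 1),
        thrips_count=(0, 1),
        borer_diameter=(size * 0.10, size * 0.16),
        rot_size=(size * 0.22, size * 0.34),
        thrips_length=(size * 0.40, size * 0.60),
        thrips_aspect=(6.0, 8.0),
        noise_std=4.0,
    )


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([86.0, 118.0, 70.0])
    img = np.empty((size, size, 3), dtype=np.float32)
    low = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 8.0)
    low = low / (np.abs(low).max() + 1e-9)
    grad = np.linspace(-1.0, 1.0, size)[:, None]
    for ch in range(3):
        img[..., ch] = base[ch] * (1.0 + 0.18 * low + 0.08 * grad)
    # leaf-like soft blotches
    for _ in range(6):
        cy, cx = rng.integers(0, size, 2)
        ry, rx = rng.integers(size // 16, size // 5, 2)
        rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(size, size))
        img[rr, cc] *= rng.uniform(0.85, 1.12)
    return img


def _fruit_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                angle: float) -> np.ndarray:
    rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(size, size), rotation=angle)
    m = np.zeros((size, size), dtype=bool)
    m[rr, cc] = True
    return m


def _paint_fruit(img: np.ndarray, mask: np.ndarray, cy: float, cx: float,
                 ry: float, rx: float, rng: np.random.Generator) -> None:
    size = img.shape[0]
    yy, xx = np.nonzero(mask)
    # radial shading toward the rim + a specular highlight streak
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    shade = 1.05 - 0.45 * r2
    color = np.array([52.0, 24.0, 66.0]) * rng.uniform(0.9, 1.1)
    img[yy, xx] = color[None, :] * shade[:, None]
    hy, hx = cy - 0.35 * ry, cx - 0.25 * rx
    rr, cc = skdraw.ellipse(hy, hx, max(2.0, ry * 0.18), max(2.0, rx * 0.10),
                            shape=(size, size), rotation=rng.uniform(-0.5, 0.5))
    keep = mask[rr, cc]
    img[rr[keep], cc[keep]] = img[rr[keep], cc[keep]] * 0.4 + np.array([235.0, 225.0, 240.0]) * 0.6


def _lesion_center(fruit: dict, margin: float, rng: np.random.Generator) -> tuple[float, float]:
    """A point well inside the fruit ellipse (margin in [0,1) of the radius)."""
    t = rng.uniform(0, 2 * np.pi)
    u = np.sqrt(rng.uniform(0, 1)) * (1.0 - margin)
    dy = u * fruit["ry"] * np.sin(t)
    dx = u * fruit["rx"] * np.cos(t)
    ca, sa = np.cos(fruit["angle"]), np.sin(fruit["angle"])
    return fruit["cy"] + dy * ca - dx * sa, fruit["cx"] + dy * sa + dx * ca


def _draw_borer(img, fruit, spec: SceneSpec, rng) -> np.ndarray | None:
    size = img.shape[0]
    d = rng.uniform(*spec.borer_diameter)
    cy, cx = _lesion_center(fruit, 0.25, rng)
    rr, cc = skdraw.disk((cy, cx), max(d / 2.0, 1.0), shape=(size, size))
    keep = fruit["mask"][rr, cc]
    rr, cc = rr[keep], cc[keep]
    if len(rr) == 0:
        return None
    m = np.zeros((size, size), dtype=bool)
    m[rr, cc] = True
    img[rr, cc] = np.array([24.0, 12.0, 16.0]) * rng.uniform(0.8, 1.2)
    # darker rim
    rr2, cc2 = skdraw.circle_perimeter(int(round(cy)), int(round(cx)),
                                       max(int(round(d / 2.0)), 1), shape=(size, size))
    keep2 = fruit["mask"][rr2, cc2]
    img[rr2[keep2], cc2[keep2]] = np.array([12.0, 6.0, 8.0])
    return m


def _draw_rot(img, fruit, spec: SceneSpec, rng) -> np.ndarray | None:
    size = img.shape[0]
    s = rng.uniform(*spec.rot_size)
    cy, cx = _lesion_center(fruit, 0.3, rng)
    nang = 12
    ang = np.linspace(0, 2 * np.pi, nang, endpoint=False)
    radii = (s / 2.0) * (1.0 + 0.45 * rng.uniform(-1, 1, nang))
    radii = np.maximum(radii, 2.0)
    ys = cy + radii * np.sin(ang)
    xs = cx + radii * np.cos(ang)
    rr, cc = skdraw.polygon(ys, xs, shape=(size, size))
    keep = fruit["mask"][rr, cc]
    rr, cc = rr[keep], cc[keep]
    if len(rr) == 0:
        return None
    m = np.zeros((size, size), dtype=bool)
    m[rr, cc] = True
    mottle = rng.uniform(0.7, 1.15, size=len(rr))
    img[rr, cc] = np.array([96.0, 62.0, 30.0])[None, :] * mottle[:, None]
    return m


def _draw_thrips(img, fruit, spec: SceneSpec, rng) -> np.ndarray | None:
    # retry until the clipped stripe's box keeps the elongated aspect
    size = img.shape[0]
    for attempt in range(6):
        length = rng.uniform(*spec.thrips_length) * (0.9**attempt)
        aspect = rng.uniform(*spec.thrips_aspect)
        width = max(length / aspect, 1.5)
        cy, cx = _lesion_center(fruit, 0.35, rng)
        y0 = cy - length / 2.0
        ys = np.arange(int(round(y0)), int(round(y0 + length)))
        phase = rng.uniform(0, 2 * np.pi)
        amp = width / 4.0
        xs = cx + amp * np.sin(2 * np.pi * (ys - ys[0]) / max(length, 1.0) + phase)
        m = np.zeros((size, size), dtype=bool)
        half = width / 2.0
        for y, x in zip(ys, xs):
            if not 0 <= y < size:
                continue
            x1 = int(np.floor(x - half))
            x2 = int(np.ceil(x + half))
            m[y, max(x1, 0) : min(x2 + 1, size)] = True
        m &= fruit["mask"]
        rr, cc = np.nonzero(m)
        if len(rr) == 0:
            continue
        x1b, y1b, x2b, y2b = _tight_box(m)
        if (y2b - y1b) / max(x2b - x1b, 1.0) < 4.0:
            continue
        tone = rng.uniform(0.85, 1.1, size=len(rr))
        img[rr, cc] = np.array([178.0, 148.0, 96.0])[None, :] * tone[:, None]
        return m
    return None


def _tight_box(mask: np.ndarray) -> np.ndarray:
    yy, xx = np.nonzero(mask)
    return np.array([xx.min(), yy.min(), xx.max() + 1, yy.max() + 1], dtype=np.float64)


def synth_scene(spec: SceneSpec, rng: np.random.Generator) -> LabeledImage:
    """Render one scene; returns the image plus one box per lesion (or one
    Healthy box per unlesioned fruit)."""
    size = spec.size
    img = _background(size, rng)

    n_fruit = int(rng.integers(spec.fruit_count[0], spec.fruit_count[1] + 1))
    fruits = []
    for _ in range(n_fruit):
        ry = rng.uniform(*spec.fruit_axes[0]) / 2.0
        rx = rng.uniform(*spec.fruit_axes[1]) / 2.0
        cy = rng.uniform(ry * 0.8, size - ry * 0.8)
        cx = rng.uniform(rx * 0.8, size - rx * 0.8)
        angle = rng.uniform(-0.4, 0.4)
        mask = _fruit_mask(size, cy, cx, ry, rx, angle)
        if not mask.any():
            continue
        _paint_fruit(img, mask, cy, cx, ry, rx, rng)
        fruits.append({"cy": cy, "cx": cx, "ry": ry, "rx": rx, "angle": angle, "mask": mask})

    boxes, classes, masksets = [], [], []
    drawers = (
        (FRUIT_BORER, spec.borer_count, _draw_borer),
        (FRUIT_ROT, spec.rot_count, _draw_rot),
        (MELON_THRIPS, spec.thrips_count, _draw_thrips),
    )
    for fruit in fruits:
        n_lesions = 0
        keep_healthy = rng.random() < spec.healthy_prob
        for cid, count_range, drawer in drawers:
            if keep_healthy:
                break
            n = int(rng.integers(count_range[0], count_range[1] + 1))
            for _ in range(n):
                m = drawer(img, fruit, spec, rng)
                if m is None:
                    continue
                boxes.append(_tight_box(m))
                classes.append(cid)
                if spec.emit_masks:
                    yy, xx = np.nonzero(m)
                    masksets.append(set(zip(xx.tolist(), yy.tolist())))
                n_lesions += 1
        if n_lesions == 0:
            boxes.append(_tight_box(fruit["mask"]))
            classes.append(HEALTHY)
            if spec.emit_masks:
                yy, xx = np.nonzero(fruit["mask"])
                masksets.append(set(zip(xx.tolist(), yy.tolist())))

    if spec.noise_std:
        img = img + rng.normal(0.0, spec.noise_std, img.shape)
    img = img.clip(0, 255).astype(np.uint8)

    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return LabeledImage(
        img,
        boxes_xyxy_to_cxcywh(boxes, size, size),
        np.asarray(classes, dtype=np.int64),
        masks=masksets if spec.emit_masks else None,
    )


def make_dataset(n: int, spec: SceneSpec, seed: int, out_dir: str | Path,
                 ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)) -> Path:
    """Generate n scenes, split 7:2:1 by default, and write the YOLO tree."""
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    parts = split_dataset(list(range(n)), ratios, seed=seed)
    split_of = {}
    for name, ids in zip(("train", "val", "test"), parts):
        for i in ids:
            split_of[i] = name
        (out / "images" / name).mkdir(parents=True, exist_ok=True)
        (out / "labels" / name).mkdir(parents=True, exist_ok=True)
    for i in range(n):
        item = synth_scene(spec, rng)
        name = split_of[i]
        stem = f"scene_{i:05d}"
        save_image(item.image, out / "images" / name / f"{stem}.png")
        annots = [
            (int(c), *map(float, b)) for c, b in zip(item.classes, item.boxes)
        ]
        write_yolo_labels(annots, out / "labels" / name / f"{stem}.txt")
    write_manifest(out, CLASS_NAMES)
    return out
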