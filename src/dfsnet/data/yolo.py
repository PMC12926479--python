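"""YOLO-format dataset I/O.

One ``.txt`` label file per image; each line is ``class cx cy w h`` with
centre/size coordinates normalised to [0, 1].  A dataset directory holds
``images/<split>/`` and ``labels/<split>/`` trees plus a YAML manifest with
class names and split paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

CLASS_NAMES = ("FruitBorer", "FruitRot", "MelonThrips", "Healthy")

__all__ = [
    "CLASS_NAMES",
    "LabeledImage",
    "read_yolo_labels",
    "write_yolo_labels",
    "load_image",
    "save_image",
    "write_manifest",
    "read_manifest",
    "boxes_cxcywh_to_xyxy",
    "boxes_xyxy_to_cxcywh",
]


@dataclass
class LabeledImage:
    """An H×W×3 uint8 image with normalised cxcywh boxes and class ids."""

    image: np.ndarray
    boxes: np.ndarray  # (N, 4) normalised (cx, cy, w, h)
    classes: np.ndarray  # (N,) int
    masks: list | None = None  # optional per-instance pixel sets

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.classes = np.asarray(self.classes, dtype=np.int64).reshape(-1)
        if len(self.boxes) != len(self.classes):
            raise ValueError("boxes and classes must have equal length")

    @property
    def size(self) -> tuple[int, int]:
        return self.image.shape[0], self.image.shape[1]


def read_yolo_labels(path: str | Path) -> list[tuple[int, float, float, float, float]]:
    """Parse a YOLO label file into (class, cx, cy, w, h) tuples."""
    out = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: unparseable value ({e})") from None
        if cid < 0:
            raise ValueError(f"{path}:{ln}: negative class id {cid}")
        for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{ln}: {name}={v} outside [0, 1]")
        if w <= 0 or h <= 0:
            raise ValueError(f"{path}:{ln}: non-positive box size")
        out.append((cid, cx, cy, w, h))
    return out


def write_yolo_labels(annotations, path: str | Path) -> None:
    """Write (class, cx, cy, w, h) tuples, 6 decimals, one line per object."""
    lines = []
    for cid, cx, cy, w, h in annotations:
        lines.append(f"{int(cid)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_manifest(root: str | Path, names=CLASS_NAMES,
                   splits=("train", "val", "test")) -> Path:
    root = Path(root)
    manifest = {
        "path": str(root),
        "names": {i: n for i, n in enumerate(names)},
        **{s: f"images/{s}" for s in splits},
    }
    out = root / "data.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_manifest(path: str | Path) -> dict:
    d = yaml.safe_load(Path(path).read_text())
    d["names"] = [d["names"][k] for k in sorted(d["names"])]
    return d


def boxes_cxcywh_to_xyxy(boxes: np.ndarray, w: int = 1, h: int = 1) -> np.ndarray:
    """Normalised cxcywh -> pixel (or unit) xyxy."""
    b = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    cx, cy, bw, bh = b[:, 0] * w, b[:, 1] * h, b[:, 2] * w, b[:, 3] * h
    return np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)


def boxes_xyxy_to_cxcywh(boxes: np.ndarray, w: int = 1, h: int = 1) -> np.ndarray:
    b = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return np.stack(
        [
            (b[:, 0] + b[:, 2]) / 2 / w,
            (b[:, 1] + b[:, 3]) / 2 / h,
            (b[:, 2] - b[:, 0]) / w,
            (b[:, 3] - b[:, 1]) / h,
        ],
        axis=1,
    )
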