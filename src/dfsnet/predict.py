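"""Inference: decode head outputs, filter, suppress, map back to pixels."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import nn
from .data.augment import letterbox
from .data.yolo import load_image
from .metrics import Detection
from .model import Detector
from .nn import Tensor

__all__ = ["nms", "decode_predictions", "predict"]


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.7) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first.

    Ties in score break toward the earlier index (stable order).
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    order = np.argsort(-scores, kind="stable").tolist()
    keep: list[int] = []
    while order:
        i = order.pop(0)
        keep.append(i)
        if not order:
            break
        rest = np.array(order)
        tl = np.maximum(boxes[i, :2], boxes[rest, :2])
        br = np.minimum(boxes[i, 2:], boxes[rest, 2:])
        wh = (br - tl).clip(min=0)
        inter = wh[:, 0] * wh[:, 1]
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / (area_i + area_r - inter + 1e-12)
        order = [o for o, v in zip(order, iou) if v <= iou_thr]
    return keep


def decode_predictions(model: Detector, batch: np.ndarray, conf_thresh: float = 0.25,
                       nms_iou: float = 0.7, max_det: int = 300) -> list[list[Detection]]:
    """Forward a letterboxed batch and return per-image detections (letterbox px)."""
    model.eval()
    with nn.no_grad():
        preds = model(Tensor(batch))
        cls_all, box_all, _ = model.decode(preds)
    probs = 1.0 / (1.0 + np.exp(-cls_all.data))  # (B, N, nc)
    boxes = box_all.data  # (B, N, 4)
    out = []
    for b in range(batch.shape[0]):
        dets: list[Detection] = []
        conf = probs[b].max(axis=1)
        cls = probs[b].argmax(axis=1)
        sel = np.nonzero(conf >= conf_thresh)[0]
        for c in np.unique(cls[sel]):
            rows = sel[cls[sel] == c]
            keep = nms(boxes[b, rows], conf[rows], nms_iou)
            for k in keep[:max_det]:
                r = rows[k]
                dets.append(Detection(box=tuple(boxes[b, r].tolist()), cls=int(c),
                                      conf=float(min(conf[r], 1.0)), image_id=b))
        dets.sort(key=lambda d: -d.conf)
        out.append(dets[:max_det])
    model.train()
    return out


def predict(model: Detector, images, conf_thresh: float = 0.25,
            nms_iou: float = 0.7) -> list[list[Detection]]:
    """Run detection on images (arrays or paths) of any size.

    Images are letterboxed to the model's input size; output boxes are
    mapped back to each image's original pixel frame.
    """
    if conf_thresh > 1.0:
        return [[] for _ in images]
    size = model.cfg.input_size
    arrays, tfs = [], []
    for im in images:
        if isinstance(im, (str, Path)):
            im = load_image(im)
        lb, tf = letterbox(im, size)
        arrays.append(lb)
        tfs.append(tf)
    batch = np.stack(arrays).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
    per_img = decode_predictions(model, batch, conf_thresh, nms_iou)
    out = []
    for i, (dets, tf) in enumerate(zip(per_img, tfs)):
        mapped = []
        for d in dets:
            box = tf.invert_boxes(np.array(d.box)).reshape(4)
            h, w = tf.orig_size
            box = np.clip(box, [0, 0, 0, 0], [w, h, w, h])
            if box[2] <= box[0] or box[3] <= box[1]:
                continue
            mapped.append(Detection(box=tuple(box.tolist()), cls=d.cls,
                                    conf=d.conf, image_id=i))
        out.append(mapped)
    return out
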