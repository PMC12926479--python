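"""Training: dataset loading, the optimisation loop, logging, checkpoints.

Defaults follow the reference training configuration for this detector:
AdamW at learning rate 0.001
with first-moment coefficient 0.9, batch size 16, constant schedule
(150 epochs at full scale; tests run far smaller).  The objective is the
quality-weighted classification BCE plus λ times the scale-based dynamic
box loss over task-aligned matches.  Runs are deterministic given the
seed: data order, augmentation, initialisation and optimisation all draw
from generators derived from it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .assign import assign_targets
from .data.augment import AugmentConfig, augment, letterbox, mosaic
from .data.yolo import (
    LabeledImage,
    boxes_cxcywh_to_xyxy,
    load_image,
    read_manifest,
    read_yolo_labels,
)
from .metrics import Detection, EvalReport, GroundTruth, evaluate
from .model import Detector, ModelConfig, build_model
from .nn import AdamW, Tensor
from .predict import decode_predictions
from .sdloss import SDParams, total_loss

__all__ = ["TrainConfig", "DetectionDataset", "compute_loss", "train",
           "save_checkpoint", "load_checkpoint", "evaluate_model",
           "smoke_train_config"]


@dataclass
class TrainConfig:
    data_dir: str = ""
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 150
    batch_size: int = 16
    lr: float = 0.001
    momentum: float = 0.9  # Adam beta1
    weight_decay: float = 0.0005
    seed: int = 0
    mosaic_prob: float = 0.0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    conf_thresh: float = 0.25
    nms_iou: float = 0.7
    eval_interval: int = 0  # 0: only at the end
    out_dir: str = "runs/train"
    # scale-dynamic loss knobs: delta, max_bgt, gamma, p, lambda,
    # use_mask_branch, invert_theta (see SDParams)
    loss: dict = field(default_factory=dict)

    def loss_params(self) -> SDParams:
        kw = dict(self.loss)
        kw.pop("use_mask_branch", None)  # mask pairs are supplied per batch
        if "lambda" in kw:
            kw["lam"] = kw.pop("lambda")
        return SDParams(**kw)

    def use_mask_branch(self) -> bool:
        return bool(self.loss.get("use_mask_branch", False))


def smoke_train_config(data_dir: str | Path, out_dir: str | Path,
                       seed: int = 7, epochs: int = 80) -> TrainConfig:
    """The reduced-scale training benchmark: tiny DFSNet at 128², batch 8.

    64 easy synthetic scenes train in minutes on one CPU.  The learning
    rate is raised to 0.005 because the run sees only a few hundred
    optimiser steps — at the full-scale default (0.001 over 150 epochs ×
    hundreds of batches) the tiny run would barely leave initialisation.
    """
    from .model import tiny_dfsnet_config

    return TrainConfig(
        data_dir=str(data_dir),
        model=tiny_dfsnet_config(seed=3),
        epochs=epochs,
        batch_size=8,
        lr=0.005,
        seed=seed,
        augment=AugmentConfig(translate=0.05, flip_h=0.5, flip_v=0.0,
                              scale=0.1, brightness=0.1, noise_std=3.0),
        conf_thresh=0.1,
        eval_interval=10,
        out_dir=str(out_dir),
    )


class DetectionDataset:
    """Images + labels of one split, optionally augmented, letterboxed to
    the model input size."""

    def __init__(self, root: str | Path, split: str, imgsz: int,
                 aug: AugmentConfig | None = None, mosaic_prob: float = 0.0):
        self.root = Path(root)
        manifest = read_manifest(self.root / "data.yaml")
        self.names = manifest["names"]
        self.imgsz = imgsz
        self.aug = aug
        self.mosaic_prob = mosaic_prob
        img_dir = self.root / "images" / split
        self.items = sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg"))
        if not self.items:
            raise FileNotFoundError(f"no images under {img_dir}")
        self.label_dir = self.root / "labels" / split

    def __len__(self) -> int:
        return len(self.items)

    def _load(self, i: int) -> LabeledImage:
        path = self.items[i]
        img = load_image(path)
        lbl = self.label_dir / (path.stem + ".txt")
        annots = read_yolo_labels(lbl) if lbl.exists() else []
        boxes = np.array([a[1:] for a in annots], dtype=np.float64).reshape(-1, 4)
        classes = np.array([a[0] for a in annots], dtype=np.int64)
        return LabeledImage(img, boxes, classes)

    def sample(self, i: int, rng: np.random.Generator) -> LabeledImage:
        if self.mosaic_prob and rng.random() < self.mosaic_prob:
            others = rng.integers(0, len(self.items), size=3)
            tiles = [self._load(i)] + [self._load(int(o)) for o in others]
            item, _ = mosaic(tiles, self.imgsz, rng)
        else:
            item = self._load(i)
        if self.aug is not None:
            item = augment(item, self.aug, rng)
        return item

    def as_batch(self, items: list[LabeledImage]) -> tuple[np.ndarray, list]:
        """Letterbox to imgsz; returns (B,3,S,S) float batch + px targets."""
        arrs, targets = [], []
        for it in items:
            h, w = it.size
            if (h, w) != (self.imgsz, self.imgsz):
                lb, tf = letterbox(it.image, self.imgsz)
                boxes = tf.apply_boxes(boxes_cxcywh_to_xyxy(it.boxes, w, h))
            else:
                lb = it.image
                boxes = boxes_cxcywh_to_xyxy(it.boxes, w, h)
            arrs.append(lb.astype(np.float32).transpose(2, 0, 1) / 255.0)
            targets.append({"boxes": boxes, "classes": it.classes})
        return np.stack(arrs), targets


def compute_loss(model: Detector, batch: np.ndarray, targets: list,
                 params: SDParams) -> dict:
    """Forward + assignment + total loss for one batch."""
    preds = model(Tensor(batch))
    cls_all, box_all, meta = model.decode(preds)
    nc = model.cfg.nc
    probs = 1.0 / (1.0 + np.exp(-cls_all.data))
    centers = meta["center"]
    strides = meta["stride"]
    losses, comps = [], {"cls": 0.0, "reg": 0.0}
    for b, tgt in enumerate(targets):
        res = assign_targets(probs[b], box_all.data[b], centers,
                             tgt["boxes"], tgt["classes"], nc)
        out = total_loss(cls_all[b], box_all[b], res.target_scores,
                         res.target_boxes, res.fg_mask, params,
                         theta=strides[res.fg_mask])
        losses.append(out["loss"])
        comps["cls"] += out["cls"]
        comps["reg"] += out["reg"]
    loss = losses[0]
    for l in losses[1:]:
        loss = loss + l
    loss = loss * (1.0 / len(losses))
    comps = {k: v / len(losses) for k, v in comps.items()}
    comps["loss"] = loss
    return comps


def save_checkpoint(path: str | Path, model: Detector, optimizer: AdamW | None = None,
                    epoch: int = 0, extra: dict | None = None) -> Path:
    import hashlib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg_dict = model.cfg.to_dict()
    cfg_hash = hashlib.sha1(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    meta = {"config": cfg_dict, "config_hash": cfg_hash, "epoch": epoch,
            **(extra or {})}
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        st = optimizer.state_dict()
        arrays["opt::t"] = np.array(st["t"])
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"opt::m{i}"] = m
            arrays[f"opt::v{i}"] = v
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[Detector, dict]:
    import hashlib

    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if "config_hash" in meta:
            want = hashlib.sha1(
                json.dumps(meta["config"], sort_keys=True).encode()
            ).hexdigest()
            if meta["config_hash"] != want:
                raise ValueError(f"checkpoint config hash mismatch in {path}")
        cfg = ModelConfig.from_dict(meta["config"])
        model = build_model(cfg)
        state = {k.split("::", 1)[1]: z[k] for k in z.files if k.startswith("param::")}
        model.load_state_dict(state)
        opt_state = None
        if "opt::t" in z.files:
            n = sum(1 for k in z.files if k.startswith("opt::m"))
            opt_state = {
                "t": int(z["opt::t"]),
                "m": [z[f"opt::m{i}"] for i in range(n)],
                "v": [z[f"opt::v{i}"] for i in range(n)],
            }
        meta["optimizer"] = opt_state
    return model, meta


def evaluate_model(model: Detector, dataset: DetectionDataset,
                   conf_thresh: float = 0.25, nms_iou: float = 0.7) -> EvalReport:
    """mAP of a model over one dataset split (images at their stored size)."""
    dets, gts = [], []
    bs = 8
    for start in range(0, len(dataset), bs):
        items = [dataset._load(i) for i in range(start, min(start + bs, len(dataset)))]
        batch, targets = dataset.as_batch(items)
        per_img = decode_predictions(model, batch, conf_thresh, nms_iou)
        for j, (dd, tgt) in enumerate(zip(per_img, targets)):
            img_id = start + j
            dets.extend(Detection(box=d.box, cls=d.cls, conf=d.conf, image_id=img_id)
                        for d in dd)
            gts.extend(GroundTruth(box=tuple(bx.tolist()), cls=int(c), image_id=img_id)
                       for bx, c in zip(tgt["boxes"], tgt["classes"]))
    return evaluate(dets, gts, nc=model.cfg.nc)


def train(cfg: TrainConfig, resume: str | Path | None = None) -> dict:
    """Optimise a detector on the configured dataset.

    Returns a history dict with per-epoch loss components, validation
    reports and checkpoint paths.  ``lr=0`` leaves weights untouched;
    identical seeds give identical loss curves.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "metrics.jsonl"

    train_ds = DetectionDataset(cfg.data_dir, "train", cfg.model.input_size,
                                aug=cfg.augment, mosaic_prob=cfg.mosaic_prob)
    if len(train_ds) == 0:
        raise ValueError("empty training partition")
    try:
        val_ds = DetectionDataset(cfg.data_dir, "val", cfg.model.input_size)
    except FileNotFoundError:
        val_ds = None

    start_epoch = 0
    if resume is not None:
        model, meta = load_checkpoint(resume)
        start_epoch = int(meta.get("epoch", 0))
    else:
        model = build_model(cfg.model)
        meta = {}
    params = [p for p in model.parameters()]
    opt = AdamW(params, lr=cfg.lr, betas=(cfg.momentum, 0.999),
                weight_decay=cfg.weight_decay)
    if resume is not None and meta.get("optimizer"):
        opt.load_state_dict(meta["optimizer"])

    sd = cfg.loss_params()
    history: dict = {"epochs": [], "val": []}
    best_map, best_path = -1.0, out_dir / "best.npz"
    rng = np.random.default_rng(cfg.seed)

    with open(log_path, "a") as log:
        for epoch in range(start_epoch, cfg.epochs):
            model.train()
            order = rng.permutation(len(train_ds))
            ep = {"cls": 0.0, "reg": 0.0, "loss": 0.0}
            nb = 0
            t0 = time.time()
            for s in range(0, len(order), cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                items = [train_ds.sample(int(i), rng) for i in idx]
                batch, targets = train_ds.as_batch(items)
                comps = compute_loss(model, batch, targets, sd)
                opt.zero_grad()
                comps["loss"].backward()
                opt.step()
                ep["cls"] += comps["cls"]
                ep["reg"] += comps["reg"]
                ep["loss"] += float(comps["loss"].data)
                nb += 1
            rec = {k: v / nb for k, v in ep.items()}
            rec.update(epoch=epoch, seconds=round(time.time() - t0, 2))
            history["epochs"].append(rec)

            do_eval = val_ds is not None and (
                epoch == cfg.epochs - 1
                or (cfg.eval_interval and (epoch + 1) % cfg.eval_interval == 0)
            )
            if do_eval:
                rep = evaluate_model(model, val_ds, cfg.conf_thresh, cfg.nms_iou)
                rec["map50"] = rep.map50
                rec["map50_95"] = rep.map50_95
                history["val"].append({"epoch": epoch, "map50": rep.map50,
                                       "map50_95": rep.map50_95})
                if rep.map50 > best_map:
                    best_map = rep.map50
                    save_checkpoint(best_path, model, opt, epoch + 1,
                                    {"map50": rep.map50})
            log.write(json.dumps(rec) + "\n")
            log.flush()

    last_path = save_checkpoint(out_dir / "last.npz", model, opt, cfg.epochs)
    if best_map < 0:
        best_path = last_path
    history["best_map50"] = best_map
    history["checkpoint"] = str(best_path if best_path.exists() else last_path)
    history["last"] = str(last_path)
    return history
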