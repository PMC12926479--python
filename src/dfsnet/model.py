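"""Detector assembly: baseline and DFSNet variants, plus budget accounting.

The baseline follows the public nano-scale one-stage layout: a P1–P5
backbone of CBS downsamplers and C3k2 cross-stage blocks closed by SPPF
and a position-sensitive attention stage, a top-down + bottom-up neck, and
a decoupled detection head with distribution-focal box regression.

Four independent switches turn it into DFSNet:

* ``use_pconv``  — pinwheel convolutions replace the P1/P2 downsamplers;
* ``use_msda``   — the backbone C3k2 blocks at P3–P5 gain a parallel MSDA
  path (wavelet multi-scale + directional edge enhancement);
* ``use_msla``   — the three neck fusion blocks feeding the head become
  CSP-MSLA units (linear attention in a cross-stage wrapper), at slimmer
  stage widths;
* ``use_sddh``   — the head becomes the shared-tower SDDH: per-level 1×1
  projections into a common width, a weight-shared depthwise-separable
  tower with level-specific batch norm, and direct distance regression
  supervised by the scale-based dynamic loss.

``count_parameters`` counts trainable scalars exactly;``count_flops`` runs
one forward pass with the convolution MAC counter armed and reports
2·MACs (the convention of common profilers, which count convolutions on
the fused model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .layers.common import C2PSA, C3k2, ConvBNAct, DWConv, SPPF
from .layers.msda import C3k2MSDA
from .layers.msla import CSPMSLA
from .layers.pinwheel import PConv
from .nn import Tensor
from .nn.functional import flop_counter

__all__ = [
    "ModelConfig",
    "PredictionSet",
    "Detector",
    "build_model",
    "baseline_config",
    "dfsnet_config",
    "count_parameters",
    "count_flops",
]

STRIDES = (8, 16, 32)


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(math.ceil(x / divisor) * divisor))


@dataclass
class ModelConfig:
    """Structural description of one detector build."""

    nc: int = 4
    class_names: tuple = ("FruitBorer", "FruitRot", "MelonThrips", "Healthy")
    input_size: int = 640
    width: float = 0.25
    depth: float = 0.50
    max_channels: int = 1024
    use_pconv: bool = False
    use_msda: bool = False
    use_msla: bool = False
    use_sddh: bool = False
    # DFSNet stage widths for the three CSP-MSLA neck outputs (P3, P4, P5)
    msla_widths: tuple = (64, 96, 104)
    # width of the top-down 40x40 fusion block when the MSLA neck is active
    msla_mid: int | None = 96
    # reduced widths of the parallel MSDA paths at backbone P3/P4/P5
    msda_widths: tuple = (32, 32, 24)
    sddh_width: int = 96
    sddh_depth: int = 4
    reg_max: int = 16
    seed: int = 0

    def ch(self, c: int) -> int:
        return make_divisible(min(c, self.max_channels) * self.width, 8)

    def n(self, reps: int) -> int:
        return max(round(reps * self.depth), 1)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for key in ("class_names", "msla_widths", "msda_widths"):
            d[key] = list(d[key])
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("class_names", "msla_widths", "msda_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return ModelConfig(**d)


def baseline_config(**kw) -> ModelConfig:
    return ModelConfig(**kw)


def dfsnet_config(**kw) -> ModelConfig:
    kw.setdefault("use_pconv", True)
    kw.setdefault("use_msda", True)
    kw.setdefault("use_msla", True)
    kw.setdefault("use_sddh", True)
    return ModelConfig(**kw)


def tiny_dfsnet_config(input_size: int = 128, **kw) -> ModelConfig:
    """A reduced-width DFSNet for CPU-scale experiments and tests."""
    kw.setdefault("width", 0.125)
    kw.setdefault("max_channels", 512)
    kw.setdefault("msla_widths", (16, 24, 32))
    kw.setdefault("msla_mid", 24)
    kw.setdefault("msda_widths", (8, 8, 8))
    kw.setdefault("sddh_width", 24)
    kw.setdefault("sddh_depth", 2)
    return dfsnet_config(input_size=input_size, **kw)


@dataclass
class PredictionSet:
    """Raw per-level head outputs plus decode metadata."""

    cls: list  # per level: (B, nc, H, W) logits
    box: list  # per level: (B, 4*reg_max, H, W) distributions or (B, 4, H, W) distances
    strides: tuple = STRIDES


class BaselineHead(nn.Module):
    """Decoupled head with distribution-focal box regression."""

    def __init__(self, nc: int, ch: tuple, reg_max: int = 16, rng=None):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = nn.ModuleList()
        self.cv3 = nn.ModuleList()
        for x in ch:
            self.cv2.append(
                nn.Sequential(
                    ConvBNAct(x, c2, 3, rng=rng),
                    ConvBNAct(c2, c2, 3, rng=rng),
                    nn.Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng),
                )
            )
            self.cv3.append(
                nn.Sequential(
                    nn.Sequential(DWConv(x, x, 3, rng=rng), ConvBNAct(x, c3, 1, rng=rng)),
                    nn.Sequential(DWConv(c3, c3, 3, rng=rng), ConvBNAct(c3, c3, 1, rng=rng)),
                    nn.Conv2d(c3, nc, 1, bias=True, rng=rng),
                )
            )
        for m in self.cv3:
            m[2].bias.data[:] = -math.log((1 - 0.01) / 0.01)
        self.register_buffer("dfl_proj", np.arange(reg_max, dtype=np.float32))

    def forward(self, feats: list) -> PredictionSet:
        cls = [m(f) for m, f in zip(self.cv3, feats)]
        box = [m(f) for m, f in zip(self.cv2, feats)]
        return PredictionSet(cls=cls, box=box)

    def decode_distances(self, box_out: Tensor) -> Tensor:
        """(B, 4*reg_max, H, W) -> (B, 4, H, W) expected ltrb distances (cells)."""
        b, _, h, w = box_out.shape
        x = box_out.reshape(b, 4, self.reg_max, h * w)
        probs = x.softmax(axis=2)
        proj = Tensor(self.dfl_proj.reshape(1, 1, self.reg_max, 1).astype(probs.dtype))
        return (probs * proj).sum(axis=2).reshape(b, 4, h, w)


class SDDH(nn.Module):
    """Shape-aware dynamic detection head (shared-tower, direct regression).

    All three levels share one depthwise-separable tower and the final 1×1
    predictors; only the input projections, batch norms and the per-level
    regression scales are level-specific, which is what makes the head
    light.  Box outputs are ltrb distances in grid cells via softplus.
    """

    def __init__(self, nc: int, ch: tuple, width: int = 72, depth: int = 2, rng=None):
        super().__init__()
        self.nc = nc
        self.width = width
        self.depth = depth
        self.proj = nn.ModuleList([ConvBNAct(x, width, 1, rng=rng) for x in ch])
        self.tower_dw = nn.ModuleList()
        self.tower_pw = nn.ModuleList()
        self.tower_bns = nn.ModuleList()
        for _ in range(depth):
            self.tower_dw.append(
                nn.Conv2d(width, width, 3, padding=1, groups=width, bias=False, rng=rng)
            )
            self.tower_pw.append(nn.Conv2d(width, width, 1, bias=False, rng=rng))
            for _ in ch:  # level-specific norms: (level-major within depth)
                self.tower_bns.append(nn.BatchNorm2d(width))
        self.cls_pred = nn.Conv2d(width, nc, 1, bias=True, rng=rng)
        self.reg_pred = nn.Conv2d(width, 4, 1, bias=True, rng=rng)
        self.cls_pred.bias.data[:] = -math.log((1 - 0.01) / 0.01)
        self.reg_scale = nn.Parameter(np.ones(len(ch), dtype=np.float32))

    def forward(self, feats: list) -> PredictionSet:
        cls, box = [], []
        nlev = len(self.proj)
        for i, f in enumerate(feats):
            t = self.proj[i](f)
            for j in range(self.depth):
                t = self.tower_dw[j](t)
                t = self.tower_pw[j](t)
                t = self.tower_bns[j * nlev + i](t).silu()
            cls.append(self.cls_pred(t))
            box.append(self.reg_pred(t))
        return PredictionSet(cls=cls, box=box)

    def decode_distances(self, box_out: Tensor, level: int = 0) -> Tensor:
        """(B, 4, H, W) raw -> positive ltrb distances in grid cells."""
        scale = self.reg_scale[level : level + 1].reshape(1, 1, 1, 1)
        return box_out.softplus() * scale


class Detector(nn.Module):
    """Backbone + neck + head; returns per-level prediction maps."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.ch
        n = cfg.n(2)

        c1, c2_, c3_, c4_, c5_ = c(64), c(128), c(256), c(512), c(1024)

        # -- backbone ---------------------------------------------------------
        if cfg.use_pconv:
            self.stem1 = PConv(3, c1, stride=2, rng=rng)
            self.stem2 = PConv(c1, c2_, stride=2, rng=rng)
        else:
            self.stem1 = ConvBNAct(3, c1, 3, 2, rng=rng)
            self.stem2 = ConvBNAct(c1, c2_, 3, 2, rng=rng)
        self.b2 = C3k2(c2_, c3_, n=n, c3k=False, e=0.25, rng=rng)
        self.down3 = ConvBNAct(c3_, c3_, 3, 2, rng=rng)
        if cfg.use_msda:
            mw = cfg.msda_widths
            mk = lambda ci, co, c3k, i: C3k2MSDA(ci, co, n=n, c3k=c3k,
                                                 e=0.25 if not c3k else 0.5,
                                                 msda_width=mw[i], rng=rng)
        else:
            mk = lambda ci, co, c3k, i: C3k2(ci, co, n=n, c3k=c3k,
                                             e=0.25 if not c3k else 0.5, rng=rng)
        self.b3 = mk(c3_, c4_, False, 0)
        self.down4 = ConvBNAct(c4_, c4_, 3, 2, rng=rng)
        self.b4 = mk(c4_, c4_, True, 1)
        self.down5 = ConvBNAct(c4_, c5_, 3, 2, rng=rng)
        self.b5 = mk(c5_, c5_, True, 2)
        self.sppf = SPPF(c5_, c5_, 5, rng=rng)
        self.psa = C2PSA(c5_, c5_, n=cfg.n(2), rng=rng)

        # -- neck -------------------------------------------------------------
        self.up = nn.Upsample(2)
        mid = (cfg.msla_mid or c4_) if cfg.use_msla else c4_
        self.n_td4 = C3k2(c5_ + c4_, mid, n=n, c3k=False, rng=rng)  # 40x40 mid
        if cfg.use_msla:
            w3, w4, w5 = cfg.msla_widths
            # depthwise-separable downsamplers keep the attention neck light
            dsep = lambda w: nn.Sequential(DWConv(w, w, 3, 2, rng=rng),
                                           ConvBNAct(w, w, 1, rng=rng))
            self.n_p3 = CSPMSLA(mid + c4_, w3, rng=rng)
            self.n_down3 = dsep(w3)
            self.n_p4 = CSPMSLA(w3 + mid, w4, rng=rng)
            self.n_down4 = dsep(w4)
            self.n_p5 = CSPMSLA(w4 + c5_, w5, rng=rng)
            head_ch = (w3, w4, w5)
        else:
            self.n_p3 = C3k2(c4_ + c4_, c3_, n=n, c3k=False, rng=rng)
            self.n_down3 = ConvBNAct(c3_, c3_, 3, 2, rng=rng)
            self.n_p4 = C3k2(c3_ + c4_, c4_, n=n, c3k=False, rng=rng)
            self.n_down4 = ConvBNAct(c4_, c4_, 3, 2, rng=rng)
            self.n_p5 = C3k2(c4_ + c5_, c5_, n=n, c3k=True, rng=rng)
            head_ch = (c3_, c4_, c5_)

        # -- head -------------------------------------------------------------
        self.head_ch = head_ch
        if cfg.use_sddh:
            self.head = SDDH(cfg.nc, head_ch, width=cfg.sddh_width,
                             depth=cfg.sddh_depth, rng=rng)
        else:
            self.head = BaselineHead(cfg.nc, head_ch, reg_max=cfg.reg_max, rng=rng)

    # -- forward ---------------------------------------------------------------
    def backbone(self, x: Tensor) -> tuple:
        x = self.stem2(self.stem1(x))
        x = self.b2(x)
        p3 = self.b3(self.down3(x))
        p4 = self.b4(self.down4(p3))
        p5 = self.psa(self.sppf(self.b5(self.down5(p4))))
        return p3, p4, p5

    def forward(self, x: Tensor) -> PredictionSet:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        h, w = x.shape[-2:]
        if h % 32 or w % 32:
            raise ValueError(f"input size must be a multiple of 32, got {h}x{w}")
        p3, p4, p5 = self.backbone(x)
        td4 = self.n_td4(nn.concatenate([self.up(p5), p4], axis=1))
        o3 = self.n_p3(nn.concatenate([self.up(td4), p3], axis=1))
        o4 = self.n_p4(nn.concatenate([self.n_down3(o3), td4], axis=1))
        o5 = self.n_p5(nn.concatenate([self.n_down4(o4), p5], axis=1))
        return self.head([o3, o4, o5])

    # -- decode ----------------------------------------------------------------
    def decode(self, preds: PredictionSet) -> tuple:
        """Return (cls_logits (N, nc) Tensor, boxes_px (N, 4) Tensor, meta).

        meta holds per-anchor stride and grid centre arrays (NumPy).
        Rows are ordered level-major, row-major within a level.
        """
        cls_list, box_list, strides_arr, centers = [], [], [], []
        for lvl, (cl, bx) in enumerate(zip(preds.cls, preds.box)):
            b, nc, h, w = cl.shape
            stride = preds.strides[lvl]
            if isinstance(self.head, SDDH):
                dist = self.head.decode_distances(bx, level=lvl)  # cells
            else:
                dist = self.head.decode_distances(bx)
            ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            cx = (xs.reshape(-1) + 0.5)
            cy = (ys.reshape(-1) + 0.5)
            d = dist.reshape(b, 4, h * w)
            l, t, r, bo = d[:, 0], d[:, 1], d[:, 2], d[:, 3]
            cxt = Tensor(cx.astype(d.dtype))
            cyt = Tensor(cy.astype(d.dtype))
            x1 = (cxt - l) * stride
            y1 = (cyt - t) * stride
            x2 = (cxt + r) * stride
            y2 = (cyt + bo) * stride
            boxes = nn.stack([x1, y1, x2, y2], axis=-1)  # (B, HW, 4)
            cls_list.append(cl.reshape(b, nc, h * w).swapaxes(1, 2))
            box_list.append(boxes)
            strides_arr.append(np.full(h * w, stride, dtype=np.float64))
            centers.append(np.stack([cx * stride, cy * stride], axis=1))
        cls_all = nn.concatenate(cls_list, axis=1)
        box_all = nn.concatenate(box_list, axis=1)
        meta = {
            "stride": np.concatenate(strides_arr),
            "center": np.concatenate(centers, axis=0),
        }
        return cls_all, box_all, meta


def build_model(cfg: ModelConfig) -> Detector:
    if cfg.nc < 1:
        raise ValueError("need at least one class")
    if len(cfg.msla_widths) != 3:
        raise ValueError("msla_widths must have three entries (P3, P4, P5)")
    return Detector(cfg)


def count_parameters(model: Detector) -> int:
    """Exact number of trainable scalars."""
    return model.num_parameters()


def count_flops(model: Detector, input_size: int | None = None) -> float:
    """GFLOPs of one forward pass (2 ops per convolution MAC)."""
    size = input_size or model.cfg.input_size
    model.eval()
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    with nn.no_grad(), flop_counter() as ctx:
        model(Tensor(x))
    model.train()
    return 2.0 * ctx["macs"] / 1e9
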