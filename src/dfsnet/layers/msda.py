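"""MSDA: multi-scale directional aggregation with edge enhancement.

The block maps channels with a 1×1 projection, splits the result into a
multi-scale stream F_m and an attention stream F_a, and processes them in
parallel:

* the multi-scale branch stacks two wavelet convolutions around a GELU,
  F_ms = F_m + WT₂(GELU(WT₁(F_m))), a residual large-receptive-field path;
* the DEE branch estimates horizontal/vertical feature gradients with
  depthwise kernels (initialised to Sobel filters), fuses them, gates the
  fused response through a sigmoid 1×1 convolution and re-injects it
  residually — a constant input produces exactly zero edge response, so
  flat regions pass through untouched.

The two streams are concatenated, projected back with a 1×1 convolution
and added to the block input.  ``C3k2MSDA`` wires an MSDA path in parallel
with a standard C3k2 stage and fuses the two by concat + 1×1.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import Tensor
from .common import C3k2, ConvBNAct
from .wavelet import WTConv2d

__all__ = ["msda_split", "MultiScaleBranch", "DEE", "MSDA", "C3k2MSDA"]

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()


def msda_split(f0: Tensor, ratio: float = 0.5) -> tuple[Tensor, Tensor]:
    """Channel-wise split of F0 into (F_m, F_a); concatenation inverts it.

    The first ``floor(C * ratio)`` channels form F_m, the rest F_a.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must lie in (0, 1), got {ratio}")
    c = f0.shape[-3]
    if c < 2:
        raise ValueError("need at least 2 channels to split")
    cm = int(c * ratio)
    cm = min(max(cm, 1), c - 1)
    if f0.ndim == 3:
        return f0[:cm], f0[cm:]
    return f0[:, :cm], f0[:, cm:]


class MultiScaleBranch(nn.Module):
    """F_ms = F_m + WT₂(GELU(WT₁(F_m))) — residual by construction."""

    def __init__(self, channels: int, wt_levels: int = 2, rng=None):
        super().__init__()
        self.wt1 = WTConv2d(channels, levels=wt_levels, rng=rng)
        self.wt2 = WTConv2d(channels, levels=wt_levels, rng=rng)

    def forward(self, fm: Tensor) -> Tensor:
        return fm + self.wt2(self.wt1(fm).gelu())


class DEE(nn.Module):
    """Directional edge enhancer.

    The input is split into channel halves F_a1 / F_a2 feeding a horizontal
    and a vertical depthwise gradient kernel; the fused response F_d is
    sigmoid-gated and added back onto the input.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 2:
            raise ValueError(f"DEE needs an even channel count, got {channels}")
        self.channels = channels
        ch = channels // 2
        # replicate-padded gradient convs: a constant map yields an exactly
        # zero edge response everywhere, borders included
        self.grad_h = nn.Conv2d(ch, ch, 3, padding=0, groups=ch, bias=False, rng=rng)
        self.grad_v = nn.Conv2d(ch, ch, 3, padding=0, groups=ch, bias=False, rng=rng)
        # learnable, but started as true image-gradient operators
        self.grad_h.weight.data[:] = SOBEL_X[None, None]
        self.grad_v.weight.data[:] = SOBEL_Y[None, None]
        self.gate = nn.Conv2d(ch, ch, 1, bias=True, rng=rng)

    @staticmethod
    def _replicate_pad1(x: Tensor) -> Tensor:
        x = nn.concatenate([x[..., :1, :], x, x[..., -1:, :]], axis=-2)
        return nn.concatenate([x[..., :, :1], x, x[..., :, -1:]], axis=-1)

    def edge_response(self, fa: Tensor) -> tuple[Tensor, Tensor]:
        """Return (F_d, F_att): fused gradient magnitude and its gated form."""
        ch = self.channels // 2
        fa1 = fa[:, :ch] if fa.ndim == 4 else fa[:ch]
        fa2 = fa[:, ch:] if fa.ndim == 4 else fa[ch:]
        squeeze = fa.ndim == 3
        if squeeze:
            fa1 = fa1.reshape(1, *fa1.shape)
            fa2 = fa2.reshape(1, *fa2.shape)
        fd = self.grad_h(self._replicate_pad1(fa1)) + self.grad_v(self._replicate_pad1(fa2))
        a = self.gate(fd).sigmoid()
        fatt = fd * a
        if squeeze:
            fd = fd.reshape(*fd.shape[1:])
            fatt = fatt.reshape(*fatt.shape[1:])
        return fd, fatt

    def forward(self, fa: Tensor) -> Tensor:
        if fa.shape[-3] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {fa.shape[-3]}")
        _, fatt = self.edge_response(fa)
        axis = -3
        return fa + nn.concatenate([fatt, fatt], axis=axis)


class MSDA(nn.Module):
    """1×1 in-projection → split → {multi-scale, DEE} → concat → 1×1 → +x.

    Channel-preserving; with both projections zeroed the block is exactly
    the identity, and its output approaches the input as the branch
    weights shrink.
    """

    def __init__(self, channels: int, ratio: float = 0.5, wt_levels: int = 2, rng=None):
        super().__init__()
        if channels < 4:
            raise ValueError("MSDA needs at least 4 channels")
        self.channels = channels
        self.ratio = ratio
        cm = int(channels * ratio)
        cm = min(max(cm, 1), channels - 1)
        ca = channels - cm
        if ca % 2:  # DEE needs an even split
            cm += 1
            ca -= 1
        self.cm = cm
        self.in_proj = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.ms = MultiScaleBranch(cm, wt_levels=wt_levels, rng=rng)
        self.dee = DEE(ca, rng=rng)
        self.out_proj = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-3] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-3]}")
        f0 = self.in_proj(x)
        fm = f0[:, : self.cm] if f0.ndim == 4 else f0[: self.cm]
        fa = f0[:, self.cm :] if f0.ndim == 4 else f0[self.cm :]
        fms = self.ms(fm)
        fae = self.dee(fa)
        merged = nn.concatenate([fms, fae], axis=-3)
        return x + self.out_proj(merged)


class C3k2MSDA(nn.Module):
    """C3k2 stage with a parallel MSDA path, fused by concat + 1×1.

    One path keeps the original cross-stage C3k2 flow; the other reduces the
    input with a 1×1, runs MSDA at the reduced width and contributes extra
    multi-scale/edge context.  Zeroing the MSDA path reproduces the plain
    C3k2 output up to the fuse projection.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, msda_width: int | None = None,
                 wt_levels: int = 2, rng=None):
        super().__init__()
        w = msda_width if msda_width is not None else max(4, c2 // 4)
        w += w % 2
        self.c3k2 = C3k2(c1, c2, n=n, c3k=c3k, e=e, rng=rng)
        self.reduce = ConvBNAct(c1, w, 1, rng=rng)
        self.msda = MSDA(w, wt_levels=wt_levels, rng=rng)
        self.fuse = ConvBNAct(c2 + w, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        main = self.c3k2(x)
        side = self.msda(self.reduce(x))
        return self.fuse(nn.concatenate([main, side], axis=1))
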