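"""Standard detector building blocks.

These are the stock components of the baseline one-stage detector: the
CBS unit (conv + batch-norm + SiLU), cross-stage-partial bottleneck stacks
(C3k / C3k2), SPPF pooling pyramid, and the position-sensitive softmax
attention block that closes the backbone.  Channel widths, depths and
wiring follow the public nano-scale layout so that parameter and FLOP
budgets are comparable with published figures.
"""

from __future__ import annotations

import math

import numpy as np

from .. import nn
from ..nn import Tensor

__all__ = ["ConvBNAct", "DWConv", "Bottleneck", "C3k", "C3k2", "SPPF", "PSABlock", "C2PSA"]


def autopad(k: int) -> int:
    return k // 2


class ConvBNAct(nn.Module):
    """CBS block: bias-free convolution, batch norm, SiLU (optionally off)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | tuple | None = None,
                 g: int = 1, act: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, stride=s, padding=autopad(k) if p is None else p,
                              groups=g, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class DWConv(ConvBNAct):
    """Depthwise CBS (groups = gcd of in/out channels)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__(c1, c2, k, s, g=math.gcd(c1, c2), act=act, rng=rng)


class Bottleneck(nn.Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, g: int = 1,
                 k=(3, 3), e: float = 0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNAct(c1, c_, k[0], 1, rng=rng)
        self.cv2 = ConvBNAct(c_, c2, k[1], 1, g=g, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(nn.Module):
    """CSP bottleneck with three convolutions and n inner blocks."""

    def __init__(self, c1: int, c2: int, n: int = 2, shortcut: bool = True,
                 g: int = 1, e: float = 0.5, k: int = 3, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBNAct(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvBNAct(2 * c_, c2, 1, rng=rng)
        self.m = nn.Sequential(
            *(Bottleneck(c_, c_, shortcut, g, k=(k, k), e=1.0, rng=rng) for _ in range(n))
        )

    def forward(self, x):
        return self.cv3(nn.concatenate([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(nn.Module):
    """Two-conv CSP stage: split, run n inner blocks on the live half, re-fuse."""

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, g: int = 1, shortcut: bool = True, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBNAct((2 + n) * self.c, c2, 1, rng=rng)
        self.m = nn.ModuleList(
            [
                C3k(self.c, self.c, 2, shortcut, g, rng=rng)
                if c3k
                else Bottleneck(self.c, self.c, shortcut, g, rng=rng)
                for _ in range(n)
            ]
        )

    def forward(self, x):
        y0 = self.cv1(x)
        ys = [y0[:, : self.c], y0[:, self.c :]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(nn.concatenate(ys, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained k-pools, concatenated."""

    def __init__(self, c1: int, c2: int, k: int = 5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBNAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBNAct(c_ * 4, c2, 1, 1, rng=rng)
        self.m = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.m(y[-1]))
        return self.cv2(nn.concatenate(y, axis=1))


class _SoftmaxAttention(nn.Module):
    """Multi-head softmax attention over flattened spatial tokens with a
    depthwise positional-encoding path on V."""

    def __init__(self, dim: int, num_heads: int = 8, attn_ratio: float = 0.5, rng=None):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim**-0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = ConvBNAct(dim, h, 1, act=False, rng=rng)
        self.proj = ConvBNAct(dim, dim, 1, act=False, rng=rng)
        self.pe = ConvBNAct(dim, dim, 3, 1, g=dim, act=False, rng=rng)

    def forward(self, x):
        b, c, hh, ww = x.shape
        n = hh * ww
        qkv = self.qkv(x)
        qkv = qkv.reshape(b, self.num_heads, self.key_dim * 2 + self.head_dim, n)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim : 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim :]
        attn = (q.swapaxes(-2, -1) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = v @ attn.swapaxes(-2, -1)
        out = out.reshape(b, c, hh, ww) + self.pe(v.reshape(b, c, hh, ww))
        return self.proj(out)


class PSABlock(nn.Module):
    def __init__(self, c: int, attn_ratio: float = 0.5, num_heads: int = 4,
                 shortcut: bool = True, rng=None):
        super().__init__()
        self.attn = _SoftmaxAttention(c, num_heads=num_heads, attn_ratio=attn_ratio, rng=rng)
        self.ffn = nn.Sequential(
            ConvBNAct(c, c * 2, 1, rng=rng), ConvBNAct(c * 2, c, 1, act=False, rng=rng)
        )
        self.add = shortcut

    def forward(self, x):
        x = x + self.attn(x) if self.add else self.attn(x)
        x = x + self.ffn(x) if self.add else self.ffn(x)
        return x


class C2PSA(nn.Module):
    """CSP wrapper around a stack of position-sensitive attention blocks."""

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5, rng=None):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * e)
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBNAct(2 * self.c, c1, 1, rng=rng)
        self.m = nn.Sequential(
            *(PSABlock(self.c, attn_ratio=0.5, num_heads=max(self.c // 64, 1), rng=rng)
              for _ in range(n))
        )

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c :]
        b = self.m(b)
        return self.cv2(nn.concatenate([a, b], axis=1))
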