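"""Multi-Scale Linear Attention (MSLA) and its CSP neck wrapper.

Softmax attention costs O(N²·d) over N spatial tokens.  MSLA replaces the
softmax with a non-negative kernel feature map φ (ReLU here) and exploits
associativity: Y = φ(Q)·(φ(K)ᵀ·V) is evaluated K-first, so the d×d matrix
φ(K)ᵀV is formed once and the cost drops to O(N·d²).  Rows are normalised
by φ(Q)·Σφ(K) with an ε guard.  Positional/multi-scale structure enters
through parallel depthwise convolutions (kernel sizes 3/5/7/9 by default)
applied to the Q and K maps before flattening; their outputs are summed
with the identity so zero-weight branches leave Q/K untouched.

``CSPMSLA`` embeds MSLA in a cross-stage-partial split: one channel half
runs attention (+ a small depthwise conv block), the other passes through,
and a 1×1 fuses the concatenation.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import Tensor
from .common import ConvBNAct, DWConv

__all__ = [
    "kernel_feature",
    "linear_attention",
    "linear_attention_macs",
    "quadratic_attention",
    "quadratic_attention_macs",
    "MultiScaleQKEnhance",
    "MSLA",
    "CSPMSLA",
]

EPS = 1e-6


def kernel_feature(x: Tensor | np.ndarray) -> Tensor:
    """φ: the element-wise non-negative feature map (ReLU), φ(0) = 0."""
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))
    return x.relu()


def linear_attention(q: Tensor, k: Tensor, v: Tensor, eps: float = EPS) -> Tensor:
    """Kernelised attention in K-first association order.

    Shapes: q, k, v are (..., N, d).  Computes
    ``Y_i = φ(q_i)·(Σ_j φ(k_j)ᵀ v_j) / (φ(q_i)·Σ_j φ(k_j) + ε)``
    at O(N·d²) cost; an all-zero φ(K) column sum yields zeros, not NaN.
    """
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("Q, K, V must share the token dimension")
    fq = kernel_feature(q)
    fk = kernel_feature(k)
    kv = fk.swapaxes(-2, -1) @ v  # (..., d, d) — formed once
    num = fq @ kv  # (..., N, d)
    ksum = fk.sum(axis=-2, keepdims=True)  # (..., 1, d)
    den = (fq * ksum).sum(axis=-1, keepdims=True) + eps
    return num / den


def linear_attention_macs(n: int, d: int) -> int:
    """Analytic multiply–accumulate count of the K-first evaluation."""
    return n * d * d + n * d * d + n * d  # KᵀV, Q·(KᵀV), normaliser


def quadratic_attention(q: Tensor, k: Tensor, v: Tensor, eps: float = EPS) -> Tensor:
    """Reference O(N²·d) evaluation: explicit row-normalised φ(Q)φ(K)ᵀ times V."""
    fq = kernel_feature(q)
    fk = kernel_feature(k)
    attn = fq @ fk.swapaxes(-2, -1)  # (..., N, N)
    den = attn.sum(axis=-1, keepdims=True) + eps
    return (attn / den) @ v


def quadratic_attention_macs(n: int, d: int) -> int:
    return n * n * d + n * n * d + n * n


class MultiScaleQKEnhance(nn.Module):
    """Identity plus a sum of parallel depthwise convolutions at several scales."""

    def __init__(self, channels: int, scales=(3, 5, 7, 9), rng=None):
        super().__init__()
        self.scales = tuple(scales)
        self.branches = nn.ModuleList(
            [
                nn.Conv2d(channels, channels, k, padding=k // 2, groups=channels,
                          bias=False, rng=rng)
                for k in self.scales
            ]
        )

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for b in self.branches:
            out = out + b(x)
        return out


class MSLA(nn.Module):
    """1×1 Q/K/V projections, multi-scale Q/K enhancement, per-head linear
    attention over flattened tokens, output projection and a residual."""

    def __init__(self, channels: int, heads: int = 4, scales=(3, 5, 7, 9), rng=None):
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels ({channels}) must divide by heads ({heads})")
        self.channels = channels
        self.heads = heads
        self.q_proj = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.k_proj = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.v_proj = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.q_enh = MultiScaleQKEnhance(channels, scales, rng=rng)
        self.k_enh = MultiScaleQKEnhance(channels, scales, rng=rng)
        self.out_proj = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        b, c, h, w = x.shape
        n = h * w
        d = c // self.heads
        q = self.q_enh(self.q_proj(x))
        k = self.k_enh(self.k_proj(x))
        v = self.v_proj(x)

        def to_tokens(t):  # (B, C, H, W) -> (B, heads, N, d)
            return t.reshape(b, self.heads, d, n).swapaxes(-2, -1)

        y = linear_attention(to_tokens(q), to_tokens(k), to_tokens(v))
        y = y.swapaxes(-2, -1).reshape(b, c, h, w)
        return x + self.out_proj(y)


class CSPMSLA(nn.Module):
    """Cross-stage-partial MSLA unit for the neck fusion points.

    cv1 maps the fused input to the stage width, the channel halves go
    through {MSLA + depthwise conv block, identity}, and cv2 re-fuses.
    """

    def __init__(self, c1: int, c2: int, heads: int = 4, scales=(3, 5, 7, 9), rng=None):
        super().__init__()
        if c2 % 2:
            raise ValueError(f"stage width must be even, got {c2}")
        ch = c2 // 2
        if ch % heads:
            heads = 2 if ch % 2 == 0 else 1
        self.c = ch
        self.cv1 = ConvBNAct(c1, c2, 1, rng=rng)
        self.attn = MSLA(ch, heads=heads, scales=scales, rng=rng)
        self.post = DWConv(ch, ch, 3, rng=rng)
        self.cv2 = ConvBNAct(c2, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c :]
        a = self.post(self.attn(a))
        return self.cv2(nn.concatenate([a, b], axis=1))
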