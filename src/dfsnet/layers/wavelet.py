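"""Haar wavelet-domain convolution (WTConv).

A single orthonormal 2-D Haar step splits a feature map into four
half-resolution subbands — LL (structure) and LH/HL/HH (oriented detail).
WTConv recursively decomposes the LL chain ``levels`` deep, applies a small
depthwise convolution independently to every subband at every level, and
reconstructs back to full resolution, adding a base depthwise spatial
convolution of the input.  Because one wavelet step halves resolution, a
3×3 kernel at level L covers a ~(3·2^L)-pixel footprint, giving a large
effective receptive field at depthwise cost.

The Haar pair is fixed and orthonormal (energy preserving); the transform
itself is not learned.  Odd spatial sizes are replicate-padded on the
bottom/right before each decomposition and cropped after reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import Tensor

__all__ = ["SubbandSet", "haar_dwt2", "haar_idwt2", "WTConv2d"]


@dataclass
class SubbandSet:
    """The four Haar subbands of one decomposition level.

    Each band has spatial size ⌈H/2⌉×⌈W/2⌉ of the (possibly replicate-padded)
    input; ``orig_size`` remembers the pre-padding size so the inverse can
    crop back exactly.
    """

    ll: Tensor
    lh: Tensor
    hl: Tensor
    hh: Tensor
    orig_size: tuple[int, int] | None = None

    def bands(self) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        return (self.ll, self.lh, self.hl, self.hh)


def _replicate_pad_br(x: Tensor, pad_b: int, pad_r: int) -> Tensor:
    """Replicate the last row/column (used to even-up odd sizes)."""
    if pad_b:
        x = nn.concatenate([x, x[..., -1:, :]], axis=-2)
    if pad_r:
        x = nn.concatenate([x, x[..., :, -1:]], axis=-1)
    return x


def haar_dwt2(x: Tensor | np.ndarray) -> SubbandSet:
    """Single-level orthonormal 2-D Haar transform over the trailing axes.

    For each 2×2 block [[a, b], [c, d]]:
    LL=(a+b+c+d)/2, LH=(a−b+c−d)/2, HL=(a+b−c−d)/2, HH=(a−b−c+d)/2,
    so ‖x‖² = ‖LL‖²+‖LH‖²+‖HL‖²+‖HH‖².
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))
    if x.ndim < 2 or x.shape[-1] < 1 or x.shape[-2] < 1:
        raise ValueError(f"need at least a 1x1 spatial map, got shape {x.shape}")
    h, w = x.shape[-2:]
    x = _replicate_pad_br(x, h % 2, w % 2)
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return SubbandSet(ll, lh, hl, hh, orig_size=(h, w))


def haar_idwt2(s: SubbandSet) -> Tensor:
    """Exact inverse of :func:`haar_dwt2` (crops replicate padding back off)."""
    shapes = {t.shape for t in s.bands()}
    if len(shapes) != 1:
        raise ValueError(f"subband shapes differ: {sorted(shapes)}")
    ll, lh, hl, hh = s.bands()
    a = (ll + lh + hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    c = (ll + lh - hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5
    # interleave 2x2 blocks back: stack then reshape
    top = nn.stack([a, b], axis=-1)  # (..., h2, w2, 2)
    bot = nn.stack([c, d], axis=-1)
    rows = nn.stack([top, bot], axis=-2)  # (..., h2, w2, 2, 2)
    h2, w2 = ll.shape[-2:]
    lead = ll.shape[:-2]
    out = rows.transpose(*range(len(lead)), len(lead), len(lead) + 2, len(lead) + 1, len(lead) + 3)
    out = out.reshape(*lead, 2 * h2, 2 * w2)
    if s.orig_size is not None:
        h, w = s.orig_size
        out = out[..., :h, :w]
    return out


class WTConv2d(nn.Module):
    """Depthwise convolution over a recursive Haar subband pyramid.

    Purely linear (no norm/activation inside), so scaling the input scales
    the output.  Per-level and base paths carry per-channel learnable gains.
    With subband kernels initialised to the identity and the base path
    zeroed, the module is an exact identity map.
    """

    def __init__(self, channels: int, levels: int = 2, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if levels < 1:
            raise ValueError("levels must be >= 1")
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.channels = channels
        self.levels = levels
        self.kernel_size = kernel_size
        self.base_conv = nn.Conv2d(channels, channels, kernel_size, padding=kernel_size // 2,
                                   groups=channels, bias=False, rng=rng)
        self.base_gain = nn.Parameter(np.ones((channels, 1, 1), dtype=np.float32))
        self.subband_convs = nn.ModuleList(
            [
                nn.Conv2d(4 * channels, 4 * channels, kernel_size, padding=kernel_size // 2,
                          groups=4 * channels, bias=False, rng=rng)
                for _ in range(levels)
            ]
        )
        self._gains = [
            nn.Parameter(np.ones((4 * channels, 1, 1), dtype=np.float32)) for _ in range(levels)
        ]
        for i, g in enumerate(self._gains):
            setattr(self, f"gain_{i}", g)

    def init_identity(self) -> None:
        """Set every subband kernel to the delta kernel and zero the base path."""
        k = self.kernel_size
        for conv in self.subband_convs:
            conv.weight.data[:] = 0.0
            conv.weight.data[:, 0, k // 2, k // 2] = 1.0
        self.base_conv.weight.data[:] = 0.0
        self.base_gain.data[:] = 1.0
        for g in self._gains:
            g.data[:] = 1.0

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-3] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-3]}")
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)

        processed: list[SubbandSet] = []
        cur = x
        for lvl in range(self.levels):
            s = haar_dwt2(cur)
            stackb = nn.concatenate(s.bands(), axis=1)  # (B, 4C, h2, w2)
            out = self.subband_convs[lvl](stackb) * self._gains[lvl]
            c = self.channels
            conv_s = SubbandSet(out[:, :c], out[:, c : 2 * c], out[:, 2 * c : 3 * c],
                                out[:, 3 * c :], orig_size=s.orig_size)
            processed.append(conv_s)
            cur = conv_s.ll

        z = None
        for s in reversed(processed):
            ll = s.ll if z is None else z
            z = haar_idwt2(SubbandSet(ll, s.lh, s.hl, s.hh, orig_size=s.orig_size))

        out = z + self.base_conv(x) * self.base_gain
        if squeeze:
            out = out.reshape(*out.shape[1:])
        return out
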