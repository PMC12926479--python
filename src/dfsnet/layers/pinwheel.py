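"""Pinwheel convolution (PConv): direction-aware downsampling.

Standard convolution responds identically in every spatial direction, which
washes out oriented shallow structure — thrips feeding stripes are strongly
anisotropic and borer holes live at the few-pixel scale.  PConv runs four
parallel branches, each padding the input asymmetrically on one side
(left / right / top / bottom) before a CBS with an asymmetric kernel
(1×k for the horizontal pair, k×1 for the vertical pair).  The four branch
outputs are channel-concatenated and fused by a 2×2 CBS.  With k=3 the
layer is lighter than the k×k convolution it replaces.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import Tensor
from .common import ConvBNAct

__all__ = ["directional_pad", "PConv", "DIRECTIONS"]

DIRECTIONS = ("left", "right", "top", "bottom")


def directional_pad(x: Tensor | np.ndarray, direction: str, amount: int) -> Tensor:
    """Zero-pad a feature map by ``amount`` pixels on one named side only.

    Works on any tensor whose trailing two axes are spatial (C×H×W or
    B×C×H×W).  The un-padded region is returned untouched.
    """
    if amount < 0:
        raise ValueError(f"pad amount must be >= 0, got {amount}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))
    l = r = t = b = 0
    if direction == "left":
        l = amount
    elif direction == "right":
        r = amount
    elif direction == "top":
        t = amount
    else:
        b = amount
    return x.pad2d(l, r, t, b)


class PConv(nn.Module):
    """Four directional asymmetric-padded CBS branches plus a 2×2 fusion CBS.

    Parameters
    ----------
    in_channels, out_channels:
        ``out_channels`` must be divisible by 4 (one quarter per branch).
    stride:
        Spatial stride, carried by the branch convolutions; the fusion conv
        is stride 1 and preserves size.
    branch_kernel:
        Length k of the asymmetric branch kernels (1×k horizontal, k×1
        vertical); each branch pads by k−1 on its named side.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 branch_kernel: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if out_channels % 4:
            raise ValueError("out_channels must be divisible by 4")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.branch_kernel = branch_kernel
        k = branch_kernel
        cb = out_channels // 4
        # horizontal kernels for left/right, vertical for top/bottom
        self.branch_left = ConvBNAct(in_channels, cb, (1, k), stride, p=0, rng=rng)
        self.branch_right = ConvBNAct(in_channels, cb, (1, k), stride, p=0, rng=rng)
        self.branch_top = ConvBNAct(in_channels, cb, (k, 1), stride, p=0, rng=rng)
        self.branch_bottom = ConvBNAct(in_channels, cb, (k, 1), stride, p=0, rng=rng)
        # 2x2 fusion, padded (l,r,t,b)=(0,1,0,1) to preserve spatial size
        self.fuse = ConvBNAct(out_channels, out_channels, 2, 1, p=(0, 1, 0, 1), rng=rng)

    def _branches(self, x: Tensor) -> Tensor:
        if x.shape[-3] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[-3]}")
        pad = self.branch_kernel - 1
        outs = [
            self.branch_left(directional_pad(x, "left", pad)),
            self.branch_right(directional_pad(x, "right", pad)),
            self.branch_top(directional_pad(x, "top", pad)),
            self.branch_bottom(directional_pad(x, "bottom", pad)),
        ]
        return nn.concatenate(outs, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(self._branches(x))
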