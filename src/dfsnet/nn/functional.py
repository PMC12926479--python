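"""Convolution, pooling and resampling primitives with custom backward passes.

Convolution is evaluated by im2col + BLAS matmul (the fast path on CPU);
depthwise convolution takes a kernel-position loop instead, which avoids
materialising the huge im2col buffer when groups == channels.  A process-wide
counter can be armed to record the multiply–accumulate cost of every
convolution executed, which is how the model profiler measures FLOPs.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, is_grad_enabled

__all__ = ["conv2d", "max_pool2d", "upsample_nearest2d", "flop_counter", "conv2d_macs"]

# -- FLOP accounting ----------------------------------------------------------

_flop_ctx: list[dict] = []


@contextlib.contextmanager
def flop_counter():
    """Collect MACs of every convolution run inside the context.

    Yields a dict whose ``"macs"`` entry holds the running multiply–accumulate
    count.  FLOPs follow the usual profiler convention of 2 ops per MAC.
    """
    ctx = {"macs": 0}
    _flop_ctx.append(ctx)
    try:
        yield ctx
    finally:
        _flop_ctx.pop()


def _record_macs(n: int) -> None:
    for ctx in _flop_ctx:
        ctx["macs"] += int(n)


def conv2d_macs(c_in: int, c_out: int, kh: int, kw: int, oh: int, ow: int, groups: int = 1) -> int:
    """Analytic multiply–accumulate count of one convolution layer."""
    return (c_in // groups) * c_out * kh * kw * oh * ow


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _quad_padding(padding):
    """Normalize padding to (left, right, top, bottom)."""
    if isinstance(padding, int):
        return (padding, padding, padding, padding)
    padding = tuple(padding)
    if len(padding) == 2:  # (ph, pw)
        ph, pw = padding
        return (pw, pw, ph, ph)
    if len(padding) == 4:
        return padding
    raise ValueError(f"bad padding spec {padding!r}")


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Strided view (B, C, KH, KW, OH, OW) of the padded input."""
    b, c, hp, wp = xp.shape
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    sb, sc, sy, sx = xp.strides
    view = as_strided(
        xp,
        shape=(b, c, kh, kw, oh, ow),
        strides=(sb, sc, sy, sx, sy * sh, sx * sw),
        writeable=False,
    )
    return view, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride=1,
           padding=0, groups: int = 1) -> Tensor:
    """2-D cross-correlation over NCHW input.

    ``padding`` may be an int, an (ph, pw) pair, or an asymmetric
    (left, right, top, bottom) quadruple.
    """
    b, c, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c != c_in_g * groups:
        raise ValueError(f"input has {c} channels, weight expects {c_in_g * groups}")
    if c_out % groups:
        raise ValueError("out_channels must be divisible by groups")
    sh, sw = _pair(stride)
    pl, pr, pt, pb = _quad_padding(padding)

    xp = np.pad(x.data, [(0, 0), (0, 0), (pt, pb), (pl, pr)])
    depthwise = groups == c and c_in_g == 1

    if depthwise:
        oh = (xp.shape[2] - kh) // sh + 1
        ow = (xp.shape[3] - kw) // sw + 1
        out_data = np.zeros((b, c_out, oh, ow), dtype=x.dtype)
        mult = c_out // c  # usually 1
        wdat = weight.data
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
                if mult == 1:
                    out_data += sl * wdat[:, 0, i, j][None, :, None, None]
                else:
                    for m in range(mult):
                        out_data[:, m::mult] += sl * wdat[m::mult, 0, i, j][None, :, None, None]
        cols = None
    else:
        view, oh, ow = _im2col(xp, kh, kw, sh, sw)
        if groups == 1:
            cols = np.ascontiguousarray(view).reshape(b, c * kh * kw, oh * ow)
            wmat = weight.data.reshape(c_out, c * kh * kw)
            out_data = np.matmul(wmat, cols).reshape(b, c_out, oh, ow)
        else:
            cg = c // groups
            og = c_out // groups
            colsg = np.ascontiguousarray(view).reshape(b, groups, cg * kh * kw, oh * ow)
            wmat = weight.data.reshape(groups, og, cg * kh * kw)
            out_data = np.einsum("gok,bgkl->bgol", wmat, colsg).reshape(b, c_out, oh, ow)
            cols = colsg
        if not (is_grad_enabled() and (x.requires_grad or weight.requires_grad)):
            cols = None

    _record_macs(conv2d_macs(c, c_out, kh, kw, oh, ow, groups) * b)

    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if depthwise:
            wdat = weight.data
            mult = c_out // c
            if weight.requires_grad:
                gw = np.zeros_like(wdat)
                for i in range(kh):
                    for j in range(kw):
                        sl = xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
                        if mult == 1:
                            gw[:, 0, i, j] = (g * sl).sum(axis=(0, 2, 3))
                        else:
                            for m in range(mult):
                                gw[m::mult, 0, i, j] = (g[:, m::mult] * sl).sum(axis=(0, 2, 3))
                weight._accum(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        if mult == 1:
                            contrib = g * wdat[:, 0, i, j][None, :, None, None]
                        else:
                            contrib = sum(
                                g[:, m::mult] * wdat[m::mult, 0, i, j][None, :, None, None]
                                for m in range(mult)
                            )
                        gxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += contrib
                x._accum(gxp[:, :, pt : pt + h, pl : pl + w])
            return
        g2 = g.reshape(b, groups, c_out // groups, oh * ow) if groups > 1 else g.reshape(b, c_out, oh * ow)
        if weight.requires_grad:
            if groups == 1:
                gw = np.einsum("bol,bkl->ok", g2, cols).reshape(weight.shape)
            else:
                gw = np.einsum("bgol,bgkl->gok", g2, cols).reshape(weight.shape)
            weight._accum(gw)
        if x.requires_grad:
            if groups == 1:
                wmat = weight.data.reshape(c_out, c * kh * kw)
                gcols = np.matmul(wmat.T, g2)  # (b, c*kh*kw, L)
                gcols = gcols.reshape(b, c, kh, kw, oh, ow)
            else:
                cg = c // groups
                wmat = weight.data.reshape(groups, c_out // groups, cg * kh * kw)
                gcols = np.einsum("gok,bgol->bgkl", wmat, g2)
                gcols = gcols.reshape(b, c, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += gcols[:, :, i, j]
            x._accum(gxp[:, :, pt : pt + h, pl : pl + w])

    return Tensor._make(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel_size: int, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling with -inf padding (so padded cells never win)."""
    k = kernel_size
    s = stride if stride is not None else k
    b, c, h, w = x.shape
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)],
                constant_values=-np.inf)
    view, oh, ow = _im2col(xp, k, k, s, s)
    win = np.ascontiguousarray(view).reshape(b, c, k * k, oh, ow)
    idx = win.argmax(axis=2)
    out_data = np.take_along_axis(win, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gwin = np.zeros((b, c, k * k, oh, ow), dtype=g.dtype)
        np.put_along_axis(gwin, idx[:, :, None], g[:, :, None], axis=2)
        gwin = gwin.reshape(b, c, k, k, oh, ow)
        gxp = np.zeros_like(xp, dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += gwin[:, :, i, j]
        x._accum(gxp[:, :, padding : padding + h, padding : padding + w])

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    b, c, h, w = x.shape

    def backward(g):
        x._accum(g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)
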