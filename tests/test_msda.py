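"""MSDA block: split semantics, residual identities, edge-response
behaviour of DEE, and the composed block against its own sub-ops."""

import numpy as np
import pytest

from dfsnet import nn
from dfsnet.layers.common import C3k2
from dfsnet.layers.msda import DEE, MSDA, C3k2MSDA, MultiScaleBranch, msda_split
from dfsnet.nn import Tensor


@pytest.mark.parametrize("channels,ratio,expect", [(64, 0.5, (32, 32)), (6, 0.5, (3, 3))])
def test_split_channel_allocation(channels, ratio, expect, rng):
    f0 = Tensor(rng.normal(size=(1, channels, 4, 4)))
    fm, fa = msda_split(f0, ratio)
    assert (fm.shape[1], fa.shape[1]) == expect


def test_split_concat_roundtrip(rng):
    f0 = Tensor(rng.normal(size=(2, 10, 3, 3)))
    fm, fa = msda_split(f0, 0.5)
    assert np.array_equal(nn.concatenate([fm, fa], axis=1).data, f0.data)


@pytest.mark.parametrize("ratio", [0.0, 1.0, -0.2, 1.5])
def test_split_ratio_validation(ratio):
    with pytest.raises(ValueError):
        msda_split(Tensor(np.zeros((1, 4, 2, 2))), ratio)


def test_multiscale_branch_residual_identity(rng):
    ms = MultiScaleBranch(4, rng=rng)
    for _, p in ms.named_parameters():
        p.data[:] = 0.0
    x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    assert np.allclose(ms(Tensor(x)).data, x)


def test_multiscale_branch_composition_oracle(rng):
    """Forward equals F_m + WT2(GELU(WT1(F_m))) built from the sub-ops."""
    ms = MultiScaleBranch(3, rng=rng)
    x = Tensor(rng.normal(size=(1, 3, 8, 8)))
    manual = x + ms.wt2(ms.wt1(x).gelu())
    assert np.allclose(ms(x).data, manual.data, atol=1e-10)


def test_dee_constant_input_passthrough(rng):
    dee = DEE(8, rng=rng)
    fa = Tensor(np.full((1, 8, 6, 6), 2.5, dtype=np.float32))
    fd, fatt = dee.edge_response(fa)
    assert np.allclose(fd.data, 0.0, atol=1e-5)
    assert np.allclose(fatt.data, 0.0, atol=1e-5)
    assert np.allclose(dee(fa).data, fa.data, atol=1e-5)


def test_dee_gate_bounds(rng):
    dee = DEE(4, rng=rng)
    fa = Tensor(rng.normal(size=(1, 4, 5, 5)))  # float64: sigmoid stays open
    fd, _ = dee.edge_response(fa)
    a = dee.gate(fd).sigmoid().data
    assert np.all(a > 0.0) and np.all(a < 1.0)


def test_dee_vertical_step_edge_localised(rng):
    """Horizontal-difference kernel fires on the edge column; the vertical
    branch sees a constant half and stays silent."""
    dee = DEE(2, rng=rng)
    img = np.zeros((1, 2, 8, 8), dtype=np.float32)
    img[:, :, :, 4:] = 1.0  # vertical step edge at column 4
    fd, _ = dee.edge_response(Tensor(img))
    # interior rows avoid the zero-padding artefacts at the image border
    resp = np.abs(fd.data[0, 0][1:7, :])
    edge_mass = resp[:, 3:5].sum()
    assert edge_mass > 0.9 * resp.sum()  # concentrated at the step columns
    on_cols = resp.sum(axis=0)
    assert on_cols[0] == pytest.approx(0.0, abs=1e-5)
    assert on_cols[7] == pytest.approx(0.0, abs=1e-5)


def test_dee_response_monotonic_in_ramp_slope(rng):
    dee = DEE(2, rng=rng)
    means = []
    for s in [0.5, 1.0, 2.0, 4.0]:
        ramp = np.tile(np.arange(8, dtype=np.float32) * s, (8, 1))
        fa = Tensor(np.stack([ramp, ramp])[None])
        fd, _ = dee.edge_response(fa)
        means.append(np.abs(fd.data).mean())
    assert all(b >= a for a, b in zip(means, means[1:]))


def test_dee_odd_channels_rejected():
    with pytest.raises(ValueError):
        DEE(5)


def test_msda_outer_residual_identity(rng):
    msda = MSDA(8, rng=rng)
    msda.in_proj.weight.data[:] = 0.0
    msda.out_proj.weight.data[:] = 0.0
    x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
    assert np.allclose(msda(Tensor(x)).data, x, atol=1e-6)


def test_msda_shape_preservation(rng):
    msda = MSDA(16, rng=rng)
    y = msda(Tensor(rng.normal(size=(2, 16, 20, 20)).astype(np.float32)))
    assert y.shape == (2, 16, 20, 20)


def test_msda_forward_equals_manual_composition(rng):
    msda = MSDA(8, rng=rng)
    x = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
    f0 = msda.in_proj(x)
    fm, fa = f0[:, : msda.cm], f0[:, msda.cm :]
    manual = x + msda.out_proj(nn.concatenate([msda.ms(fm), msda.dee(fa)], axis=1))
    assert np.allclose(msda(x).data, manual.data, atol=1e-6)


def test_c3k2msda_zeroed_side_path_matches_fused_plain_path(rng):
    blk = C3k2MSDA(8, 16, msda_width=4, rng=rng)
    x = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    blk.eval()
    full = blk(x).data
    # zero the MSDA side branch: output must equal fuse(C3k2(x) || 0)
    for _, p in blk.reduce.named_parameters():
        p.data[:] = 0.0
    for _, p in blk.msda.named_parameters():
        p.data[:] = 0.0
    side_zero = blk(x).data
    main = blk.c3k2(x)
    manual = blk.fuse(nn.concatenate(
        [main, Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))], axis=1)).data
    assert np.allclose(side_zero, manual, atol=1e-6)
    assert not np.allclose(full, side_zero)


def test_c3k2msda_has_more_parameters_than_plain(rng):
    plain = C3k2(32, 64, rng=rng)
    enriched = C3k2MSDA(32, 64, rng=rng)
    assert enriched.num_parameters() > plain.num_parameters()
    # the plain path inside is structurally identical
    assert enriched.c3k2.num_parameters() == plain.num_parameters()


def test_residual_vanishes_with_branch_weights(rng):
    """Scaling branch weights toward zero drives ||out - in|| to zero."""
    x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
    norms = []
    for scale in (1.0, 0.1, 0.01):
        msda = MSDA(8, rng=np.random.default_rng(5))
        for _, p in msda.named_parameters():
            p.data = p.data * scale
        norms.append(float(np.linalg.norm(msda(Tensor(x)).data - x)))
    assert norms[0] > norms[1] > norms[2]
    assert norms[2] < 1e-2
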