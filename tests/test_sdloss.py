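"""Scale-based dynamic loss: worked values, algebraic identities, ranges,
monotonicity, and gradient direction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfsnet.nn import Tensor
from dfsnet.sdloss import (
    Box,
    SDParams,
    bbox_loc_loss,
    bbox_scale_loss,
    box_iou,
    dynamic_weights,
    mask_iou,
    mask_scale_loss,
    polar_stats,
    scale_factor,
    sdb_loss,
    sdb_loss_batch,
    sdm_loss,
    total_loss,
)

BP = Box(0, 0, 10, 10)
BGT = Box(5, 5, 15, 15)


def rasterized_iou(a: Box, b: Box, res: int = 400) -> float:
    """Fine-grid counting oracle for IoU."""
    xs = np.linspace(min(a.x1, b.x1), max(a.x2, b.x2), res)
    ys = np.linspace(min(a.y1, b.y1), max(a.y2, b.y2), res)
    gx, gy = np.meshgrid(xs, ys)
    ina = (gx >= a.x1) & (gx <= a.x2) & (gy >= a.y1) & (gy <= a.y2)
    inb = (gx >= b.x1) & (gx <= b.x2) & (gy >= b.y1) & (gy <= b.y2)
    return (ina & inb).sum() / (ina | inb).sum()


class TestBoxIoU:
    def test_identical_boxes(self):
        assert box_iou(BP, BP) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou(BP, Box(20, 20, 30, 30)) == 0.0

    def test_worked_pair_against_rasterization_oracle(self):
        val = box_iou(BP, BGT)
        assert val == pytest.approx(25 / 175, abs=1e-12)
        assert val == pytest.approx(rasterized_iou(BP, BGT), abs=5e-3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(5, 5, 5, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        g = np.random.default_rng(seed)
        a = Box(*np.sort(g.uniform(0, 20, 2)).tolist(), *(np.sort(g.uniform(0, 20, 2)) + 21).tolist())
        a = Box(a.x1, a.y2 - 21, a.x2, a.y1 + 21) if False else a
        x1, x2 = np.sort(g.uniform(0, 50, 2) + [0, 1])
        y1, y2 = np.sort(g.uniform(0, 50, 2) + [0, 1])
        b = Box(x1, y1, x2 + 1e-3, y2 + 1e-3)
        v1, v2 = box_iou(a, b), box_iou(b, a)
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert 0.0 <= v1 <= 1.0


class TestScaleAndWeights:
    def test_bbox_scale_loss_endpoints(self):
        assert bbox_scale_loss(BP, BP, gamma=0.0) == 0.0
        assert bbox_scale_loss(BP, Box(20, 20, 30, 30), gamma=0.25) == 1.25
        assert bbox_scale_loss(BP, BGT, gamma=0.0) == pytest.approx(6 / 7, abs=1e-12)

    def test_loc_loss_closed_form(self):
        # centres (5,5) and (10,10); enclosing box (0,0,15,15)
        assert bbox_loc_loss(BP, BGT) == pytest.approx(50 / 450, abs=1e-12)

    def test_loc_loss_concentric_zero(self):
        assert bbox_loc_loss(Box(2, 2, 8, 8), Box(0, 0, 10, 10)) == 0.0

    def test_loc_loss_translation_invariance(self):
        base = bbox_loc_loss(BP, BGT)
        shifted = bbox_loc_loss(
            Box(BP.x1 + 7, BP.y1 - 3, BP.x2 + 7, BP.y2 - 3),
            Box(BGT.x1 + 7, BGT.y1 - 3, BGT.x2 + 7, BGT.y2 - 3),
        )
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_scale_factor_worked_values(self):
        s = SDParams(theta=1.0)
        assert scale_factor(81.0, s) == pytest.approx(0.5)
        assert scale_factor(8.1, s) == pytest.approx(0.05)

    def test_scale_factor_clamped_at_delta(self):
        s = SDParams(theta=32.0)
        assert scale_factor(10_000.0, s) == 0.5

    def test_dynamic_weights_worked_values(self):
        assert dynamic_weights(0.5, 0.5) == (1.0, 1.0)
        b1, b2 = dynamic_weights(0.05, 0.5)
        assert (b1, b2) == (pytest.approx(0.55), pytest.approx(1.45))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 0.5))
    def test_weight_sum_identity(self, beta3):
        b1, b2 = dynamic_weights(beta3, 0.5)
        assert b1 + b2 == pytest.approx(2.0, abs=1e-12)
        assert 0.5 <= b1 <= 1.0 and 1.0 <= b2 <= 1.5

    def test_dynamic_weights_validation(self):
        with pytest.raises(ValueError):
            dynamic_weights(0.6, 0.5)
        with pytest.raises(ValueError):
            dynamic_weights(0.0, 0.5)


class TestSDB:
    def test_identical_boxes_zero(self):
        assert sdb_loss(BP, BP, SDParams(gamma=0.0)) == pytest.approx(0.0)

    def test_worked_chain(self):
        # area(gt)=100 >= 81 -> beta3=0.5, beta1=beta2=1 -> 6/7 + 1/9
        val = sdb_loss(BP, BGT, SDParams(theta=1.0, gamma=0.0))
        assert val == pytest.approx(6 / 7 + 1 / 9, abs=1e-12)

    def test_loss_decreases_approaching_target(self):
        s = SDParams()
        losses = [
            sdb_loss(Box(t, t, t + 10, t + 10), BGT, s)
            for t in np.linspace(0, 5, 11)
        ]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_small_target_emphasis(self):
        """At fixed IoU and centre offset, beta2 never grows with gt area."""
        s = SDParams(theta=1.0)
        b2s = []
        for side in (3, 6, 9, 15, 30):
            gt = Box(0, 0, side, side)
            beta3 = scale_factor(gt, s)
            b2s.append(dynamic_weights(beta3, s.delta)[1])
        assert all(b <= a for a, b in zip(b2s, b2s[1:]))
        assert b2s[0] > b2s[-1]  # strictly more centre emphasis for 3x3 than 30x30

    def test_gradient_points_toward_target_center(self):
        """Finite-difference direction check on the batched form."""
        pred = Tensor(np.array([[0.0, 0.0, 10.0, 10.0]]), requires_grad=True)
        gt = np.array([[5.0, 5.0, 15.0, 15.0]])
        sdb_loss_batch(pred, gt, SDParams(), theta=1.0).sum().backward()
        g = pred.grad[0]
        # moving x1,x2 (and y1,y2) jointly toward +x reduces the loss:
        # gradient wrt both edges must be negative in sum
        assert g[0] + g[2] < 0 and g[1] + g[3] < 0

    def test_batched_matches_scalar(self, rng):
        s = SDParams(theta=8.0)
        preds, gts = [], []
        for _ in range(12):
            x1, y1 = rng.uniform(0, 20, 2)
            preds.append([x1, y1, x1 + rng.uniform(1, 15), y1 + rng.uniform(1, 15)])
            x1, y1 = rng.uniform(0, 20, 2)
            gts.append([x1, y1, x1 + rng.uniform(1, 15), y1 + rng.uniform(1, 15)])
        batch = sdb_loss_batch(Tensor(np.array(preds)), np.array(gts), s, theta=8.0).data
        scalar = [sdb_loss(Box(*p), Box(*g), s) for p, g in zip(preds, gts)]
        assert np.allclose(batch, scalar, atol=1e-9)


class TestMaskBranch:
    def test_mask_iou_examples(self):
        a = {(0, 0), (1, 0), (2, 0)}
        assert mask_iou(a, a) == 1.0
        assert mask_iou(a, {(5, 5)}) == 0.0
        mp = {(i, 0) for i in range(4)} | {(0, 1), (1, 1), (2, 1)}
        mgt = {(0, 1), (1, 1), (2, 1)} | {(i, 2) for i in range(5)}
        assert len(mp & mgt) == 3 and len(mp | mgt) == 12
        assert mask_iou(mp, mgt) == 0.25

    def test_mask_scale_loss_values(self):
        assert mask_scale_loss(1.0, 1.0) == 0.0
        assert mask_scale_loss(0.0, 0.7) == 1.0
        assert mask_scale_loss(0.25, 0.8) == pytest.approx(0.8)

    def test_polar_stats_single_pixel_at_pole(self):
        d, a = polar_stats({(3, 4)}, (3.0, 4.0))
        assert d == 0.0 and a == 0.0

    def test_polar_stats_symmetric_cross(self):
        r = 5
        m = {(r, 0), (-r, 0), (0, r), (0, -r)}
        d, a = polar_stats(m, (0.0, 0.0))
        assert d == pytest.approx(r)
        assert a == 0.0  # vanishing resultant -> convention

    def test_polar_rotation_equivariance(self):
        pts = [(3, 1), (5, 2), (4, -1), (6, 0)]
        _, a0 = polar_stats(set(pts), (0.0, 0.0))
        ang = math.pi / 3
        rot = {(x * math.cos(ang) - y * math.sin(ang), x * math.sin(ang) + y * math.cos(ang))
               for x, y in pts}
        _, a1 = polar_stats(rot, (0.0, 0.0))
        assert (a1 - a0) % (2 * math.pi) == pytest.approx(ang, abs=1e-9)

    def test_sdm_identical_masks_zero(self):
        m = {(x, y) for x in range(3) for y in range(3)}
        assert sdm_loss(m, m, SDParams(p=1.0)) == pytest.approx(0.0)

    def test_sdm_angle_gap_term(self):
        """Equal radii, angle gap pi/2 -> L_ML = 1 exactly."""
        s = SDParams(p=1.0, theta=1.0)
        mgt = {(5, 0)}
        mp = {(0, 5)}
        pole = (0.0, 0.0)
        val = sdm_loss(mp, mgt, s, pole=pole)
        # L_MS = 1 (disjoint), L_ML = 0 (radius) + 4*(pi/2)^2/pi^2 = 1
        beta3 = scale_factor(1.0, s)
        b1m, b2m = 1.0 + 0.5 - beta3, 1.0 - 0.5 + beta3
        assert val == pytest.approx(b1m * 1.0 + b2m * 1.0, abs=1e-9)

    def test_sdm_radius_ratio_term(self):
        s = SDParams(p=1.0, theta=1.0)
        mgt = {(4, 0)}
        mp = {(8, 0)}  # same angle, double radius -> L_ML = 0.5
        beta3 = scale_factor(1.0, s)
        b1m, b2m = 1.5 - beta3, 0.5 + beta3
        val = sdm_loss(mp, mgt, s, pole=(0.0, 0.0))
        assert val == pytest.approx(b1m * 1.0 + b2m * 0.5, abs=1e-9)

    def test_sdm_weight_ranges(self):
        s = SDParams(theta=1.0)
        for npix in (1, 40, 200):
            mgt = {(i, 0) for i in range(npix)}
            beta3 = scale_factor(float(npix), s)
            b1m, b2m = 1.0 + s.delta - beta3, 1.0 - s.delta + beta3
            assert 1.0 <= b1m < 1.5 or b1m == pytest.approx(1.0)
            assert 0.5 < b2m <= 1.0
            assert b1m + b2m == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_iou(set(), set())
        with pytest.raises(ValueError):
            sdm_loss(set(), {(0, 0)}, SDParams())


class TestTotalLoss:
    def _setup(self, rng, n=6, nc=4):
        logits = Tensor(rng.normal(size=(n, nc)), requires_grad=True)
        boxes = Tensor(np.abs(rng.normal(size=(n, 4))) * 5, requires_grad=False)
        b = boxes.data
        boxes = Tensor(np.stack([b[:, 0], b[:, 1], b[:, 0] + b[:, 2] + 1, b[:, 1] + b[:, 3] + 1], axis=1))
        return logits, boxes

    def test_perfect_predictions_zero_regression(self, rng):
        logits, boxes = self._setup(rng)
        scores = np.zeros((6, 4))
        scores[0, 1] = 1.0
        fg = np.zeros(6, dtype=bool)
        fg[0] = True
        tb = np.zeros((6, 4))
        tb[0] = boxes.data[0]
        out = total_loss(logits, boxes, scores, tb, fg, SDParams(gamma=0.0), theta=1.0)
        assert out["reg"] == pytest.approx(0.0, abs=1e-9)

    def test_lambda_scales_regression_linearly(self, rng):
        logits, boxes = self._setup(rng)
        scores = np.zeros((6, 4))
        scores[[0, 2], [1, 3]] = 0.8
        fg = np.zeros(6, dtype=bool)
        fg[[0, 2]] = True
        tb = np.zeros((6, 4))
        tb[0] = boxes.data[0] + 2.0
        tb[2] = boxes.data[2] + 3.0
        lo1 = total_loss(logits, boxes, scores, tb, fg, SDParams(lam=7.5))
        lo2 = total_loss(logits, boxes, scores, tb, fg, SDParams(lam=15.0))
        reg1 = float(lo1["loss"].data) - lo1["cls"]
        reg2 = float(lo2["loss"].data) - lo2["cls"]
        assert reg2 == pytest.approx(2.0 * reg1, rel=1e-9)

    def test_batch_equals_sum_of_instances(self, rng):
        """3-instance fixture: the regression term decomposes per match."""
        logits, boxes = self._setup(rng, n=5)
        scores = np.zeros((5, 4))
        fg = np.zeros(5, dtype=bool)
        tb = np.zeros((5, 4))
        weights = [0.9, 0.4, 0.7]
        for row, wgt in zip((0, 1, 3), weights):
            fg[row] = True
            scores[row, row % 4] = wgt
            tb[row] = boxes.data[row] + row + 1.0
        s = SDParams(lam=1.0)
        out = total_loss(logits, boxes, scores, tb, fg, s, theta=1.0)
        norm = scores.sum()
        expected = sum(
            (w / norm) * float(sdb_loss_batch(boxes[r : r + 1], tb[r : r + 1], s, theta=1.0).data[0])
            for r, w in zip((0, 1, 3), weights)
        )
        assert out["reg"] == pytest.approx(expected, rel=1e-9)

    def test_no_matches_classification_only(self, rng):
        logits, boxes = self._setup(rng)
        out = total_loss(logits, boxes, np.zeros((6, 4)), np.zeros((6, 4)),
                         np.zeros(6, dtype=bool), SDParams())
        assert out["reg"] == 0.0
        assert float(out["loss"].data) == pytest.approx(out["cls"])

    def test_mask_pairs_add_sdm_term(self, rng):
        logits, boxes = self._setup(rng)
        masks = [({(0, 0), (1, 0)}, {(0, 0), (1, 0)})]
        out = total_loss(logits, boxes, np.zeros((6, 4)), np.zeros((6, 4)),
                         np.zeros(6, dtype=bool), SDParams(p=1.0), mask_pairs=masks)
        assert out["mask"] == pytest.approx(0.0, abs=1e-9)
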