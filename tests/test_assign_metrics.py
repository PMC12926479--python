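"""Assignment, NMS and evaluation against brute-force oracles."""

import itertools

import numpy as np
import pytest

from dfsnet.assign import assign_targets, pairwise_iou
from dfsnet.metrics import Detection, GroundTruth, average_precision, evaluate
from dfsnet.predict import nms


def brute_force_assign(cls_probs, pred_boxes, centers, gt_boxes, gt_classes,
                       topk=10, alpha=0.5, beta=6.0):
    """Loop/sort reference for the task-aligned assigner."""
    n, m = len(pred_boxes), len(gt_boxes)
    iou = np.zeros((n, m))
    align = np.zeros((n, m))
    inside = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            iou[i, j] = pairwise_iou(pred_boxes[i:i+1], gt_boxes[j:j+1])[0, 0]
            gx1, gy1, gx2, gy2 = gt_boxes[j]
            inside[i, j] = gx1 < centers[i, 0] < gx2 and gy1 < centers[i, 1] < gy2
            if inside[i, j]:
                align[i, j] = cls_probs[i, gt_classes[j]] ** alpha * iou[i, j] ** beta
    chosen = np.zeros((n, m), dtype=bool)
    for j in range(m):
        order = sorted(range(n), key=lambda i: (-align[i, j], i))
        picked = [i for i in order if inside[i, j] and align[i, j] > 0][:topk]
        for i in picked:
            chosen[i, j] = True
    matches = set()
    for i in range(n):
        js = np.nonzero(chosen[i])[0]
        if len(js) == 0:
            continue
        if len(js) > 1:
            js = [js[int(np.argmax(iou[i, js]))]]
            if not chosen[i, js[0]]:
                continue
        matches.add((i, int(js[0])))
    return matches


def brute_force_nms(boxes, scores, thr):
    """Exhaustive pairwise suppression reference."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    keep = []
    for i in order:
        ok = True
        for k in keep:
            if pairwise_iou(boxes[i:i+1], boxes[k:k+1])[0, 0] > thr:
                ok = False
                break
        if ok:
            keep.append(i)
    return keep


class TestAssign:
    def test_single_perfect_candidate_matched(self):
        probs = np.full((1, 4), 0.9)
        boxes = np.array([[0.0, 0.0, 10.0, 10.0]])
        centers = np.array([[5.0, 5.0]])
        res = assign_targets(probs, boxes, centers, boxes.copy(), np.array([2]), nc=4)
        assert res.fg_mask[0]
        assert res.gt_index[0] == 0
        assert res.target_scores[0, 2] > 0

    def test_zero_iou_candidate_unmatched(self):
        probs = np.full((1, 4), 0.9)
        boxes = np.array([[0.0, 0.0, 2.0, 2.0]])
        centers = np.array([[50.0, 50.0]])
        gt = np.array([[40.0, 40.0, 60.0, 60.0]])
        res = assign_targets(probs, boxes, centers, gt, np.array([0]), nc=4)
        assert not res.fg_mask.any()  # centre inside but IoU 0 -> alignment 0

    def test_empty_gt_returns_background(self):
        res = assign_targets(np.zeros((5, 4)), np.zeros((5, 4)),
                             np.zeros((5, 2)), np.zeros((0, 4)),
                             np.zeros(0, dtype=int), nc=4)
        assert not res.fg_mask.any()

    def test_matches_brute_force_on_random_fixture(self, rng):
        """3 gts / 10 candidates: identical match set to the loop oracle."""
        n, m, nc = 10, 3, 4
        probs = rng.uniform(0.01, 0.99, size=(n, nc))
        centers = rng.uniform(0, 100, size=(n, 2))
        pred = np.concatenate([centers - rng.uniform(2, 12, (n, 2)),
                               centers + rng.uniform(2, 12, (n, 2))], axis=1)
        g1 = rng.uniform(0, 80, size=(m, 2))
        gt = np.concatenate([g1, g1 + rng.uniform(15, 40, (m, 2))], axis=1)
        gcls = rng.integers(0, nc, m)
        res = assign_targets(probs, pred, centers, gt, gcls, nc=nc, topk=4)
        got = {(i, int(res.gt_index[i])) for i in np.nonzero(res.fg_mask)[0]}
        want = brute_force_assign(probs, pred, centers, gt, gcls, topk=4)
        assert got == want

    def test_target_score_normalisation(self, rng):
        """Max target score of a gt equals its best candidate IoU."""
        probs = rng.uniform(0.3, 0.9, size=(6, 2))
        gt = np.array([[10.0, 10.0, 40.0, 40.0]])
        centers = rng.uniform(12, 38, size=(6, 2))
        pred = np.concatenate([centers - 10, centers + 10], axis=1)
        res = assign_targets(probs, pred, centers, gt, np.array([1]), nc=2)
        ious = pairwise_iou(pred, gt)[:, 0]
        assert res.target_scores.max() == pytest.approx(ious[res.fg_mask].max())


class TestNMS:
    def test_duplicate_boxes_keep_higher_confidence(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
        keep = nms(boxes, np.array([0.5, 0.9]), 0.7)
        assert keep == [1]

    def test_matches_exhaustive_oracle_on_fixture(self, rng):
        boxes = []
        for _ in range(6):
            x, y = rng.uniform(0, 30, 2)
            boxes.append([x, y, x + rng.uniform(5, 20), y + rng.uniform(5, 20)])
        boxes = np.array(boxes)
        scores = rng.uniform(0.1, 0.95, 6)
        for thr in (0.3, 0.5, 0.7):
            assert nms(boxes, scores, thr) == brute_force_nms(boxes, scores, thr)


class TestEvaluate:
    def _gts(self):
        return [
            GroundTruth((0, 0, 10, 10), 0, 0),
            GroundTruth((20, 20, 35, 35), 0, 0),
            GroundTruth((50, 50, 70, 70), 1, 0),
        ]

    def test_perfect_detections(self):
        dets = [Detection(g.box, g.cls, 1.0, g.image_id) for g in self._gts()]
        rep = evaluate(dets, self._gts())
        assert rep.precision == 1.0 and rep.recall == 1.0
        assert rep.map50 == 1.0 and rep.map50_95 == 1.0

    def test_no_detections(self):
        rep = evaluate([], self._gts())
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.map50 == 0.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([Detection((0, 0, 5, 5), 7, 0.9, 0)], self._gts(), nc=4)

    def test_five_dets_three_gts_vs_bruteforce(self):
        """Hand fixture scored against an exhaustive greedy reference at 0.5."""
        gts = self._gts()
        dets = [
            Detection((0, 0, 10, 10), 0, 0.95, 0),     # TP
            Detection((1, 1, 11, 11), 0, 0.9, 0),      # duplicate -> FP
            Detection((21, 21, 34, 34), 0, 0.8, 0),    # TP
            Detection((49, 51, 69, 71), 1, 0.7, 0),    # TP (class 1)
            Detection((100, 100, 120, 120), 1, 0.6, 0)  # FP
        ]
        rep = evaluate(dets, gts, iou_thresholds=(0.5,))
        # brute force over confidence order per class:
        # class 0: [TP, FP, TP] -> P-R points (1,1/2), (1/2,1/2), (2/3,1)
        # AP0 = mean over 101 recall samples of envelope
        r0 = np.array([0.5, 0.5, 1.0]); p0 = np.array([1.0, 0.5, 2/3])
        r1 = np.array([1.0, 1.0]); p1 = np.array([1.0, 0.5])
        ap0 = average_precision(r0, p0)
        ap1 = average_precision(r1, p1)
        assert rep.ap50[0] == pytest.approx(ap0)
        assert rep.ap50[1] == pytest.approx(ap1)
        assert rep.map50 == pytest.approx((ap0 + ap1) / 2)
        assert rep.confusion == {"tp": 3, "fp": 2, "fn": 0}

    def test_duplicate_lower_confidence_tp_never_raises_ap(self):
        gts = self._gts()
        dets = [Detection(g.box, g.cls, 0.9, 0) for g in gts]
        base = evaluate(dets, gts).map50
        extra = dets + [Detection((0.5, 0.5, 10.5, 10.5), 0, 0.3, 0)]
        dup = evaluate(extra, gts).map50
        assert dup <= base + 1e-12

    def test_bounds_and_threshold_ordering(self, rng):
        gts, dets = [], []
        for i in range(12):
            x, y = rng.uniform(0, 80, 2)
            box = (x, y, x + rng.uniform(8, 25), y + rng.uniform(8, 25))
            cls = int(rng.integers(0, 3))
            gts.append(GroundTruth(box, cls, i % 3))
            jitter = rng.uniform(-4, 4, 4)
            dbox = tuple(np.array(box) + jitter)
            dets.append(Detection(dbox, cls, float(rng.uniform(0.2, 1.0)), i % 3))
        rep = evaluate(dets, gts)
        for v in [rep.precision, rep.recall, rep.map50, rep.map50_95, *rep.ap50.values()]:
            assert 0.0 <= v <= 1.0
        assert rep.map50 >= rep.map50_95
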