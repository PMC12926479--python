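"""Dataset I/O, letterboxing, augmentation and the synthetic generator."""

import numpy as np
import pytest

from dfsnet.data import (
    AugmentConfig,
    LabeledImage,
    SceneSpec,
    augment,
    boxes_cxcywh_to_xyxy,
    easy_spec,
    letterbox,
    make_dataset,
    mosaic,
    read_manifest,
    read_yolo_labels,
    split_counts,
    split_dataset,
    synth_scene,
    write_yolo_labels,
)
from dfsnet.data.synth import FRUIT_BORER, HEALTHY, MELON_THRIPS


class TestYoloIO:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    def test_roundtrip_three_boxes(self, tmp_path):
        annots = [(0, 0.5, 0.5, 0.1, 0.2), (2, 0.25, 0.75, 0.05, 0.05),
                  (3, 0.125, 0.5, 0.5, 0.9)]
        p = tmp_path / "labels.txt"
        write_yolo_labels(annots, p)
        back = read_yolo_labels(p)
        for a, b in zip(annots, back):
            assert a[0] == b[0]
            assert np.allclose(a[1:], b[1:], atol=1e-6)

    def test_line_format(self, tmp_path):
        p = tmp_path / "one.txt"
        p.write_text("0 0.5 0.5 0.1 0.2\n")
        (cid, cx, cy, w, h), = read_yolo_labels(p)
        assert (cid, cx, cy, w, h) == (0, 0.5, 0.5, 0.1, 0.2)

    @pytest.mark.parametrize("bad", ["0 0.5 0.5 0.1", "x 0.5 0.5 0.1 0.2",
                                     "0 1.5 0.5 0.1 0.2", "0 0.5 0.5 0 0.2"])
    def test_malformed_lines_error_with_line_number(self, tmp_path, bad):
        p = tmp_path / "bad.txt"
        p.write_text("1 0.5 0.5 0.2 0.2\n" + bad + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_labels(p)


class TestLetterbox:
    def test_square_is_pure_resize(self):
        img = np.zeros((100, 100, 3), np.uint8)
        out, tf = letterbox(img, 64)
        assert out.shape == (64, 64, 3)
        assert tf.pad_x == 0 and tf.pad_y == 0

    def test_1920x1080_band_arithmetic(self):
        img = np.full((1080, 1920, 3), 200, np.uint8)
        out, tf = letterbox(img, 640)
        assert tf.scale == pytest.approx(1 / 3)
        assert tf.pad_y == 140 and tf.pad_x == 0
        assert np.all(out[:140] == 114) and np.all(out[-140:] == 114)
        assert np.all(out[140:500] == 200)

    def test_transform_inverse_on_corners(self):
        img = np.zeros((300, 500, 3), np.uint8)
        _, tf = letterbox(img, 640)
        pts = np.array([[0.0, 0.0], [500.0, 300.0], [123.0, 45.0]])
        back = tf.invert_points(tf.apply_points(pts))
        assert np.allclose(back, pts, atol=1e-9)


class TestAugment:
    def _item(self, rng):
        return synth_scene(easy_spec(128), rng)

    def test_identity_config_returns_item_unchanged(self, rng):
        item = self._item(rng)
        cfg = AugmentConfig(translate=0, flip_h=0, flip_v=0, scale=0,
                            brightness=0, noise_std=0)
        out = augment(item, cfg, rng)
        assert out is item

    def test_horizontal_flip_maps_cx(self, rng):
        item = self._item(rng)
        cfg = AugmentConfig(translate=0, flip_h=1.0, flip_v=0, scale=0,
                            brightness=0, noise_std=0.0001)
        out = augment(item, cfg, np.random.default_rng(1))
        assert np.allclose(out.boxes[:, 0], 1.0 - item.boxes[:, 0], atol=1e-9)
        assert np.array_equal(out.classes, item.classes)
        assert np.allclose(out.boxes[:, 1:], item.boxes[:, 1:], atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        item = self._item(rng)
        cfg = AugmentConfig()
        a = augment(item, cfg, np.random.default_rng(5))
        b = augment(item, cfg, np.random.default_rng(5))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.boxes, b.boxes)

    def test_boxes_stay_inside_frame(self, rng):
        item = self._item(rng)
        cfg = AugmentConfig(translate=0.3, scale=0.3)
        for seed in range(5):
            out = augment(item, cfg, np.random.default_rng(seed))
            xy = boxes_cxcywh_to_xyxy(out.boxes, 128, 128)
            assert np.all(xy >= -1e-6) and np.all(xy <= 128 + 1e-6)

    def test_box_tracks_lesion_after_flip(self, rng):
        """Geometry consistency: transformed box still covers the lesion."""
        spec = easy_spec(128)
        item = synth_scene(spec, np.random.default_rng(21))
        cfg = AugmentConfig(translate=0, flip_h=1.0, flip_v=0, scale=0,
                            brightness=0, noise_std=0.0001)
        out = augment(item, cfg, np.random.default_rng(0))
        flipped = item.image[:, ::-1]
        # augmented image is the mirrored original (up to noise)
        assert np.abs(out.image.astype(int) - flipped.astype(int)).max() <= 3

    def test_mosaic_boxes_inside_canvas_and_provenance(self, rng):
        items = [synth_scene(easy_spec(128), np.random.default_rng(s)) for s in range(4)]
        out, order = mosaic(items, 256, np.random.default_rng(3))
        assert sorted(order) == [0, 1, 2, 3]
        xy = boxes_cxcywh_to_xyxy(out.boxes, 256, 256)
        assert np.all(xy >= 0) and np.all(xy <= 256)
        # replay: same seed gives the same tile order, pixels prove placement
        out2, order2 = mosaic(items, 256, np.random.default_rng(3))
        assert order2 == order
        assert np.array_equal(out.image, out2.image)
        half = 128
        quads = [(0, 0), (0, half), (half, 0), (half, half)]
        for quad, idx in enumerate(order):
            oy, ox = quads[quad]
            tile, _ = letterbox(items[idx].image, half)
            assert np.array_equal(out.image[oy:oy + half, ox:ox + half], tile)


class TestSynth:
    def test_same_seed_identical_output(self):
        a = synth_scene(SceneSpec(), np.random.default_rng(9))
        b = synth_scene(SceneSpec(), np.random.default_rng(9))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.boxes, b.boxes)
        assert np.array_equal(a.classes, b.classes)

    def test_zero_lesions_only_healthy(self):
        spec = SceneSpec(borer_count=(0, 0), rot_count=(0, 0), thrips_count=(0, 0))
        item = synth_scene(spec, np.random.default_rng(2))
        assert len(item.classes) > 0
        assert np.all(item.classes == HEALTHY)

    def test_lesion_centres_inside_fruit_and_stripe_aspect(self):
        spec = SceneSpec(emit_masks=True)
        for seed in range(8):
            item = synth_scene(spec, np.random.default_rng(seed))
            size = spec.size
            for cls, box, mask in zip(item.classes, item.boxes, item.masks):
                if cls == HEALTHY:
                    continue
                # rasterized-membership: box centre is a drawn lesion region
                cx, cy = box[0] * size, box[1] * size
                xs = np.array([p[0] for p in mask])
                ys = np.array([p[1] for p in mask])
                assert xs.min() - 1 <= cx <= xs.max() + 1
                assert ys.min() - 1 <= cy <= ys.max() + 1
                if cls == MELON_THRIPS:
                    assert box[3] / box[2] >= 4.0

    def test_borer_boxes_exercise_small_target_regime(self):
        """Default borer holes mostly fall under the 81 px² cap."""
        areas = []
        for seed in range(20):
            item = synth_scene(SceneSpec(), np.random.default_rng(seed))
            for cls, box in zip(item.classes, item.boxes):
                if cls == FRUIT_BORER:
                    areas.append(box[2] * 640 * box[3] * 640)
        assert len(areas) > 10
        assert np.median(areas) < 4 * 81  # small-object regime overall
        assert min(areas) < 81

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(thrips_length=(30, 500))
        with pytest.raises(ValueError):
            SceneSpec(thrips_aspect=(2.0, 3.0))


class TestSplit:
    def test_small_exact(self):
        assert split_counts(10, (0.7, 0.2, 0.1)) == (7, 2, 1)

    def test_printed_counts(self):
        assert split_counts(7256, (0.7, 0.2, 0.1)) == (5080, 1451, 725)

    def test_partition_properties(self):
        ids = list(range(101))
        parts = split_dataset(ids, (0.7, 0.2, 0.1), seed=4)
        flat = [i for p in parts for i in p]
        assert sorted(flat) == ids
        assert len(set(flat)) == len(ids)

    def test_bad_ratios(self):
        with pytest.raises(ValueError):
            split_counts(10, (0.5, 0.2, 0.1))


class TestMakeDataset:
    def test_tree_and_manifest(self, tmp_path):
        root = make_dataset(10, easy_spec(96), seed=1, out_dir=tmp_path / "d")
        man = read_manifest(root / "data.yaml")
        assert man["names"] == ["FruitBorer", "FruitRot", "MelonThrips", "Healthy"]
        n_train = len(list((root / "images/train").glob("*.png")))
        n_val = len(list((root / "images/val").glob("*.png")))
        n_test = len(list((root / "images/test").glob("*.png")))
        assert (n_train, n_val, n_test) == (7, 2, 1)
        for img in (root / "images/train").glob("*.png"):
            assert (root / "labels/train" / (img.stem + ".txt")).exists()
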