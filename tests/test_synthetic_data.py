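"""Synthetic canopy generator: determinism, label safety, augmentations,
the 7:2:1 split, and YOLO label I/O."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whorlnet.amccdh import GroundTruthBox
from whorlnet.synthetic_data import (GenerationError, LabeledImage,
                                     LabelParseError, SceneParams,
                                     affine_transform, generate_benchmark_suite,
                                     generate_scene, lighting_transform,
                                     random_occlusion, read_yolo_labels,
                                     split_dataset, write_yolo_labels)

SMALL = dict(image_size=(96, 96), n_targets=3, target_size_range=(12, 24))


class TestGeneration:
    def test_target_count_matches_request(self):
        img = generate_scene(SceneParams(**SMALL, seed=5))
        assert len(img.boxes) == 3
        assert img.pixels.shape == (96, 96, 3) and img.pixels.dtype == np.uint8

    def test_same_seed_byte_identical(self):
        a = generate_scene(SceneParams(**SMALL, seed=9))
        b = generate_scene(SceneParams(**SMALL, seed=9))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert [g.box for g in a.boxes] == [g.box for g in b.boxes]

    def test_different_seed_differs(self):
        a = generate_scene(SceneParams(**SMALL, seed=1))
        b = generate_scene(SceneParams(**SMALL, seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_boxes_normalized_inside_frame(self):
        img = generate_scene(SceneParams(**SMALL, seed=3))
        for g in img.boxes:
            cx, cy, w, h = g.box
            assert 0 <= cx - w / 2 and cx + w / 2 <= 1
            assert 0 <= cy - h / 2 and cy + h / 2 <= 1

    def test_impossible_packing_raises(self):
        with pytest.raises(GenerationError, match="could not place"):
            generate_scene(SceneParams(image_size=(64, 64), n_targets=30,
                                       target_size_range=(40, 60), seed=0))

    def test_background_similarity_reduces_hue_distance(self):
        """High similarity scenes put the whorl hue near the canopy hue."""
        def mean_target_hue_shift(sim):
            p = SceneParams(image_size=(128, 128), n_targets=4,
                            target_size_range=(30, 40),
                            background_similarity=sim,
                            occlusion_fraction_range=(0, 0), seed=11)
            img = generate_scene(p)
            hsv_shift = []
            for g in img.boxes:
                cx, cy, w, h = g.box
                x0, x1 = int((cx - w / 4) * 128), int((cx + w / 4) * 128)
                y0, y1 = int((cy - h / 4) * 128), int((cy + h / 4) * 128)
                patch = img.pixels[y0:y1, x0:x1].astype(float) / 255
                r, gr, b = patch[..., 0], patch[..., 1], patch[..., 2]
                # red-green balance tracks the hue offset away from green
                hsv_shift.append(float(np.mean(r - b)))
            return np.mean(hsv_shift)

        assert mean_target_hue_shift(0.0) > mean_target_hue_shift(1.0)

    def test_benchmark_suite_regime_fractions(self):
        suite = generate_benchmark_suite(9, seed=0, image_size=(96, 96))
        assert len(suite) == 9
        assert sum(s.meta["small_target"] for s in suite) == 3
        assert sum(s.meta["high_similarity"] for s in suite) == 3
        assert sum(s.meta["high_occlusion"] for s in suite) == 3


class TestAugmentations:
    def _img(self, seed=0):
        return generate_scene(SceneParams(**SMALL, seed=seed))

    def test_occlusion_keeps_labels_and_is_seeded(self):
        img = self._img()
        a = random_occlusion(img, np.random.default_rng(4))
        b = random_occlusion(img, np.random.default_rng(4))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert [g.box for g in a.boxes] == [g.box for g in img.boxes]

    def test_zero_patches_identity(self):
        img = self._img()
        out = random_occlusion(img, np.random.default_rng(0), max_patches=0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_lighting_zero_delta_identity(self):
        img = self._img()
        out = lighting_transform(img, 0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_lighting_clips_to_valid_range(self):
        img = self._img()
        bright = lighting_transform(img, 2.0)
        assert bright.pixels.max() == 255 and bright.pixels.min() >= 0

    def test_lighting_monotone_on_midgray(self):
        gray = LabeledImage(np.full((8, 8, 3), 128, np.uint8), [])
        means = [lighting_transform(gray, d).pixels.mean()
                 for d in (-0.2, -0.1, 0.0, 0.1, 0.2)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_affine_identity(self):
        img = self._img()
        out = affine_transform(img, rotation=0.0, translation=(0, 0))
        np.testing.assert_array_equal(out.pixels, img.pixels)
        for a, b in zip(out.boxes, img.boxes):
            np.testing.assert_allclose(a.box, b.box, atol=1e-6)

    def test_rotation_90_square_swaps_box_extents(self):
        # corner-point oracle on a square image: (cx,cy,w,h) maps to a box
        # with swapped extents at the rotated center
        img = LabeledImage(np.zeros((100, 100, 3), np.uint8),
                           [GroundTruthBox((0.3, 0.4, 0.2, 0.1))])
        out = affine_transform(img, rotation=90.0)
        assert len(out.boxes) == 1
        cx, cy, w, h = out.boxes[0].box
        np.testing.assert_allclose((w, h), (0.1, 0.2), atol=1e-6)
        # center rotates CCW about the image center
        np.testing.assert_allclose((cx, cy), (1 - 0.4 - 0.01, 0.3 - 0.01),
                                   atol=0.02)

    def test_translation_out_of_frame_removes_box(self):
        img = LabeledImage(np.zeros((50, 50, 3), np.uint8),
                           [GroundTruthBox((0.1, 0.1, 0.1, 0.1))])
        out = affine_transform(img, translation=(-30, -30))
        assert out.boxes == []

    def test_boxes_always_inside_after_clipping(self):
        img = self._img(seed=8)
        out = affine_transform(img, rotation=37.0, translation=(11, -7))
        for g in out.boxes:
            cx, cy, w, h = g.box
            assert -1e-6 <= cx - w / 2 and cx + w / 2 <= 1 + 1e-6
            assert -1e-6 <= cy - h / 2 and cy + h / 2 <= 1 + 1e-6


class TestSplit:
    def test_published_dataset_size_apportionment(self):
        train, test, val = split_dataset(list(range(2600)), (7, 2, 1), seed=0)
        assert (len(train), len(test), len(val)) == (1820, 520, 260)

    def test_ten_items(self):
        train, test, val = split_dataset(list(range(10)), (7, 2, 1), seed=1)
        assert (len(train), len(test), len(val)) == (7, 2, 1)

    @given(st.integers(0, 200), st.integers(0, 2 ** 16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_partition_property(self, n, seed):
        items = list(range(n))
        parts = split_dataset(items, (7, 2, 1), seed=seed)
        merged = sorted(x for p in parts for x in p)
        assert merged == items
        assert sum(len(p) for p in parts) == n

    def test_seeded_shuffle_reproducible(self):
        a = split_dataset(list(range(50)), seed=3)
        b = split_dataset(list(range(50)), seed=3)
        assert a == b

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            split_dataset([1, 2], (7, 0, 1))


class TestLabelIO:
    def test_format_line(self, tmp_path):
        path = tmp_path / "img.txt"
        write_yolo_labels([GroundTruthBox((0.5, 0.5, 0.1, 0.2))], path)
        assert path.read_text() == "0 0.500000 0.500000 0.100000 0.200000\n"

    def test_empty_file_zero_boxes(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        assert read_yolo_labels(path) == []

    def test_round_trip_hundred_random_boxes(self, tmp_path, rng):
        boxes = [GroundTruthBox(tuple(np.round(rng.uniform(0.05, 0.9, 4), 6)))
                 for _ in range(100)]
        path = tmp_path / "many.txt"
        write_yolo_labels(boxes, path)
        back = read_yolo_labels(path)
        for a, b in zip(boxes, back):
            np.testing.assert_allclose(a.box, b.box, atol=1e-6)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1 0.1\n0 broken\n")
        with pytest.raises(LabelParseError, match=":2:"):
            read_yolo_labels(path)


def test_scene_params_validation():
    with pytest.raises(ValueError, match="target sizes"):
        SceneParams(image_size=(64, 64), target_size_range=(0, 10))
    with pytest.raises(ValueError, match="occlusion"):
        SceneParams(occlusion_fraction_range=(0.9, 0.1))
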