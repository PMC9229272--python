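"""Thresholding and connected-domain labeling, checked against independent
oracles (brute-force Otsu scan, skimage partition agreement)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from skimage.filters import threshold_otsu as skimage_otsu

import rotospin as rs
from rotospin.segment import (
    binarize,
    dilate,
    label_components,
    otsu_threshold,
    remove_small_objects,
    segment_frame,
)


def brute_force_otsu(image: np.ndarray) -> int:
    """Independent O(256*n) oracle: evaluate the between-class variance of
    every candidate threshold directly on the pixel data."""
    img = np.rint(np.asarray(image, dtype=float)).clip(0, 255)
    best_t, best_var = None, -1.0
    n = img.size
    for t in range(255):
        bg = img[img <= t]
        fg = img[img > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size / n, fg.size / n
        var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if var > best_var + 1e-12:  # strict: keeps the smallest argmax
            best_t, best_var = t, var
    return best_t


class TestOtsu:
    def test_bimodal_smallest_tiebreak(self):
        img = np.concatenate([np.full(100, 50), np.full(100, 200)]).reshape(10, 20)
        t = otsu_threshold(img)
        assert t == brute_force_otsu(img) == 50

    def test_two_level_image_partitions_exactly(self):
        img = np.array([[0, 255], [0, 255]], dtype=np.uint8)
        t = otsu_threshold(img)
        mask = binarize(img, t)
        assert set(img[mask == 1]) == {255} and set(img[mask == 0]) == {0}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_images(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (64, 64)).astype(np.uint8)
        assert otsu_threshold(img) == brute_force_otsu(img)

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_agrees_with_skimage(self, seed):
        """Cross-check against the library implementation: the foreground /
        background partition must be identical even if the threshold
        convention (<= vs <) differs."""
        rng = np.random.default_rng(100 + seed)
        img = np.clip(
            rng.normal(80, 15, (48, 48)).round(), 0, 255
        ).astype(np.uint8)
        img[10:20, 10:20] = np.clip(rng.normal(190, 10, (10, 10)).round(), 0, 255)
        ours = img > otsu_threshold(img)
        theirs = img > skimage_otsu(img)
        assert np.array_equal(ours, theirs)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 42, dtype=np.uint8))


class TestBinarize:
    def test_threshold_255_empty_mask(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert binarize(img, 255).sum() == 0

    def test_threshold_zero_on_positive_image_full_mask(self):
        img = np.full((5, 5), 17, dtype=np.uint8)
        assert binarize(img, 0).all()

    def test_partition_counts(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        mask = binarize(img, 128)
        assert mask.sum() + (mask == 0).sum() == img.size

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 300)


class TestMorphology:
    def test_remove_small_objects_keeps_large_only(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[2:5, 2:3] = 1  # area 3
        mask[10:22, 10:20] = 1  # area 120
        out = remove_small_objects(mask, min_area=10)
        assert out.sum() == 120
        assert out[2:5, 2:3].sum() == 0

    def test_min_area_zero_identity(self, rng):
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        assert np.array_equal(remove_small_objects(mask, 0), mask)

    def test_removal_is_monotone(self, rng):
        mask = (rng.random((32, 32)) > 0.6).astype(np.uint8)
        out = remove_small_objects(mask, 5)
        assert np.all(out <= mask)

    def test_exact_min_area_component_kept(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[1:3, 1:4] = 1  # area 6
        assert np.array_equal(remove_small_objects(mask, 6), mask)

    def test_dilate_single_pixel_disk_radius_one(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        out = dilate(mask, 1)
        assert out.sum() == 5  # plus-shape
        assert out[2, 2] and out[1, 2] and out[3, 2] and out[2, 1] and out[2, 3]

    def test_dilate_radius_zero_identity(self, rng):
        mask = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        assert np.array_equal(dilate(mask, 0), mask)

    def test_dilation_extensive(self, rng):
        mask = (rng.random((20, 20)) > 0.8).astype(np.uint8)
        out = dilate(mask, 2)
        assert np.all(out >= mask)


class TestLabelComponents:
    def test_empty_mask(self):
        assert label_components(np.zeros((8, 8), dtype=np.uint8)) == []

    def test_two_squares(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        mask[10:13, 12:15] = 1
        dets = label_components(mask)
        assert len(dets) == 2
        assert [d.area for d in dets] == [9, 9]
        assert dets[0].centroid == (3.0, 3.0)
        assert dets[1].centroid == (11.0, 13.0)
        assert dets[0].bbox == (2, 2, 3, 3)

    def test_diagonal_pixels_are_one_component(self):
        # 8-connectivity keeps diagonal necks together
        mask = np.eye(5, dtype=np.uint8)
        assert len(label_components(mask)) == 1

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        mask=arrays(
            np.uint8, st.tuples(st.integers(4, 20), st.integers(4, 20)), elements=st.integers(0, 1)
        )
    )
    def test_area_conservation(self, mask):
        dets = label_components(mask)
        assert sum(d.area for d in dets) == int(mask.sum())

    def test_ordering_by_bbox_origin(self, rng):
        mask = (rng.random((40, 40)) > 0.9).astype(np.uint8)
        dets = label_components(mask)
        keys = [(d.bbox[0], d.bbox[1]) for d in dets]
        assert keys == sorted(keys)


class TestSegmentFrame:
    def test_detects_exactly_the_cells(self, replica):
        """Debris and noise are cleaned away; the one rendered cell remains."""
        from rotospin.areatrack import resolve_video_preprocessing
        from rotospin.preprocess import preprocess_frame

        _, stack, truth = replica
        pre = resolve_video_preprocessing(stack, None)
        img = preprocess_frame(stack[0], **pre)
        _, dets = segment_frame(img)
        assert len(dets) == 1
        assert dets[0].centroid == pytest.approx(tuple(truth.centroid[0]), abs=1.5)

    def test_detected_area_close_to_truth(self, replica):
        """Detected area differs from the silhouette by at most the boundary
        band added by thresholding + one dilation pass."""
        from rotospin.areatrack import resolve_video_preprocessing
        from rotospin.preprocess import preprocess_frame

        _, stack, truth = replica
        pre = resolve_video_preprocessing(stack, None)
        for t in (0, 50):
            img = preprocess_frame(stack[t], **pre)
            _, dets = segment_frame(img)
            perimeter = 2 * np.pi * 12
            assert abs(dets[0].area - truth.projected_area[t]) <= 2 * perimeter

    def test_invert_flag_finds_dark_cells(self):
        img = np.full((64, 64), 200, dtype=np.uint8)
        img[20:32, 20:32] = 60  # dark cell
        _, dets = segment_frame(img, invert=True)
        assert len(dets) == 1
        assert dets[0].centroid == pytest.approx((25.5, 25.5), abs=1.5)
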