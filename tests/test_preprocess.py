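"""Shading removal and contrast enhancement: exact mappings, monotonicity,
gain-field recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import rotospin as rs
from rotospin.datatypes import StretchParams
from rotospin.preprocess import (
    _log_histogram_entropy,
    VignetteFitError,
    correct_vignette,
    estimate_vignette_gain,
    gamma_correct,
    log_luminance_map,
    minmax_stretch,
    piecewise_linear_stretch,
    preprocess_frame,
    to_grayscale,
)

uint8_images = arrays(
    np.uint8, st.tuples(st.integers(4, 16), st.integers(4, 16)), elements=st.integers(0, 255)
)


class TestLogLuminanceMap:
    @pytest.mark.parametrize(
        "value, expected",
        [(0, 0.0), (255, 255.0), (15, 255 * np.log(16) / np.log(256))],
    )
    def test_pointwise_values(self, value, expected):
        out = log_luminance_map(np.array([[value]], dtype=float))
        assert out[0, 0] == pytest.approx(expected)
        if value == 15:
            assert out[0, 0] == pytest.approx(127.5)

    def test_range_and_shape_preserved(self, rng):
        img = rng.integers(0, 256, (32, 48)).astype(np.uint8)
        out = log_luminance_map(img)
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 255

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            log_luminance_map(np.zeros((2, 2)), N=1)


class TestGammaCorrect:
    def test_identity_at_gamma_one(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.allclose(gamma_correct(img, 1.0), img)

    def test_square_root_midpoint(self):
        # normalized 0.25 at gamma 0.5 -> 0.5, i.e. 63.75 -> 127.5
        assert gamma_correct(np.array([[63.75]]), 0.5)[0, 0] == pytest.approx(127.5)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            gamma_correct(np.zeros((2, 2)), 0.0)

    def test_corner_to_center_ratio_improves(self):
        """On a vignetted flat field, gamma < 1 pulls the corner/center
        brightness ratio toward 1 (concave tone curve)."""
        stack, _ = rs.render_video(rs.flat_field_scene(vignette_strength=0.35, seed=0))
        frame = stack[0].astype(float)
        out = gamma_correct(frame, 0.5)
        before = frame[:8, :8].mean() / frame[92:100, 92:100].mean()
        after = out[:8, :8].mean() / out[92:100, 92:100].mean()
        assert before < after < 1.0


class TestStretches:
    def test_piecewise_identity_when_breakpoints_on_diagonal(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        params = StretchParams(a=50, b=150, y_a=50, y_b=150)
        assert np.allclose(piecewise_linear_stretch(img, params), img)

    def test_piecewise_midpoint_interpolation(self):
        params = StretchParams(a=50, b=150, y_a=20, y_b=235)
        assert piecewise_linear_stretch(np.array([[100.0]]), params)[0, 0] == pytest.approx(127.5)

    def test_piecewise_monotone_on_all_levels(self):
        levels = np.arange(256, dtype=float).reshape(1, -1)
        params = StretchParams(a=30, b=200, y_a=10, y_b=250)
        out = piecewise_linear_stretch(levels, params)
        assert np.all(np.diff(out[0]) >= 0)

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            StretchParams(a=100, b=50, y_a=0, y_b=255)

    def test_minmax_endpoints_and_midvalue(self):
        img = np.arange(10, 91, 10, dtype=float).reshape(3, 3)  # {10..90}
        out = minmax_stretch(img, 0, 255)
        assert out.min() == 0.0 and out.max() == 255.0
        assert out.flat[4] == pytest.approx((50 - 10) / 80 * 255)  # = 127.5

    def test_minmax_identity_when_full_range(self):
        img = np.array([[0.0, 128.0], [200.0, 255.0]])
        assert np.allclose(minmax_stretch(img, 0, 255), img)

    def test_minmax_idempotent(self, rng):
        img = rng.integers(20, 200, (16, 16)).astype(float)
        once = minmax_stretch(img, 10, 240)
        twice = minmax_stretch(once, 10, 240)
        assert np.allclose(once, twice)

    def test_minmax_constant_image_rejected(self):
        with pytest.raises(ValueError):
            minmax_stretch(np.full((4, 4), 7.0))


@settings(max_examples=25, derandomize=True, deadline=None)
@given(img=uint8_images)
def test_point_ops_preserve_shape_range_and_order(img):
    """All enhancement ops keep [0,255], keep shape, and never invert the
    ordering of two pixels (monotone tone mapping)."""
    params = StretchParams(a=60, b=180, y_a=30, y_b=220)
    for out in (
        gamma_correct(img, 0.4),
        piecewise_linear_stretch(img, params),
        log_luminance_map(img),
    ):
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 255
        flat_in, flat_out = img.ravel().astype(float), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= -1e-9)


class TestVignetteGain:
    def test_flat_image_yields_unit_gain(self, rng):
        flat = np.clip(150 + rng.normal(0, 2, (96, 96)), 0, 255)
        gain = estimate_vignette_gain(flat)
        assert np.abs(gain - 1).max() < 0.05

    def test_known_quadratic_gain_recovered(self):
        """Applying 1/g* then fitting recovers g* within 5% at the corners."""
        stack, _ = rs.render_video(rs.flat_field_scene(vignette_strength=0.35, seed=1))
        gain = estimate_vignette_gain(stack[0])
        true_corner = 1.0 / 0.65
        assert gain.max() == pytest.approx(true_corner, rel=0.05)

    def test_entropy_decreases_after_correction(self):
        stack, _ = rs.render_video(rs.flat_field_scene(vignette_strength=0.3, seed=2))
        gain = estimate_vignette_gain(stack[0])
        corrected = correct_vignette(stack[0], gain)
        assert _log_histogram_entropy(corrected) <= _log_histogram_entropy(stack[0])

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_vignette_gain(np.full((32, 32), 100.0))


class TestCorrectVignette:
    def test_unit_gain_identity(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(float)
        assert np.allclose(correct_vignette(img, np.ones_like(img)), img)

    def test_product_and_clipping(self):
        img = np.array([[100.0, 200.0]])
        gain = np.array([[1.5, 1.5]])
        out = correct_vignette(img, gain)
        assert out[0, 0] == 150.0
        assert out[0, 1] == 255.0  # clipped

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correct_vignette(np.zeros((4, 4)), np.ones((3, 3)))


class TestPreprocessFrame:
    def test_uint8_output_full_chain(self, replica):
        _, stack, _ = replica
        out = preprocess_frame(stack[0])
        assert out.dtype == np.uint8 and out.shape == stack[0].shape

    def test_color_input_collapsed(self):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[..., 1] = 255  # pure green
        assert to_grayscale(rgb)[0, 0] == 150  # round(0.587*255)

    def test_unknown_modes_rejected(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        with pytest.raises(ValueError):
            preprocess_frame(img, vignette="sharpen")
        with pytest.raises(ValueError):
            preprocess_frame(img, stretch="histeq")
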