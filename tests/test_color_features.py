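"""Unit tests for the chromatic feature conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitfuse.color_features import (
    LAB_BREAKPOINT,
    LAB_OFFSET,
    LAB_SLOPE,
    FeatureImage,
    extract_feature_images,
    minmax_normalize,
    normalize_feature,
    rgb_normalize,
    rgb_to_xyz,
    rgb_to_yiq,
    xyz_to_lab,
)

rgb_channel = st.integers(min_value=0, max_value=255)


class TestRgbNormalize:
    @pytest.mark.parametrize(
        "pixel,expected",
        [
            ((100, 100, 100), (1 / 3, 1 / 3, 1 / 3)),
            ((255, 0, 0), (1.0, 0.0, 0.0)),
            ((0, 0, 0), (1 / 3, 1 / 3, 1 / 3)),  # black: gray-point convention
        ],
    )
    def test_examples(self, pixel, expected):
        assert rgb_normalize(pixel) == pytest.approx(expected, abs=1e-12)

    @given(r=rgb_channel, g=rgb_channel, b=rgb_channel)
    @settings(max_examples=100, deadline=None)
    def test_chromaticity_sums_to_one(self, r, g, b):
        c = rgb_normalize((r, g, b))
        assert c.sum() == pytest.approx(1.0, abs=1e-9)
        assert (c >= 0).all() and (c <= 1).all()

    @pytest.mark.parametrize("pixel", [(-1, 0, 0), (0, 256, 0), (np.nan, 0, 0)])
    def test_rejects_out_of_range(self, pixel):
        with pytest.raises(ValueError):
            rgb_normalize(pixel)


class TestRgbToXyz:
    def test_gray_point_lands_on_equal_tristimulus(self):
        # Each matrix row sums to 1, so the gray chromaticity maps to
        # X = Y = Z = 1/3.
        xyz = rgb_to_xyz((1 / 3, 1 / 3, 1 / 3))
        assert xyz == pytest.approx([0.333333, 0.333333, 0.333333], abs=1e-6)

    def test_pure_red_is_first_matrix_column(self):
        assert rgb_to_xyz((1, 0, 0)) == pytest.approx(
            [0.433953, 0.212671, 0.017758], abs=1e-12
        )

    def test_zero_maps_to_zero(self):
        assert rgb_to_xyz((0, 0, 0)) == pytest.approx([0, 0, 0], abs=0)


class TestXyzToLab:
    @pytest.mark.parametrize(
        "xyz,expected_lab",
        [
            ((1, 1, 1), (100.0, 0.0, 0.0)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_reference_points(self, xyz, expected_lab):
        assert xyz_to_lab(xyz) == pytest.approx(expected_lab, abs=1e-9)

    def test_equal_tristimulus_has_zero_chroma(self):
        # Direct evaluation: L* = 116 * t^(1/3) - 16 at t = 0.333333.
        t = 0.333333
        lab = xyz_to_lab((t, t, t))
        assert lab[1] == 0.0 and lab[2] == 0.0
        assert lab[0] == pytest.approx(116.0 * t ** (1 / 3) - 16.0, abs=1e-9)
        assert lab[0] == pytest.approx(64.43, abs=0.01)

    def test_companding_continuous_at_breakpoint(self):
        t = LAB_BREAKPOINT
        assert t ** (1 / 3) == pytest.approx(LAB_SLOPE * t + LAB_OFFSET, abs=1e-3)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            xyz_to_lab((-0.1, 0.2, 0.2))


class TestRgbToYiq:
    def test_zero_maps_to_zero(self):
        assert rgb_to_yiq((0, 0, 0)) == pytest.approx([0, 0, 0], abs=0)

    def test_white_has_slightly_negative_i(self):
        # 255 * (0.5957 - 0.2745 - 0.3213) with the printed coefficients.
        assert rgb_to_yiq((255, 255, 255))[1] == pytest.approx(-0.0255, abs=1e-9)

    def test_pure_red_scales_first_coefficients(self):
        assert rgb_to_yiq((255, 0, 0)) == pytest.approx(
            [76.2450, 151.9035, 53.9325], abs=1e-9
        )

    @given(r=rgb_channel, g=rgb_channel, b=rgb_channel, alpha=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_linearity(self, r, g, b, alpha):
        scaled = rgb_to_yiq(alpha * np.array([r, g, b], dtype=float))
        assert scaled == pytest.approx(alpha * rgb_to_yiq((r, g, b)), abs=1e-9)


class TestExtractFeatureImages:
    def test_gray_image_has_identically_zero_a_star(self):
        img = np.full((5, 4, 3), 77, dtype=np.uint8)
        a, _ = extract_feature_images(img)
        assert np.abs(a.values).max() == 0.0

    def test_uniform_red_image(self):
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        img[..., 0] = 255
        a, i = extract_feature_images(img)
        assert np.ptp(a.values) == 0.0 and a.values[0, 0] > 0
        assert i.values == pytest.approx(np.full((3, 3), 151.9035), abs=1e-9)

    def test_shape_preserved(self):
        img = np.zeros((2, 3, 3), dtype=np.uint8)
        a, i = extract_feature_images(img)
        assert a.values.shape == (2, 3) and i.values.shape == (2, 3)

    def test_a_star_sign_orders_red_above_green(self):
        red = extract_feature_images(np.full((1, 1, 3), (200, 40, 40), np.uint8))[0]
        green = extract_feature_images(np.full((1, 1, 3), (40, 200, 40), np.uint8))[0]
        assert red.values[0, 0] > 0 > green.values[0, 0]

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            extract_feature_images(np.zeros((0, 3, 3)))


class TestNormalizeFeature:
    def test_minmax_definition(self):
        out = minmax_normalize(np.array([10.0, 20.0, 30.0]))
        assert out == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_maps_to_zeros(self):
        assert (minmax_normalize(np.full((3, 3), 7.0)) == 0).all()

    def test_idempotent_on_full_range(self, rng):
        vals = rng.uniform(size=(8, 8))
        vals.flat[0], vals.flat[1] = 0.0, 1.0
        assert minmax_normalize(vals) == pytest.approx(vals, abs=1e-12)

    def test_populates_normalized_grid(self, rng):
        f = FeatureImage(values=rng.normal(size=(6, 6)) * 50, channel_tag="a_star")
        out = normalize_feature(f)
        assert out.normalized.min() == 0.0 and out.normalized.max() == 1.0
        # applying twice equals once on (now full-range) input
        assert minmax_normalize(out.normalized) == pytest.approx(out.normalized)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([1.0, np.inf]))
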