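"""Grayscale preprocessing operators against hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis.extra import numpy as hnp

from satquant.errors import ParameterError
from satquant.filters import (
    NormalizationParams,
    convolve_kernel,
    edge_magnitude,
    median_filter,
    normalize_range,
    rolling_ball_subtract,
    sharpen,
)


def _ball_opening_oracle(img, radius):
    """Brute-force spherical-cap erosion-then-dilation with edge replication."""
    h, w = img.shape
    offsets = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offsets.append((dy, dx, np.sqrt(radius * radius - dy * dy - dx * dx)))

    def clampat(r, c):
        return img_f[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]

    img_f = img.astype(float)
    eroded = np.empty_like(img_f)
    for r in range(h):
        for c in range(w):
            eroded[r, c] = min(clampat(r + dy, c + dx) - z for dy, dx, z in offsets)
    img_f = eroded

    def clampat2(r, c):
        return eroded[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]

    opened = np.empty_like(eroded)
    for r in range(h):
        for c in range(w):
            opened[r, c] = max(clampat2(r - dy, c - dx) + z for dy, dx, z in offsets)
    return opened


class TestRollingBall:
    def test_flat_background_fully_removed(self):
        out = rolling_ball_subtract(np.full((40, 40), 100, dtype=np.uint8), 15)
        np.testing.assert_array_equal(out, 0)

    def test_zero_image_unchanged(self):
        out = rolling_ball_subtract(np.zeros((30, 30), dtype=np.uint8), 15)
        np.testing.assert_array_equal(out, 0)

    def test_bright_spike_on_constant_background(self):
        img = np.full((40, 40), 10, dtype=np.uint8)
        img[20, 20] = 255
        out = rolling_ball_subtract(img, 15)
        assert out[20, 20] >= 240
        assert out[5, 5] == 0

    def test_matches_brute_force_cap_opening(self, rng):
        img = rng.integers(0, 256, (14, 14)).astype(np.uint8)
        radius = 3
        background = np.clip(_ball_opening_oracle(img, radius), 0, None)
        expected = np.floor(np.clip(img.astype(float) - background, 0, 255) + 0.5)
        out = rolling_ball_subtract(img, radius)
        np.testing.assert_array_equal(out, expected.astype(np.uint8))

    def test_never_increases_any_pixel(self, rng):
        img = rng.integers(0, 256, (32, 48)).astype(np.uint8)
        out = rolling_ball_subtract(img, 5)
        assert (out <= img).all()

    def test_idempotent_on_flat_background_residual(self):
        img = np.full((40, 40), 20, dtype=np.uint8)
        img[10:14, 10:14] = 200
        once = rolling_ball_subtract(img, 15)
        twice = rolling_ball_subtract(once, 15)
        np.testing.assert_array_equal(once, twice)

    def test_radius_exceeding_both_dimensions_rejected(self):
        with pytest.raises(ParameterError):
            rolling_ball_subtract(np.zeros((8, 8), dtype=np.uint8), 10)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ParameterError):
            rolling_ball_subtract(np.zeros((8, 8), dtype=np.uint8), 0)


class TestSharpen:
    def test_constant_image_unchanged(self):
        img = np.full((6, 6), 90, dtype=np.uint8)
        np.testing.assert_array_equal(sharpen(img), img)

    def test_single_pixel_response(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 4
        out = sharpen(img)
        assert out[2, 2] == 12          # 4 * 12 / 4
        assert out[1, 1] == 0           # -4/4 clamps to 0
        assert out[0, 0] == 0

    def test_matches_direct_convolution(self, rng):
        img = rng.integers(0, 256, (6, 7)).astype(np.uint8)
        padded = np.pad(img.astype(float), 1, mode="edge")
        expected = np.empty_like(img, dtype=float)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                window = padded[r:r + 3, c:c + 3]
                expected[r, c] = (12 * window[1, 1] - (window.sum() - window[1, 1])) / 4
        expected = np.floor(np.clip(expected, 0, 255) + 0.5)
        np.testing.assert_array_equal(sharpen(img), expected.astype(np.uint8))

    def test_checkerboard_never_inverted(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255
        out = sharpen(board.astype(np.uint8))
        assert (out[board == 255] == 255).all()
        assert (out[board == 0] == 0).all()


class TestEdgeMagnitude:
    def test_constant_image_maps_to_zero(self):
        np.testing.assert_array_equal(
            edge_magnitude(np.full((8, 8), 123, dtype=np.uint8)), 0)

    def test_vertical_step_saturates_along_edge(self):
        img = np.zeros((3, 4), dtype=np.uint8)
        img[:, 2:] = 255
        out = edge_magnitude(img)
        assert (out[:, 1] == 255).all() and (out[:, 2] == 255).all()
        assert (out[:, 0] < 255).all()

    def test_disk_gives_boundary_ring(self):
        yy, xx = np.mgrid[0:21, 0:21]
        disk = ((yy - 10) ** 2 + (xx - 10) ** 2 <= 36) * 200
        out = edge_magnitude(disk.astype(np.uint8))
        assert out[10, 10] == 0          # flat interior
        assert out[10, 4] > 100          # boundary response
        assert out[0, 0] == 0            # flat exterior


class TestNormalizeRange:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([[50, 150]], [[0, 255]]),
            ([[0, 128, 255]], [[0, 128, 255]]),
            ([[100, 150, 200]], [[0, 128, 255]]),
        ],
    )
    def test_minmax_stretch(self, values, expected):
        out = normalize_range(np.array(values, dtype=np.uint8))
        np.testing.assert_array_equal(out, expected)

    def test_output_extremes_hit_target_bounds(self, rng):
        img = rng.integers(30, 200, (12, 12)).astype(np.uint8)
        img[0, 0], img[1, 1] = 30, 199
        out = normalize_range(img)
        assert out.min() == 0 and out.max() == 255

    def test_constant_image_warns_and_returns_c(self):
        img = np.full((4, 4), 77, dtype=np.uint8)
        with pytest.warns(UserWarning):
            out = normalize_range(img, NormalizationParams(c=0, d=255))
        np.testing.assert_array_equal(out, 0)

    def test_invalid_target_range_rejected(self):
        with pytest.raises(ParameterError):
            NormalizationParams(c=10, d=10)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((7, 7), 42, dtype=np.uint8)
        np.testing.assert_array_equal(median_filter(img, 1), img)

    def test_isolated_pixel_vanishes(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 255
        np.testing.assert_array_equal(median_filter(img, 1), 0)

    def test_solid_block_center_survives(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[3:6, 3:6] = 255
        out = median_filter(img, 1)
        assert out[4, 4] == 255          # 9/9 window majority
        assert out[3, 4] == 255          # 6/9 majority on block edge
        assert out[3, 3] == 0            # 4/9 at block corner

    def test_commutes_with_transpose(self, rng):
        img = rng.integers(0, 256, (10, 14)).astype(np.uint8)
        np.testing.assert_array_equal(
            median_filter(img.T, 1), median_filter(img, 1).T)


class TestConvolveKernel:
    def test_identity_kernel(self, rng):
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        k = np.zeros((3, 3)); k[1, 1] = 1
        np.testing.assert_array_equal(convolve_kernel(img, k), img)

    def test_normalized_ones_on_constant(self):
        img = np.full((6, 6), 30, dtype=np.uint8)
        np.testing.assert_array_equal(
            convolve_kernel(img, np.ones((3, 3)), normalize=True), img)

    def test_mean_kernel_spreads_single_pixel(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 9
        out = convolve_kernel(img, np.ones((3, 3)), normalize=True)
        np.testing.assert_array_equal(out[1:4, 1:4], 1)
        assert out.sum() == 9

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            convolve_kernel(np.zeros((4, 4), dtype=np.uint8), np.ones((2, 3)))

    @given(hnp.arrays(np.uint8, (9, 9)))
    def test_symmetric_kernel_commutes_with_transpose(self, img):
        k = np.ones((3, 3)) / 9.0
        np.testing.assert_array_equal(
            convolve_kernel(img.T, k), convolve_kernel(img, k).T)
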