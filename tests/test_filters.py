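"""Intensity filters and binary morphology against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from adherens.image import ImageChannel
from adherens.junctions import (
    binarize,
    close_gaps,
    dilate_binary,
    gaussian_blur,
    huang_threshold,
    sharpen,
    skeletonize,
    subtract_background,
)

from conftest import make_channel


# ---------------------------------------------------------------------------
# rolling-ball background subtraction

class TestSubtractBackground:
    def test_flat_image_maps_to_zero(self):
        out = subtract_background(make_channel(np.full((64, 64), 57)), radius=20)
        assert np.all(out.pixels == 0)

    def test_small_bright_disk_preserved_vs_ball_opening_oracle(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 6 ** 2
        img[disk] = 100
        out = subtract_background(make_channel(img), radius=20)
        # oracle: grayscale opening with a ball structuring function
        r = 20
        y, x = np.mgrid[-r : r + 1, -r : r + 1]
        d2 = x * x + y * y
        footprint = d2 <= r * r
        height = np.sqrt(np.maximum(r * r - d2, 0.0))
        height -= height.max()
        eroded = ndi.grey_erosion(img.astype(float), structure=height, footprint=footprint)
        background = ndi.grey_dilation(eroded, structure=height, footprint=footprint)
        oracle = np.clip(img.astype(float) - background, 0, 255)
        assert np.abs(out.pixels.astype(int) - np.rint(oracle).astype(int)).max() <= 1
        assert np.all(np.abs(out.pixels[disk].astype(int) - 100) <= 1)

    def test_output_never_exceeds_input(self, rng):
        img = make_channel(rng.integers(0, 256, (64, 64)))
        out = subtract_background(img, radius=20)
        assert np.all(out.pixels <= img.pixels)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(make_channel(np.zeros((64, 64))), radius=0)


# ---------------------------------------------------------------------------
# Gaussian blur

class TestGaussianBlur:
    def test_constant_unchanged(self):
        out = gaussian_blur(make_channel(np.full((32, 32), 99)), sigma=2.0, passes=2)
        assert np.all(out.pixels == 99)

    def test_two_passes_compose_like_sigma_sqrt2(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[32, 32] = 255
        double = gaussian_blur(make_channel(img), sigma=2.0, passes=2)
        single = gaussian_blur(make_channel(img), sigma=2.0 * np.sqrt(2), passes=1)
        assert np.abs(double.pixels.astype(int) - single.pixels.astype(int)).max() <= 1

    def test_intensity_mass_preserved(self, rng):
        img = make_channel(rng.integers(40, 216, (64, 64)))
        out = gaussian_blur(img, sigma=2.0, passes=2)
        before, after = img.pixels.sum(), out.pixels.sum()
        assert abs(int(after) - int(before)) / before < 1e-3

    def test_invalid_parameters_rejected(self):
        img = make_channel(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            gaussian_blur(img, sigma=0)
        with pytest.raises(ValueError):
            gaussian_blur(img, passes=0)


# ---------------------------------------------------------------------------
# sharpen

class TestSharpen:
    def test_constant_is_identity(self):
        out = sharpen(make_channel(np.full((32, 32), 123)))
        assert np.all(out.pixels == 123)

    def test_single_pixel_arithmetic(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10, 10] = 40
        out = sharpen(make_channel(img))
        assert out.pixels[10, 10] == 120  # 40 * 12 / 4
        assert out.pixels[10, 11] == 0  # -40/4 clipped at 0

    def test_matches_direct_convolution_oracle(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = sharpen(make_channel(img))
        kernel = np.array([[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]]) / 4.0
        padded = np.pad(img.astype(float), 1, mode="edge")
        oracle = np.zeros_like(img, dtype=float)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                oracle[r, c] = np.sum(padded[r : r + 3, c : c + 3] * kernel)
        oracle = np.clip(np.rint(oracle), 0, 255)
        assert np.array_equal(out.pixels, oracle.astype(np.uint8))

    def test_checkerboard_contrast_not_decreased(self):
        img = np.indices((32, 32)).sum(axis=0) % 2 * 255
        out = sharpen(make_channel(img))
        assert np.array_equal(out.pixels, img.astype(np.uint8))


# ---------------------------------------------------------------------------
# Huang threshold

def _huang_fuzziness_bruteforce(hist):
    """Plain-loop reference for Huang's criterion (independent oracle)."""
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    C = float(last - first)
    best_t, best_s = None, np.inf
    for t in range(first, last):
        low = [(g, h) for g, h in enumerate(hist[: t + 1]) if h]
        high = [(g, h) for g, h in enumerate(hist) if h and g > t]
        mu0 = sum(g * h for g, h in low) / sum(h for _, h in low)
        mu1 = sum(g * h for g, h in high) / sum(h for _, h in high)
        s = 0.0
        for g, h in low + high:
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / C)
            if 0 < u < 1:
                s += h * (-u * np.log(u) - (1 - u) * np.log(1 - u))
        if s < best_s - 1e-12:
            best_s, best_t = s, t
    return best_t


class TestHuangThreshold:
    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_levels = int(rng.integers(2, 40))
            levels = rng.choice(256, size=n_levels, replace=False)
            counts = rng.integers(1, 50, size=n_levels)
            pixels = np.repeat(levels, counts).astype(np.uint8)
            side = int(np.ceil(np.sqrt(pixels.size)))
            padded = np.zeros(side * side, dtype=np.uint8)
            padded[: pixels.size] = pixels
            img = make_channel(padded.reshape(side, side))
            hist = np.bincount(padded, minlength=256)
            assert huang_threshold(img) == _huang_fuzziness_bruteforce(hist)

    def test_symmetric_bimodal_splits_classes(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[8:] = 255
        t = huang_threshold(make_channel(img))
        assert 0 <= t < 255
        mask = binarize(make_channel(img), t)
        assert np.all(mask[8:])
        assert not np.any(mask[:8])

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            huang_threshold(make_channel(np.full((16, 16), 77)))


# ---------------------------------------------------------------------------
# binarize / dilate

def test_binarize_threshold_semantics():
    img = make_channel(np.array([[0, 10], [255, 21]]))
    assert not binarize(img, 255).any()
    assert np.array_equal(binarize(img, 0), np.array([[False, True], [True, True]]))
    rendered = make_channel(np.where(binarize(img, 20), 255, 0))
    assert np.array_equal(binarize(rendered, 20), binarize(img, 20))


class TestDilateBinary:
    def test_single_pixel_becomes_3x3_block(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        out = dilate_binary(mask, iterations=1)
        assert out.sum() == 9
        assert np.all(out[3:6, 3:6])

    def test_zero_iterations_is_identity(self, rng):
        mask = rng.random((32, 32)) < 0.2
        assert np.array_equal(dilate_binary(mask, 0), mask)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 3))
    def test_dilation_is_extensive(self, seed, iterations):
        mask = np.random.default_rng(seed).random((24, 24)) < 0.15
        out = dilate_binary(mask, iterations)
        assert np.all(out[mask])
        assert out.sum() >= mask.sum()


# ---------------------------------------------------------------------------
# close_gaps

class TestCloseGaps:
    def test_collinear_break_is_repaired(self):
        mask = np.zeros((21, 60), dtype=bool)
        mask[10, 5:25] = True
        mask[10, 29:55] = True
        out = close_gaps(mask, max_bridge=10)
        _, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 1
        assert np.all(out[mask])

    def test_zero_bridge_is_identity(self):
        mask = np.zeros((21, 60), dtype=bool)
        mask[10, 5:25] = True
        mask[10, 29:55] = True
        assert np.array_equal(close_gaps(mask, max_bridge=0), mask)

    def test_closed_loop_unchanged(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10, 10:30] = mask[29, 10:30] = True
        mask[10:30, 10] = mask[10:30, 29] = True
        assert np.array_equal(close_gaps(mask, max_bridge=10), mask)


# ---------------------------------------------------------------------------
# skeletonize

class TestSkeletonize:
    def test_filled_rectangle_thins_to_single_line(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[8:13, 5:55] = True
        skel = skeletonize(mask).skeleton_mask
        _, n = ndi.label(skel, structure=np.ones((3, 3)))
        assert n == 1
        assert 40 <= skel.sum() <= 50
        rows = np.unique(np.argwhere(skel)[:, 0])
        assert rows.max() - rows.min() <= 1  # essentially horizontal

    def test_empty_mask_gives_empty_skeleton(self):
        assert skeletonize(np.zeros((16, 16), dtype=bool)).skeleton_mask.sum() == 0

    def test_idempotent_on_own_output(self, clean_monolayer):
        img, _ = clean_monolayer
        mask = dilate_binary(binarize(img, 50), 2)
        once = skeletonize(mask).skeleton_mask
        twice = skeletonize(once).skeleton_mask
        assert np.array_equal(once, twice)

    def test_component_count_preserved(self):
        mask = np.zeros((40, 80), dtype=bool)
        mask[10:14, 5:35] = True
        mask[25:29, 40:75] = True
        skel = skeletonize(mask).skeleton_mask
        s8 = np.ones((3, 3))
        assert ndi.label(skel, structure=s8)[1] == ndi.label(mask, structure=s8)[1]
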