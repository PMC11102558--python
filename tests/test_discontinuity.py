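"""The discontinuity statistic: fixed-window mask, profile, ratio."""

import numpy as np
import pytest

from adherens.discontinuity import (
    BinaryJunctionMask,
    discontinuity_ratio,
    junction_binary_mask,
    profile_outline,
    records_to_frame,
    score_image,
)
from adherens.junctions import CellOutline, select_outlines, trace_outlines
from adherens.simulate import generate_monolayer

from conftest import make_channel, noiseless_config


class TestDiscontinuityRatio:
    def test_definition_arithmetic(self):
        profile = np.array([0] * 50 + [255] * 150)
        assert discontinuity_ratio(profile) == 25.0
        assert discontinuity_ratio(np.full(200, 255)) == 0.0
        assert discontinuity_ratio(np.zeros(200)) == 100.0

    def test_invariant_to_rotation_and_reversal(self):
        rng = np.random.default_rng(7)
        profile = rng.choice([0, 255], size=137)
        base = discontinuity_ratio(profile)
        for shift in (1, 17, 76):
            assert discontinuity_ratio(np.roll(profile, shift)) == base
        assert discontinuity_ratio(profile[::-1]) == base

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            discontinuity_ratio(np.array([]))


class TestJunctionBinaryMask:
    def test_all_zero_image(self):
        mask = junction_binary_mask(make_channel(np.zeros((64, 64))))
        assert np.all(mask.pixels == 0)

    def test_flat_image_at_threshold_is_removed_as_background(self):
        mask = junction_binary_mask(make_channel(np.full((64, 64), 21)))
        assert np.all(mask.pixels == 0)

    def test_narrow_ridge_survives_subtraction_and_thresholding(self):
        """Two-step oracle on a 1-D ridge profile replicated across rows:
        a thin ridge is untouched by the rolling ball, so exactly the pixels
        whose raw value is inside [21, 255] survive."""
        cols = np.zeros(64)
        center = 32
        for c in range(64):
            cols[c] = 200 * np.exp(-((c - center) ** 2) / (2 * 2.0 ** 2))
        img = np.tile(np.rint(cols).astype(np.uint8), (64, 1))
        mask = junction_binary_mask(make_channel(img))
        expected = (img >= 21) & (img <= 255)
        # away from the top/bottom frame rows where the ball wraps the ridge
        interior = slice(20, 44)
        assert np.array_equal(mask.pixels[interior] == 255, expected[interior])

    def test_only_binary_values_allowed(self):
        with pytest.raises(ValueError):
            BinaryJunctionMask(np.array([[0, 128]], dtype=np.uint8))


def _circle_outline(radius=20, center=(32, 32)):
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pts = np.unique(
        np.column_stack(
            [
                np.rint(center[0] + radius * np.sin(theta)),
                np.rint(center[1] + radius * np.cos(theta)),
            ]
        ).astype(int),
        axis=0,
    )
    angles = np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1])
    return pts[np.argsort(angles)]


class TestProfileOutline:
    def test_uniform_foreground_and_background(self):
        path = _circle_outline()
        outline = CellOutline(cell_id=1, path=path)
        ones = BinaryJunctionMask(np.full((64, 64), 255, dtype=np.uint8))
        zeros = BinaryJunctionMask(np.zeros((64, 64), dtype=np.uint8))
        assert np.all(profile_outline(ones, outline) == 255)
        assert np.all(profile_outline(zeros, outline) == 0)
        assert len(profile_outline(ones, outline)) == len(path)

    def test_single_gap_crossing_outline_gives_one_zero_run(self):
        path = _circle_outline()
        outline = CellOutline(cell_id=1, path=path)
        pixels = np.full((64, 64), 255, dtype=np.uint8)
        gap_members = path[10:20]  # 10 consecutive path pixels
        pixels[gap_members[:, 0], gap_members[:, 1]] = 0
        profile = profile_outline(BinaryJunctionMask(pixels), outline)
        zero = profile == 0
        runs = np.diff(np.concatenate([[0], zero.astype(int), [0]]))
        starts, ends = np.nonzero(runs == 1)[0], np.nonzero(runs == -1)[0]
        assert len(starts) == 1
        assert abs((ends[0] - starts[0]) - 10) <= 2

    def test_out_of_bounds_pixel_named_in_error(self):
        outline = CellOutline(cell_id=1, path=np.array([[0, 0], [0, 70]]))
        mask = BinaryJunctionMask(np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(ValueError, match=r"\(0, 70\)"):
            profile_outline(mask, outline)


class TestScoreImage:
    def test_one_record_per_outline_with_identity(self, clean_monolayer):
        img, _ = clean_monolayer
        _, outlines = trace_outlines(img)
        kept = [o for o in outlines if not o.touches_border]
        records = score_image(img, kept)
        assert len(records) == len(kept)
        frame = records_to_frame(records)
        assert set(frame["image_id"]) == {img.image_id}
        assert np.allclose(
            frame["ratio_percent"], 100 * frame["zero_pixels"] / frame["outline_pixels"]
        )

    def test_noiseless_gap_free_image_scores_near_zero(self, clean_monolayer):
        img, _ = clean_monolayer
        _, outlines = trace_outlines(img)
        kept = [o for o in outlines if not o.touches_border]
        records = score_image(img, kept)
        assert records, "no scorable cells in fixture"
        assert all(r.ratio_percent <= 5.0 for r in records)

    def test_blank_channel_scores_100_everywhere(self, clean_monolayer):
        img, _ = clean_monolayer
        _, outlines = trace_outlines(img)
        kept = [o for o in outlines if not o.touches_border]
        blank = make_channel(np.zeros(img.shape), image_id="blank")
        records = score_image(blank, kept)
        assert records and all(r.ratio_percent == 100.0 for r in records)
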