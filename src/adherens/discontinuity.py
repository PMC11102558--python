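"""The per-cell junction-discontinuity statistic.

A cell with an intact adherens junction has cadherin-5 signal along its
entire perimeter; barrier disruption fragments that signal. The statistic
scores each cell as the percentage of its outline pixels that carry *no*
above-threshold junction signal:

    ratio (%) = 100 * (outline pixels with binary value 0) / (outline pixels)

Two tracks share only the raw channel and the rolling-ball background
subtraction. Outline geometry comes from the heavily processed chain
(blur, sharpen, auto-threshold, dilate, bridge, skeletonize); the intensity
that is scored comes from a lightly processed mask — the background-
subtracted raw channel binarized at the fixed 21–255 window. Keeping the
scoring mask light matters: the geometry track deliberately fills gaps so
that outlines stay closed, and the discontinuity must be read from a mask
that still shows them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import ImageChannel
from .junctions import CellOutline, subtract_background


@dataclass(frozen=True)
class BinaryJunctionMask:
    """Fixed-window binary junction mask (values {0, 255} only)."""

    pixels: np.ndarray
    source_image_id: str = ""
    threshold_low: int = 21
    threshold_high: int = 255

    def __post_init__(self) -> None:
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 255))):
            raise ValueError("binary mask may contain only values 0 and 255")


@dataclass(frozen=True)
class DiscontinuityRecord:
    """Per-cell scoring result."""

    image_id: str
    group_label: str
    cell_id: int
    outline_pixels: int
    zero_pixels: int
    ratio_percent: float


def junction_binary_mask(
    raw: ImageChannel,
    threshold_low: int = 21,
    threshold_high: int = 255,
    rolling_radius: int = 20,
    background_subtracted: ImageChannel | None = None,
) -> BinaryJunctionMask:
    """Background-subtract the raw channel, then apply the fixed window.

    A pixel maps to 255 iff its background-subtracted intensity lies in
    [threshold_low, threshold_high] (both inclusive); otherwise 0. The
    window is a fixed choice on the 8-bit scale, not an auto-threshold.
    ``background_subtracted`` may be supplied when the rolling-ball result
    is already available from the geometry track.
    """
    if background_subtracted is None:
        background_subtracted = subtract_background(raw, radius=rolling_radius)
    px = background_subtracted.pixels
    inside = (px >= threshold_low) & (px <= threshold_high)
    return BinaryJunctionMask(
        np.where(inside, 255, 0).astype(np.uint8),
        source_image_id=raw.image_id,
        threshold_low=threshold_low,
        threshold_high=threshold_high,
    )


def profile_outline(mask: BinaryJunctionMask, outline: CellOutline) -> np.ndarray:
    """Plot-profile of the binary mask along the outline's own pixel path.

    One sample per path pixel, in path order; each pixel is read exactly
    once, so the profile length equals the outline pixel count.
    """
    path = outline.path
    h, w = mask.pixels.shape
    bad = (path[:, 0] < 0) | (path[:, 0] >= h) | (path[:, 1] < 0) | (path[:, 1] >= w)
    if bad.any():
        r, c = path[np.argmax(bad)]
        raise ValueError(f"outline pixel ({r}, {c}) lies outside the {h}x{w} mask")
    return mask.pixels[path[:, 0], path[:, 1]]


def discontinuity_ratio(profile: np.ndarray) -> float:
    """Percent of profile samples equal to 0."""
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ValueError("profile is empty")
    return 100.0 * float(np.count_nonzero(profile == 0)) / profile.size


def score_image(
    raw: ImageChannel,
    selected_outlines: list[CellOutline],
    threshold_low: int = 21,
    threshold_high: int = 255,
    rolling_radius: int = 20,
    background_subtracted: ImageChannel | None = None,
) -> list[DiscontinuityRecord]:
    """Score every selected outline of one image: one record per cell."""
    mask = junction_binary_mask(
        raw,
        threshold_low=threshold_low,
        threshold_high=threshold_high,
        rolling_radius=rolling_radius,
        background_subtracted=background_subtracted,
    )
    records = []
    for outline in selected_outlines:
        profile = profile_outline(mask, outline)
        records.append(
            DiscontinuityRecord(
                image_id=raw.image_id,
                group_label=raw.group_label,
                cell_id=outline.cell_id,
                outline_pixels=len(profile),
                zero_pixels=int(np.count_nonzero(profile == 0)),
                ratio_percent=discontinuity_ratio(profile),
            )
        )
    return records


def records_to_frame(records: list[DiscontinuityRecord]) -> pd.DataFrame:
    """Tidy table of per-cell records (the pipeline's main CSV output)."""
    return pd.DataFrame(
        [
            {
                "group": r.group_label,
                "image_id": r.image_id,
                "cell_id": r.cell_id,
                "outline_pixels": r.outline_pixels,
                "zero_pixels": r.zero_pixels,
                "ratio_percent": r.ratio_percent,
            }
            for r in records
        ],
        columns=["group", "image_id", "cell_id", "outline_pixels", "zero_pixels", "ratio_percent"],
    )
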