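"""8-bit single-channel image container and TIFF I/O.

The pipeline's working currency is a 2-D raster of 8-bit intensities tagged
with an image identity and an experimental-group label. Micrographs of
immunostained endothelial monolayers arrive as single-channel grayscale TIFFs
(the cadherin-5 channel); everything downstream assumes the 0–255 scale, since
the fixed 21–255 junction threshold is only meaningful on 8-bit data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class ImageChannel:
    """A single 2-D 8-bit fluorescence channel.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Intensities in [0, 255].
    image_id : str
        Identifier of the source micrograph.
    group_label : str
        Experimental condition this image belongs to.
    """

    pixels: np.ndarray
    image_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("pixels must be integer-typed (8-bit scale)")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImageChannel":
        """Same identity, new raster (used by every filter stage)."""
        return replace(self, pixels=np.asarray(pixels))


def as_uint8(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round-quantize to uint8."""
    return np.clip(np.rint(values), 0, 255).astype(np.uint8)


def read_channel(
    path: str | Path,
    image_id: str | None = None,
    group_label: str = "",
    channel_index: int = 0,
    auto_rescale: bool = False,
) -> ImageChannel:
    """Read one 8-bit grayscale channel from a TIFF file.

    Multi-channel stacks are indexed with ``channel_index`` (leading axis).
    Non-8-bit data is rejected unless ``auto_rescale`` is set, in which case it
    is min–max rescaled to 0–255 — a lossy step that changes what the fixed
    21–255 threshold means, hence opt-in only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if not 0 <= channel_index < arr.shape[0]:
            raise ValueError(
                f"channel_index {channel_index} out of range for {arr.shape[0]}-channel stack"
            )
        arr = arr[channel_index]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not auto_rescale:
            raise ValueError(
                f"{path} is {arr.dtype}, not 8-bit; pass auto_rescale to min-max "
                "rescale (note: this changes the meaning of fixed thresholds)"
            )
        lo, hi = float(arr.min()), float(arr.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        arr = as_uint8((arr.astype(np.float64) - lo) * scale)
    return ImageChannel(arr, image_id=image_id or path.stem, group_label=group_label)


def write_channel(img: ImageChannel, path: str | Path) -> None:
    """Write an 8-bit single-channel TIFF (uncompressed, deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), img.pixels, photometric="minisblack")
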