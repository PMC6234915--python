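"""Core raster container and bounding-box types.

All images in phasefuse are carried as :class:`ImageGrid` — a float raster in
[0, 1], either single-plane (grayscale, edge magnitude, binary mask) or
three-plane RGB, tagged with the acquisition modality (VIS camera, FLU
camera, or synthetic). The pixel-coordinate convention is fixed project-wide:
rows increase downward, columns rightward, origin at the top-left corner,
and boxes are 0-based with half-open upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidBoxError, ShapeError

MODALITIES = ("VIS", "FLU", "synthetic")
CHANNEL_KINDS = ("rgb", "gray", "edge", "binary_mask")


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D intensity or RGB raster with a modality tag.

    Parameters
    ----------
    pixels
        ``(H, W)`` array for single-plane kinds or ``(H, W, 3)`` for RGB.
        Finite values in ``[0, 1]``; binary masks hold only 0 and 1.
    modality
        One of ``VIS``, ``FLU`` or ``synthetic``.
    channel_kind
        One of ``rgb``, ``gray``, ``edge``, ``binary_mask``.
    """

    pixels: np.ndarray
    modality: str = "synthetic"
    channel_kind: str = "gray"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel_kind {self.channel_kind!r}")
        if self.channel_kind == "rgb":
            if px.ndim != 3 or px.shape[2] != 3:
                raise ShapeError("rgb raster must have shape (H, W, 3)")
        else:
            if px.ndim != 2:
                raise ShapeError(
                    f"{self.channel_kind} raster must be 2-D, got shape {px.shape}"
                )
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ShapeError("image must be at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.channel_kind == "binary_mask":
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary_mask pixels must be 0 or 1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def is_rgb(self) -> bool:
        return self.channel_kind == "rgb"

    def with_pixels(self, pixels: np.ndarray, channel_kind: str | None = None) -> "ImageGrid":
        """Return a copy carrying new pixel data (same modality)."""
        return replace(
            self,
            pixels=pixels,
            channel_kind=self.channel_kind if channel_kind is None else channel_kind,
        )


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box ``[row_min, row_max) x [col_min, col_max)``."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise InvalidBoxError(
                f"degenerate box rows [{self.row_min}, {self.row_max}) "
                f"cols [{self.col_min}, {self.col_max})"
            )
        if self.row_min < 0 or self.col_min < 0:
            raise InvalidBoxError("box indices must be non-negative")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    def check_within(self, img: ImageGrid) -> None:
        if self.row_max > img.height or self.col_max > img.width:
            raise InvalidBoxError(
                f"box {self} exceeds image bounds {img.height}x{img.width}"
            )


def as_mask(arr: np.ndarray, modality: str = "synthetic") -> ImageGrid:
    """Wrap a boolean/0-1 array as a binary mask grid."""
    return ImageGrid(np.asarray(arr, dtype=np.float64), modality=modality,
                     channel_kind="binary_mask")
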