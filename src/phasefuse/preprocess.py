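"""Image preprocessing ahead of phase-correlation registration.

Multi-modal plant image pairs (fluorescence vs. visible light) are prepared
for frequency-domain alignment by combinations of: grayscale conversion or
color-edge extraction, removal of the blue growth mat, cropping to the plant
bounding box, and uniform pre-scaling of the FLU image to the VIS image
height. The eight standard variants are the cartesian product
{gray, edge} x {full, cropped} x {raw, filtered}.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters, transform

from .errors import ChannelError, EmptyMaskError, InvalidSizeError
from .grid import BoundingBox, ImageGrid, as_mask

#: Rec. 601 luma weights used for grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Default margin for the blue-dominance test (see :func:`remove_blue_background`).
DEFAULT_BLUE_DELTA = 0.05


def _require_rgb(img: ImageGrid) -> None:
    if not img.is_rgb:
        raise ChannelError(f"expected an rgb image, got {img.channel_kind}")


def to_grayscale(img: ImageGrid) -> ImageGrid:
    """Convert an RGB image to single-plane luminance.

    Uses the Rec. 601 weights (0.299, 0.587, 0.114); the weights sum to 1 so
    a uniform white image maps to 1.0 exactly.
    """
    _require_rgb(img)
    w = np.asarray(LUMA_WEIGHTS)
    gray = np.clip(img.pixels @ w, 0.0, 1.0)
    return ImageGrid(gray, modality=img.modality, channel_kind="gray")


def color_edges(img: ImageGrid) -> ImageGrid:
    """Color-edge magnitude image.

    Per-channel Sobel gradient magnitude, combined by per-pixel maximum over
    the three channels, then min-max rescaled to [0, 1]. Phase correlation
    relies heavily on edge information, so this variant emphasises structure
    shared between modalities while suppressing absolute intensity
    differences.
    """
    _require_rgb(img)
    mags = [filters.sobel(img.pixels[..., c]) for c in range(3)]
    edge = np.maximum.reduce(mags)
    mx = edge.max()
    if mx > 1e-12:  # guard: do not amplify numerical noise on flat images
        edge = edge / mx
    else:
        edge = np.zeros_like(edge)
    return ImageGrid(np.clip(edge, 0.0, 1.0), modality=img.modality,
                     channel_kind="edge")


def remove_blue_background(img: ImageGrid, delta: float = DEFAULT_BLUE_DELTA) -> ImageGrid:
    """Zero out blue-dominant pixels (the blue growth mat).

    A pixel is blue-dominant iff ``B > R + delta`` and ``B > G + delta``.
    Such pixels are set to 0 in all channels; everything else is untouched.
    """
    _require_rgb(img)
    r, g, b = img.pixels[..., 0], img.pixels[..., 1], img.pixels[..., 2]
    blue = (b > r + delta) & (b > g + delta)
    out = img.pixels.copy()
    out[blue] = 0.0
    return ImageGrid(out, modality=img.modality, channel_kind="rgb")


def prescale_to_height(img: ImageGrid, target_height: int) -> ImageGrid:
    """Uniformly rescale so the output height equals ``target_height``.

    The width scales by the same factor, rounded to the nearest integer
    (minimum 1 column is never reached for valid inputs since widths >= 2
    scale to >= 1 and are clipped to >= 2 via the grid invariant only when
    meaningful). Bilinear interpolation for intensities, nearest-neighbour
    for binary masks so mask bits stay exact.
    """
    if target_height < 2:
        raise InvalidSizeError(f"target height must be >= 2, got {target_height}")
    if target_height == img.height:
        return img
    factor = target_height / img.height
    target_width = max(2, int(round(img.width * factor)))
    out_shape = (target_height, target_width)
    if img.is_rgb:
        out_shape = out_shape + (3,)
    order = 0 if img.channel_kind == "binary_mask" else 1
    px = transform.resize(
        img.pixels, out_shape, order=order, mode="edge",
        anti_aliasing=(order != 0 and factor < 1.0), preserve_range=True,
    )
    px = np.clip(px, 0.0, 1.0)
    if img.channel_kind == "binary_mask":
        px = (px > 0.5).astype(np.float64)
    return ImageGrid(px, modality=img.modality, channel_kind=img.channel_kind)


def crop_to_bbox(img: ImageGrid, box: BoundingBox) -> ImageGrid:
    """Extract the sub-raster inside ``box`` (bit-exact)."""
    box.check_within(img)
    px = img.pixels[box.row_min:box.row_max, box.col_min:box.col_max].copy()
    return ImageGrid(px, modality=img.modality, channel_kind=img.channel_kind)


def plant_bbox(mask: ImageGrid, pad: int = 0) -> BoundingBox:
    """Tightest box around the mask foreground, expanded by ``pad`` pixels.

    The expanded box is clipped to the image bounds.
    """
    if mask.channel_kind != "binary_mask":
        raise ChannelError("plant_bbox expects a binary_mask image")
    rows, cols = np.nonzero(mask.pixels > 0.5)
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    return BoundingBox(
        row_min=max(0, int(rows.min()) - pad),
        col_min=max(0, int(cols.min()) - pad),
        row_max=min(mask.height, int(rows.max()) + 1 + pad),
        col_max=min(mask.width, int(cols.max()) + 1 + pad),
    )


def threshold_segment(img: ImageGrid, threshold: float | None = None) -> ImageGrid:
    """Global threshold segmentation: mask = 1 where intensity > threshold.

    With ``threshold=None`` the Otsu threshold of the image is used. This is
    the automated stand-in for interactive per-region segmentation; the
    fluorescence image's strong plant/background contrast makes a single
    global cut adequate there.
    """
    if img.is_rgb:
        raise ChannelError("threshold_segment expects a single-plane image")
    if threshold is None:
        threshold = float(filters.threshold_otsu(img.pixels))
    return as_mask(img.pixels > threshold, modality=img.modality)


def clean_mask(mask: ImageGrid, min_size: int = 0, closing_radius: int = 0) -> ImageGrid:
    """Optional morphological cleanup of a segmentation mask.

    Binary closing with a disc of ``closing_radius`` followed by removal of
    connected components smaller than ``min_size`` pixels. Both steps are
    no-ops at their defaults.
    """
    m = mask.pixels > 0.5
    if closing_radius > 0:
        r = closing_radius
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        m = ndimage.binary_closing(m, structure=(yy**2 + xx**2) <= r**2)
    if min_size > 0:
        lab, n = ndimage.label(m)
        if n:
            sizes = ndimage.sum_labels(m, lab, index=np.arange(1, n + 1))
            keep = np.concatenate(([False], sizes >= min_size))
            m = keep[lab]
    return as_mask(m, modality=mask.modality)
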