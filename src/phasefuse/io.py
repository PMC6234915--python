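"""Raster and report I/O.

PNG and TIFF rasters (8- and 16-bit) are read through imageio and
normalized to [0, 1] by the dtype maximum; binary masks are written as 0/255
PNGs so the round-trip preserves mask bits exactly. Tabular reports go
through pandas as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import PhasefuseError
from .fourier_mellin import RegistrationResult
from .grid import ImageGrid
from .transform import AffineTransform2D


def read_image(path, modality: str = "synthetic",
               channel_kind: str | None = None) -> ImageGrid:
    """Read a PNG/TIFF raster into an :class:`ImageGrid` in [0, 1]."""
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise PhasefuseError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim not in (2, 3):
        raise PhasefuseError(f"{path}: unsupported raster shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.bits not in (8, 16):
            raise PhasefuseError(f"{path}: unsupported bit depth {info.bits}")
        px = arr.astype(np.float64) / info.max
    elif np.issubdtype(arr.dtype, np.floating):
        px = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise PhasefuseError(f"{path}: unsupported dtype {arr.dtype}")
    if channel_kind is None:
        channel_kind = "rgb" if px.ndim == 3 else "gray"
    if channel_kind == "binary_mask":
        px = (px > 0.5).astype(np.float64)
    return ImageGrid(px, modality=modality, channel_kind=channel_kind)


def write_image(path, img: ImageGrid) -> None:
    """Write an intensity/RGB image as 8-bit PNG/TIFF."""
    arr = np.round(img.pixels * 255.0).astype(np.uint8)
    iio.imwrite(path, arr)


def write_mask(path, mask: ImageGrid) -> None:
    """Write a binary mask as a 0/255 single-plane PNG (bit-exact round-trip)."""
    if mask.channel_kind != "binary_mask":
        raise PhasefuseError("write_mask expects a binary_mask image")
    arr = np.where(mask.pixels > 0.5, 255, 0).astype(np.uint8)
    iio.imwrite(path, arr)


def read_mask(path, modality: str = "synthetic") -> ImageGrid:
    return read_image(path, modality=modality, channel_kind="binary_mask")


def write_transform(path, result: RegistrationResult) -> None:
    """Serialize a registration result as a JSON record."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def read_transform(path) -> AffineTransform2D:
    with open(path) as fh:
        return AffineTransform2D.from_dict(json.load(fh))


def write_report(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def sweep_report(results) -> pd.DataFrame:
    """Per-scale table of peak heights and transform components.

    Columns: scale, H, valid, T11, T12, T31, T32 (diagonal, off-diagonal and
    translational components of the affine matrix).
    """
    rows = [{"scale": r.scale_factor, "H": r.peak_height, "valid": r.valid,
             "T11": r.transform.t11, "T12": r.transform.t12,
             "T31": r.transform.t31, "T32": r.transform.t32}
            for r in results]
    return pd.DataFrame(rows)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
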