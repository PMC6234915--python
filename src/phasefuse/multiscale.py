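"""Scale-space sweep and integration of registrations into one mask.

A single affine transform cannot compensate non-uniform leaf motion between
the FLU and VIS exposures. Registering progressively downscaled copies of
the pair changes the spectral weighting (downscaling acts as smoothing), so
the phase-correlation peak locks onto different locally-optimal alignments
at different scale factors. Warping the FLU plant mask by every valid
per-scale transform and taking the pixelwise union yields an integrated
mask (IM) that covers plant configurations no single transform reaches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .errors import NoValidRegistrationError
from .fourier_mellin import (
    RegistrationConfig,
    RegistrationResult,
    ValidityBounds,
    register_affine,
    warp_image,
)
from .grid import ImageGrid, as_mask
from .preprocess import (
    color_edges,
    prescale_to_height,
    remove_blue_background,
    threshold_segment,
    to_grayscale,
)
from .transform import AffineTransform2D

logger = logging.getLogger(__name__)

#: Smallest image side (pixels) still registered during the sweep.
MIN_SWEEP_SIDE = 16


@dataclass(frozen=True)
class ScaleSweepConfig:
    """Configuration of the scale sweep.

    The default grid covers factors 0.1 to 1.0 in steps of 0.02 (46 scales);
    the upper end is always included so the full-resolution registration
    participates in the integration whenever it is valid.
    """

    scale_min: float = 0.1
    scale_max: float = 1.0
    step: float = 0.02
    variant: str = "edge"            # edge | gray; edge images share far more
                                     # structure across modalities
    filter_blue: bool = False
    h_threshold: float = 0.03
    bounds: ValidityBounds = field(default_factory=ValidityBounds)
    window: bool = True
    subpixel: bool = False
    integration: str = "union"       # union | majority
    flu_threshold: float | None = None  # None = Otsu

    def __post_init__(self):
        if not (0.0 < self.scale_min <= self.scale_max <= 1.0):
            raise ValueError("require 0 < scale_min <= scale_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def registration_config(self) -> RegistrationConfig:
        return RegistrationConfig(h_threshold=self.h_threshold,
                                  bounds=self.bounds, window=self.window,
                                  subpixel=self.subpixel)


@dataclass(frozen=True)
class SweepOutcome:
    """Everything a scale sweep produced for one image pair."""

    results: tuple[RegistrationResult, ...]
    integrated_mask: ImageGrid | None
    flu_mask: ImageGrid | None = None
    n_valid: int = 0

    @property
    def valid_results(self) -> list[RegistrationResult]:
        return [r for r in self.results if r.valid]


def scale_grid(cfg: ScaleSweepConfig) -> np.ndarray:
    """Inclusive scale grid: min, min+step, ... capped at max; max always kept."""
    n = int(math.floor((cfg.scale_max - cfg.scale_min) / cfg.step + 1e-9)) + 1
    grid = cfg.scale_min + cfg.step * np.arange(n)
    grid = np.round(grid, 12)  # keep factors clean despite float accumulation
    grid = np.minimum(grid, cfg.scale_max)
    if grid[-1] < cfg.scale_max - 1e-9:
        grid = np.append(grid, cfg.scale_max)
    else:
        grid[-1] = cfg.scale_max
    return grid


def _downscale(arr: np.ndarray, s: float) -> np.ndarray:
    """Anti-aliased downscaling; smoothing is the point of the sweep."""
    if s == 1.0:
        return arr
    out = sktransform.rescale(arr, s, order=1, anti_aliasing=True,
                              mode="reflect", preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def sweep_scales(flu: ImageGrid, vis: ImageGrid,
                 cfg: ScaleSweepConfig | None = None) -> list[RegistrationResult]:
    """Register the pair once per scale factor in the grid.

    Both single-plane images are downscaled by ``s``, registered single-step,
    and the recovered transform is mapped back to full-resolution
    coordinates (translation divided by ``s``; rotation and scale are scale
    invariant). Invalid registrations are retained with ``valid=False``;
    scales at which either image would drop below ``MIN_SWEEP_SIDE`` pixels
    a side are skipped with a log message.
    """
    cfg = cfg or ScaleSweepConfig()
    reg_cfg = cfg.registration_config()
    pf = flu.pixels
    pv = vis.pixels
    results: list[RegistrationResult] = []
    for s in scale_grid(cfg):
        s = float(s)
        min_side = min(pf.shape[0] * s, pf.shape[1] * s,
                       pv.shape[0] * s, pv.shape[1] * s)
        if min_side < MIN_SWEEP_SIDE:
            logger.info("scale %.2f skipped: downscaled side %.0f px < %d",
                        s, min_side, MIN_SWEEP_SIDE)
            continue
        res = register_affine(_downscale(pf, s), _downscale(pv, s),
                              config=reg_cfg, scale_factor=s)
        results.append(_rescale_result(res, s))
        logger.debug("scale %.2f: H=%.4f valid=%s", s, res.peak_height,
                     results[-1].valid)
    return results


def _rescale_result(res: RegistrationResult, s: float) -> RegistrationResult:
    """Map a transform estimated at scale ``s`` back to full resolution."""
    if s == 1.0:
        return res
    down = AffineTransform2D.scaling(s)
    t_full = down.inverse() @ res.transform @ down
    frame = None
    if res.frame_shape is not None:
        frame = (int(round(res.frame_shape[0] / s)),
                 int(round(res.frame_shape[1] / s)))
    return RegistrationResult(transform=t_full, peak_height=res.peak_height,
                              valid=res.valid, scale_factor=s,
                              frame_shape=frame, diagnostics=res.diagnostics)


def integrate_masks(flu_mask: ImageGrid, results,
                    vis_shape: tuple[int, int],
                    rule: str = "union") -> ImageGrid:
    """Combine per-scale registrations into a single integrated mask.

    Each valid result warps ``flu_mask`` (nearest-neighbour) into the VIS
    frame; the integrated mask is the pixelwise OR of the warped masks
    (``rule="union"``, default) or the pixelwise majority vote
    (``rule="majority"``).
    """
    valid = [r for r in results if r.valid]
    if not valid:
        raise NoValidRegistrationError(
            "no registration passed the validity gate",
            diagnostics=[{"scale": r.scale_factor, "peak_height": r.peak_height,
                          "valid": r.valid} for r in results])
    votes = np.zeros(vis_shape, dtype=np.int64)
    for r in valid:
        warped = warp_image(flu_mask, r.transform, vis_shape,
                            interpolation="nearest")
        votes += warped.pixels.astype(np.int64)
    if rule == "union":
        out = votes > 0
    elif rule == "majority":
        out = votes * 2 > len(valid)
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    return as_mask(out, modality="VIS")


def _to_plane(img: ImageGrid, variant: str) -> ImageGrid:
    if img.is_rgb:
        return color_edges(img) if variant == "edge" else to_grayscale(img)
    return img


def register_integrative(flu_rgb: ImageGrid, vis_rgb: ImageGrid,
                         cfg: ScaleSweepConfig | None = None,
                         flu_mask: ImageGrid | None = None) -> SweepOutcome:
    """End-to-end integrative registration of a raw FLU/VIS pair.

    Pipeline: optional blue-mat removal on the VIS image, grayscale or
    color-edge conversion, uniform pre-scaling of the FLU image to the VIS
    height, threshold segmentation of the FLU image (Otsu by default) unless
    a plant mask is supplied, the scale sweep, and mask integration.

    An all-invalid sweep yields an outcome with ``integrated_mask=None`` and
    ``n_valid=0`` instead of raising, so batch evaluation can count the
    failure.
    """
    cfg = cfg or ScaleSweepConfig()
    vis_in = vis_rgb
    if cfg.filter_blue and vis_rgb.is_rgb:
        vis_in = remove_blue_background(vis_rgb)
    vis_p = _to_plane(vis_in, cfg.variant)
    flu_p = _to_plane(flu_rgb, cfg.variant)
    flu_p = prescale_to_height(flu_p, vis_p.height)

    if flu_mask is None:
        flu_gray = flu_p if cfg.variant == "gray" else prescale_to_height(
            _to_plane(flu_rgb, "gray"), vis_p.height)
        flu_mask = threshold_segment(flu_gray, cfg.flu_threshold)
    else:
        flu_mask = prescale_to_height(flu_mask, vis_p.height)

    results = sweep_scales(flu_p, vis_p, cfg)
    n_valid = sum(r.valid for r in results)
    if n_valid == 0:
        return SweepOutcome(results=tuple(results), integrated_mask=None,
                            flu_mask=flu_mask, n_valid=0)
    mask = integrate_masks(flu_mask, results, vis_p.shape,
                           rule=cfg.integration)
    return SweepOutcome(results=tuple(results), integrated_mask=mask,
                        flu_mask=flu_mask, n_valid=n_valid)
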