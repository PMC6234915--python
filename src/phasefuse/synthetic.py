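"""Synthetic multi-modal (FLU/VIS-like) plant scene generator.

Produces image pairs with exact ground truth for benchmarking registration:
a plant-like foreground (elliptical leaves around a stem point, optional
thin stem) defined in the VIS frame, a known FLU-to-VIS similarity
transform, optional per-leaf rotations applied only in the VIS exposure
(emulating inertial leaf sway between the two acquisitions),
modality-specific VIS background clutter (carrier edges, illumination
gradients, marks), distinct intensity statistics per modality, and additive
Gaussian noise.

The scene geometry is analytic: leaves are mapped between frames by applying
the similarity transform to the ellipse parameters, so the ground-truth
masks are exact rasterizations rather than resampled images.

Emulated properties of real phenotyping-chamber pairs: differing camera
resolutions (FLU canvas at 0.6x the VIS linear size by default), high
plant/background contrast in FLU, cluttered and unevenly lit VIS background,
self-similar leaves, thin young shoots, and non-uniform leaf motion. Not
emulated: 3-D geometry, occlusion, specular reflections, photorealistic
texture — conclusions drawn from these scenes concern the registration
math, not botanical imaging realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ShapeError
from .grid import ImageGrid, as_mask
from .transform import AffineTransform2D

#: FLU linear size relative to VIS, echoing typical camera-resolution gaps.
DEFAULT_FLU_RATIO = 0.6

PRESET_NAMES = (
    "adult_structured",
    "young_thin_line",
    "rosette_selfsimilar",
    "nonuniform_motion",
    "cluttered_vis",
)


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse: center (x, y), semi-axes (a along the orientation, b
    across it), orientation in degrees (x toward y, i.e. clockwise on screen)."""

    cx: float
    cy: float
    a: float
    b: float
    theta_deg: float = 0.0

    def transformed(self, t: AffineTransform2D) -> "Ellipse":
        """Map through a similarity transform (exact for similarities)."""
        cx, cy = t.apply((self.cx, self.cy))
        s = t.scale
        return Ellipse(cx=cx, cy=cy, a=self.a * s, b=self.b * s,
                       theta_deg=self.theta_deg + t.rotation_deg)

    def rotated_about(self, px: float, py: float, delta_deg: float) -> "Ellipse":
        rot = AffineTransform2D.from_params(rotation_deg=delta_deg,
                                            center=(px, py))
        cx, cy = rot.apply((self.cx, self.cy))
        return replace(self, cx=cx, cy=cy, theta_deg=self.theta_deg + delta_deg)


@dataclass(frozen=True)
class ClutterSpec:
    """VIS-only background primitives: straight carrier edges, a smooth
    illumination gradient, and small rectangular marks."""

    n_lines: int = 2
    n_marks: int = 2
    gradient: bool = True
    line_intensity: float = 0.12
    mark_intensity: float = 0.85


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic FLU/VIS scene.

    All randomness used during rendering (noise) is driven by ``seed``; the
    geometry is explicit so ground truth is exact by construction.
    ``global_transform`` is the true FLU-to-VIS similarity;
    ``leaf_motions`` holds one extra rotation (degrees, about the plant
    base) per leaf, applied only in the VIS exposure.
    """

    canvas_shape: tuple[int, int]
    leaves: tuple[Ellipse, ...]
    leaf_motions: tuple[float, ...]
    global_transform: AffineTransform2D
    base_point: tuple[float, float]
    stem: Ellipse | None = None
    clutter: ClutterSpec | None = None
    noise_sigma: float = 0.05
    flu_ratio: float = DEFAULT_FLU_RATIO
    blue_mat: bool = False
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if len(self.leaf_motions) != len(self.leaves):
            raise ValueError("leaf_motions length must equal number of leaves")
        n, m = self.canvas_shape
        for e in self.leaves + ((self.stem,) if self.stem else ()):
            if not (0 <= e.cx < m and 0 <= e.cy < n):
                raise ShapeError(f"leaf center ({e.cx}, {e.cy}) outside canvas")

    @property
    def flu_shape(self) -> tuple[int, int]:
        return (max(2, int(round(self.canvas_shape[0] * self.flu_ratio))),
                max(2, int(round(self.canvas_shape[1] * self.flu_ratio))))


@dataclass(frozen=True)
class SyntheticPair:
    """Rendered pair plus exact ground truth."""

    flu: ImageGrid
    vis: ImageGrid
    flu_mask: ImageGrid
    vis_mask: ImageGrid
    true_transform: AffineTransform2D
    spec: SceneSpec


# ----------------------------------------------------------------------
# rasterization
# ----------------------------------------------------------------------

def _raster_ellipses(shape: tuple[int, int], ellipses) -> np.ndarray:
    """Exact binary rasterization of filled ellipses (pixel-center test)."""
    out = np.zeros(shape, dtype=bool)
    n, m = shape
    for e in ellipses:
        if e is None:
            continue
        r = max(e.a, e.b) + 2.0
        r0 = max(0, int(math.floor(e.cy - r)))
        r1 = min(n, int(math.ceil(e.cy + r)) + 1)
        c0 = max(0, int(math.floor(e.cx - r)))
        c1 = min(m, int(math.ceil(e.cx + r)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        th = math.radians(e.theta_deg)
        ct, st = math.cos(th), math.sin(th)
        dx = xx - e.cx
        dy = yy - e.cy
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        out[r0:r1, c0:c1] |= (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
    return out


def _vis_geometry(spec: SceneSpec) -> list[Ellipse]:
    px, py = spec.base_point
    moved = [leaf.rotated_about(px, py, d)
             for leaf, d in zip(spec.leaves, spec.leaf_motions)]
    if spec.stem is not None:
        moved.append(spec.stem)
    return moved


def _flu_geometry(spec: SceneSpec) -> list[Ellipse]:
    q = spec.global_transform.inverse()
    shapes = list(spec.leaves) + ([spec.stem] if spec.stem else [])
    return [e.transformed(q) for e in shapes]


def ground_truth_masks(spec: SceneSpec) -> tuple[ImageGrid, ImageGrid]:
    """Exact binary plant masks: (flu_mask in FLU frame, vis_mask in VIS frame)."""
    vis_mask = _raster_ellipses(spec.canvas_shape, _vis_geometry(spec))
    flu_mask = _raster_ellipses(spec.flu_shape, _flu_geometry(spec))
    return as_mask(flu_mask, modality="FLU"), as_mask(vis_mask, modality="VIS")


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _render_flu(spec: SceneSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fluorescence-like exposure: bright plant on near-black background."""
    inten = np.full(spec.flu_shape, 0.04)
    inten[mask] = 0.85
    inten = ndimage.gaussian_filter(inten, 1.0)
    rgb = np.stack([0.95 * inten, 0.30 * inten, 0.10 * inten], axis=-1)
    rgb += rng.normal(0.0, spec.noise_sigma, rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


def _render_vis(spec: SceneSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, m = spec.canvas_shape
    if spec.blue_mat:
        bg = np.array([0.28, 0.33, 0.62])
    else:
        bg = np.array([0.48, 0.46, 0.44])
    img = np.ones((n, m, 3)) * bg
    cl = spec.clutter
    if cl is not None:
        crng = np.random.default_rng(spec.seed + 7919)
        for _ in range(cl.n_lines):
            if crng.random() < 0.5:
                c = int(crng.uniform(0.03, 0.18) * m) if crng.random() < 0.5 \
                    else int(crng.uniform(0.82, 0.97) * m)
                img[:, c:c + 3, :] = cl.line_intensity
            else:
                r = int(crng.uniform(0.82, 0.97) * n)
                img[r:r + 3, :, :] = cl.line_intensity
        for _ in range(cl.n_marks):
            r = int(crng.uniform(0.05, 0.9) * n)
            c = int(crng.uniform(0.05, 0.9) * m)
            sz = int(crng.uniform(4, 10))
            img[r:r + sz, c:c + sz, :] = cl.mark_intensity
        if cl.gradient:
            gy = np.linspace(-0.12, 0.12, n)[:, None, None]
            gx = np.linspace(-0.08, 0.08, m)[None, :, None]
            img = img * (1.0 + gy + gx)
    # green plant, darker than the mat so it reads in grayscale too
    plant = np.array([0.10, 0.38, 0.12])
    img[mask] = plant
    img = ndimage.gaussian_filter(img, (0.8, 0.8, 0.0))
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_pair(spec: SceneSpec) -> SyntheticPair:
    """Render a FLU/VIS pair with exact ground truth from a scene spec.

    Deterministic given the spec (all randomness flows from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    flu_mask, vis_mask = ground_truth_masks(spec)
    flu_px = _render_flu(spec, flu_mask.pixels > 0.5, rng)
    vis_px = _render_vis(spec, vis_mask.pixels > 0.5, rng)
    return SyntheticPair(
        flu=ImageGrid(flu_px, modality="FLU", channel_kind="rgb"),
        vis=ImageGrid(vis_px, modality="VIS", channel_kind="rgb"),
        flu_mask=flu_mask,
        vis_mask=vis_mask,
        true_transform=spec.global_transform,
        spec=spec,
    )


# ----------------------------------------------------------------------
# scene construction
# ----------------------------------------------------------------------

def _global_transform(rng: np.random.Generator, spec_shape, flu_ratio,
                      max_rot: float = 5.0) -> AffineTransform2D:
    """Random plausible FLU-to-VIS similarity: resolution gap x residual pose."""
    n, m = spec_shape
    fn, fm = max(2, round(n * flu_ratio)), max(2, round(m * flu_ratio))
    s_rel = rng.uniform(0.95, 1.1)
    rot = rng.uniform(-max_rot, max_rot)
    shift = rng.uniform(-0.05, 0.05, size=2) * min(n, m)
    t = AffineTransform2D.from_params(
        scale=s_rel / flu_ratio, rotation_deg=rot,
        shift_x=float(m / 2 - fm / 2 + shift[0]),
        shift_y=float(n / 2 - fn / 2 + shift[1]),
        center=(fm / 2, fn / 2))
    return t


def make_scene(preset: str, seed: int = 0,
               canvas_shape: tuple[int, int] = (256, 256),
               noise_sigma: float = 0.05) -> SceneSpec:
    """Build a reproducible scene spec for a named difficulty preset.

    Presets
    -------
    ``adult_structured``
        Five well-developed leaves of varied size plus a stem; no leaf
        motion; light clutter. The easy regime.
    ``young_thin_line``
        A thin (<= 5 px wide) near-vertical shoot only, with carrier-edge
        clutter of similar shape — the redundant-shape failure mode of
        young shoots seen from unlucky view angles.
    ``rosette_selfsimilar``
        Six near-identical leaves in a rosette, inviting locally-optimal
        misalignments between similar leaves.
    ``nonuniform_motion``
        Five leaves of which two carry an extra rotation (4-10 degrees in
        magnitude, random sign) about the plant base in the VIS exposure:
        uncorrelated leaf sway that no single affine transform compensates.
    ``cluttered_vis``
        Adult plant with heavy VIS-only background clutter.
    """
    if preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}")
    rng = np.random.default_rng(seed)
    n, m = canvas_shape
    cx0 = m / 2 + rng.uniform(-0.04, 0.04) * m
    cy0 = n / 2 + rng.uniform(-0.04, 0.04) * n
    base = (cx0, cy0)
    scale = min(n, m) / 256.0

    leaves: list[Ellipse] = []
    stem = None
    motions: list[float] = []
    clutter = ClutterSpec()

    if preset == "young_thin_line":
        stem = Ellipse(cx=cx0, cy=cy0, a=rng.uniform(45, 60) * scale,
                       b=2.0 * scale, theta_deg=90.0 + rng.uniform(-4, 4))
        clutter = ClutterSpec(n_lines=3, n_marks=1)
    else:
        n_leaves = 6 if preset == "rosette_selfsimilar" else 5
        if preset == "rosette_selfsimilar":
            a0 = rng.uniform(30, 38) * scale
            b0 = rng.uniform(8, 11) * scale
        for i in range(n_leaves):
            ang = i * 360.0 / n_leaves + rng.uniform(-12, 12)
            if preset == "rosette_selfsimilar":
                a, b = a0, b0
            else:
                a = rng.uniform(24, 42) * scale
                b = rng.uniform(7, 13) * scale
            d = a + 4.0 * scale
            th = math.radians(ang)
            leaves.append(Ellipse(cx=cx0 + d * math.cos(th),
                                  cy=cy0 + d * math.sin(th),
                                  a=a, b=b, theta_deg=ang))
        if preset != "rosette_selfsimilar":
            stem = Ellipse(cx=cx0, cy=cy0 + 20 * scale, a=30 * scale,
                           b=3.0 * scale, theta_deg=90.0)
        if preset == "cluttered_vis":
            clutter = ClutterSpec(n_lines=4, n_marks=5)

    motions = [0.0] * len(leaves)
    if preset == "nonuniform_motion":
        moved = rng.choice(len(leaves), size=2, replace=False)
        for i in moved:
            motions[i] = float(rng.uniform(4.0, 10.0) * rng.choice((-1.0, 1.0)))

    flu_ratio = DEFAULT_FLU_RATIO
    t = _global_transform(rng, canvas_shape, flu_ratio)
    return SceneSpec(canvas_shape=canvas_shape, leaves=tuple(leaves),
                     leaf_motions=tuple(motions), global_transform=t,
                     base_point=base, stem=stem, clutter=clutter,
                     noise_sigma=noise_sigma, flu_ratio=flu_ratio,
                     blue_mat=(preset == "rosette_selfsimilar"),
                     seed=seed, name=preset)


def difficulty_presets() -> list[SceneSpec]:
    """One reproducible scene spec per named preset (fixed seeds)."""
    return [make_scene(name, seed=11 + i) for i, name in enumerate(PRESET_NAMES)]
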