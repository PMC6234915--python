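"""Fourier-Mellin phase correlation and similarity-transform registration.

Phase correlation (PC) computes the inverse Fourier transform of the
normalized cross-power spectrum (CPS) of two images. For two structurally
identical images that differ by a circular translation, the PC surface is a
Kronecker delta at the relative displacement; the height ``H`` of the global
maximum degrades gracefully with noise and structural dissimilarity and is
therefore used as a reliability score (default gate: ``H > 0.03``).

Rotation and isotropic scale are recovered by the Fourier-Mellin extension:
the magnitude spectra of the two images are resampled onto a log-polar grid,
where rotation becomes a translation along the angle axis and scaling a
translation along the log-radius axis, and PC is applied again. The full
registration chain is: pad to a common frame, window, estimate
rotation/scale, resample one image accordingly, estimate the residual
translation, and compose a similarity transform (isotropic scale + rotation
+ translation). Shear is outside the model.

``H`` normalization: the PC surface is the unnormalized-inverse DFT
(``numpy.fft.ifft2``) of the unit-modulus CPS, so two identical images give
a delta of height ~1 and the 0.03 gate is interpreted on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ShapeError, TransformError
from .grid import ImageGrid
from .transform import AffineTransform2D

#: Default reliability gate on the maximum PC peak height.
DEFAULT_H_THRESHOLD = 0.03

#: Guard below which CPS elements are zeroed instead of normalized.
CPS_EPS = 1e-12


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ValidityBounds:
    """Admissible ranges for a registration to count as successful.

    The peak-height gate is the primary criterion; these bounds reject
    transforms that are numerically fine but physically implausible for
    images taken seconds apart on the same facility.
    """

    scale_min: float = 0.5
    scale_max: float = 2.0
    rot_max_deg: float = 30.0
    shift_max_frac: float = 0.5


@dataclass(frozen=True)
class RegistrationConfig:
    h_threshold: float = DEFAULT_H_THRESHOLD
    bounds: ValidityBounds = field(default_factory=ValidityBounds)
    window: bool = True
    subpixel: bool = False
    estimate_rotation: bool = True


# ----------------------------------------------------------------------
# result containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationSurface:
    """Real-valued PC map with its global maximum.

    ``wrapped_shift`` is the (dx, dy) displacement after frequency-wrap
    disambiguation: peak coordinates above half the extent map to negative
    shifts, so ``|dx| <= W/2`` and ``|dy| <= H/2``.
    """

    values: np.ndarray
    peak_row: int
    peak_col: int
    peak_height: float
    wrapped_shift: tuple[float, float]


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one single-step registration.

    ``transform`` maps source (FLU) pixel coordinates into target (VIS)
    pixel coordinates at the resolution the registration was run at (the
    sweep rescales it back to full resolution). ``scale_factor`` records the
    sweep downscaling factor that produced the result (1.0 for single-step).
    """

    transform: AffineTransform2D
    peak_height: float
    valid: bool
    scale_factor: float = 1.0
    frame_shape: tuple[int, int] | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.transform.to_dict()
        d.update(H=self.peak_height, valid=bool(self.valid),
                 scale_factor=self.scale_factor)
        return d


# ----------------------------------------------------------------------
# spectral primitives
# ----------------------------------------------------------------------

def cross_power_spectrum(alpha: np.ndarray, beta: np.ndarray,
                         eps: float = CPS_EPS) -> np.ndarray:
    """Normalized cross-power spectrum ``alpha * conj(beta) / |alpha * conj(beta)|``.

    Elements whose modulus falls below ``eps`` are set to 0 rather than
    divided, so spectral nulls do not inject arbitrary phases.
    """
    alpha = np.asarray(alpha)
    beta = np.asarray(beta)
    if alpha.shape != beta.shape:
        raise ShapeError(f"spectra differ in shape: {alpha.shape} vs {beta.shape}")
    prod = alpha * np.conj(beta)
    mod = np.abs(prod)
    out = np.zeros_like(prod)
    ok = mod >= eps
    out[ok] = prod[ok] / mod[ok]
    return out


def _wrap(index: int, size: int) -> float:
    return float(index - size) if index > size // 2 else float(index)


def _as_plane(img) -> np.ndarray:
    if isinstance(img, ImageGrid):
        if img.is_rgb:
            raise ShapeError("phase correlation requires single-plane images")
        return img.pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError("phase correlation requires 2-D arrays")
    return arr


def phase_correlation(a, b, subpixel: bool = False) -> CorrelationSurface:
    """Phase correlation between two equally sized single-plane images.

    Returns the PC surface whose maximum locates the displacement of ``b``
    relative to ``a``: if ``b`` equals ``a`` circularly shifted by
    ``(dy, dx)`` (rows, cols), the peak sits at ``(dy, dx)`` and
    ``wrapped_shift`` reports ``(dx, dy)`` in the signed range.

    On equal maxima the lexicographically smallest (row, col) wins, which is
    what ``argmax`` on a C-ordered array yields. With ``subpixel=True`` the
    wrapped shift is refined by a 3x3 center-of-mass around the peak (the
    integer peak location is unchanged).
    """
    pa = _as_plane(a)
    pb = _as_plane(b)
    if pa.shape != pb.shape:
        raise ShapeError(f"images differ in shape: {pa.shape} vs {pb.shape}")
    if not pa.any() or not pb.any():
        raise DegenerateInputError("all-zero image has no phase information")
    fa = np.fft.fft2(pa)
    fb = np.fft.fft2(pb)
    # beta*conj(alpha) puts the delta at +shift for b = roll(a, shift)
    cps = cross_power_spectrum(fb, fa)
    surface = np.real(np.fft.ifft2(cps))
    idx = int(np.argmax(surface))
    peak_row, peak_col = divmod(idx, surface.shape[1])
    height = float(surface[peak_row, peak_col])
    dy = _wrap(peak_row, surface.shape[0])
    dx = _wrap(peak_col, surface.shape[1])
    if subpixel:
        dy, dx = _com_refine(surface, peak_row, peak_col, dy, dx)
    return CorrelationSurface(values=surface, peak_row=peak_row,
                              peak_col=peak_col, peak_height=height,
                              wrapped_shift=(dx, dy))


def _com_refine(surface: np.ndarray, r: int, c: int, dy: float, dx: float):
    """3x3 center-of-mass refinement around the integer peak."""
    h, w = surface.shape
    win = surface[np.ix_([(r - 1) % h, r, (r + 1) % h],
                         [(c - 1) % w, c, (c + 1) % w])]
    win = np.clip(win, 0.0, None)
    tot = win.sum()
    if tot <= 0:
        return dy, dx
    off = np.arange(-1, 2, dtype=float)
    return dy + float(off @ win.sum(axis=1)) / tot, dx + float(off @ win.sum(axis=0)) / tot


# ----------------------------------------------------------------------
# windowing, padding, log-polar resampling
# ----------------------------------------------------------------------

def hann_window(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def pad_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad to ``shape``, anchored at the top-left corner."""
    if arr.shape == tuple(shape):
        return arr
    out = np.zeros(shape, dtype=arr.dtype)
    out[: arr.shape[0], : arr.shape[1]] = arr
    return out


def common_frame(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
    return pad_to(a, shape), pad_to(b, shape)


def logpolar_params(shape: tuple[int, int],
                    n_theta: int | None = None,
                    n_radius: int | None = None) -> dict:
    """Resolution and radial range of the log-polar grid for ``shape``.

    Angle bins cover [0, 180) degrees (the magnitude spectrum is symmetric
    under 180-degree rotation); the log-radius axis spans [1, min(N, M)/2].
    """
    n, m = shape
    if n_theta is None:
        n_theta = max(n, m)
    if n_radius is None:
        n_radius = max(n, m) // 2
    r_min = 1.0
    r_max = min(n, m) / 2.0
    # per-bin ratio of the geometric radial grid
    base = (r_max / r_min) ** (1.0 / (n_radius - 1))
    return dict(n_theta=n_theta, n_radius=n_radius, r_min=r_min,
                r_max=r_max, base=base)


def _highpass(shape: tuple[int, int]) -> np.ndarray:
    """Radially symmetric high-emphasis filter (1 - X)(2 - X), X = cos pi fx cos pi fy."""
    fy = np.fft.fftshift(np.fft.fftfreq(shape[0]))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(shape[1]))[None, :]
    x = np.cos(np.pi * fy) * np.cos(np.pi * fx)
    return (1.0 - x) * (2.0 - x)


def logpolar_magnitude(img, n_theta: int | None = None,
                       n_radius: int | None = None,
                       window: bool = True) -> ImageGrid:
    """Windowed, high-pass-filtered FFT magnitude on a log-polar grid.

    Rows index the angle (0 to 180 degrees, exclusive), columns the
    log-radius. A rotation of the input becomes a circular shift along the
    angle axis; isotropic scaling becomes a shift along the log-radius axis.
    """
    p = _as_plane(img)
    if not np.ptp(p) > 0:
        raise DegenerateInputError("constant image has a degenerate spectrum")
    if window:
        p = p * hann_window(p.shape)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(p)))
    mag *= _highpass(p.shape)
    lp = logpolar_params(p.shape, n_theta, n_radius)
    cy = p.shape[0] / 2.0
    cx = p.shape[1] / 2.0
    theta = np.linspace(0.0, np.pi, lp["n_theta"], endpoint=False)[:, None]
    k = np.arange(lp["n_radius"])[None, :]
    radius = lp["r_min"] * lp["base"] ** k
    rows = cy + radius * np.sin(theta)
    cols = cx + radius * np.cos(theta)
    samp = ndimage.map_coordinates(mag, [rows, cols], order=1, mode="constant",
                                   cval=0.0)
    mx = samp.max()
    if mx > 0:
        samp = samp / mx
    return ImageGrid(samp, modality="synthetic", channel_kind="gray")


# ----------------------------------------------------------------------
# rotation / scale / translation estimation
# ----------------------------------------------------------------------

def _center(shape: tuple[int, int]) -> tuple[float, float]:
    return shape[1] / 2.0, shape[0] / 2.0  # (cx, cy)


def estimate_rotation_scale(a, b, window: bool = True,
                            subpixel: bool = False):
    """Rotation (deg) and isotropic scale of ``b`` relative to ``a``.

    Runs phase correlation on the log-polar magnitude spectra. The peak's
    angular shift gives the rotation, its radial shift the scale. Because
    the magnitude spectrum is invariant under 180-degree rotation, both
    candidates (theta, theta + 180) are disambiguated by the caller (see
    :func:`register_affine`); this function returns the principal candidate
    in (-90, 90].

    Returns ``(rotation_deg, scale, H_rs)`` with ``H_rs`` the log-polar PC
    peak height.
    """
    pa = _as_plane(a)
    pb = _as_plane(b)
    if pa.shape != pb.shape:
        raise ShapeError("rotation/scale estimation requires equal shapes")
    lp = logpolar_params(pa.shape)
    la = logpolar_magnitude(pa, window=window)
    lb = logpolar_magnitude(pb, window=window)
    surf = phase_correlation(la, lb, subpixel=subpixel)
    d_col, d_row = surf.wrapped_shift  # (radial bins, angle bins)
    # b rotated by +theta shifts its log-polar rows by +theta bins;
    # b scaled up by s shifts the log-radius axis by -log_base(s) bins.
    rotation = d_row * (180.0 / lp["n_theta"])
    scale = lp["base"] ** (-d_col)
    return rotation, scale, surf.peak_height


def warp_image(img, t: AffineTransform2D, out_shape: tuple[int, int],
               interpolation: str = "linear"):
    """Resample ``img`` into the target frame through similarity ``t``.

    ``t`` maps source coordinates to target coordinates; the resampler pulls
    each output pixel from ``t^{-1}``. ``interpolation`` is ``linear`` for
    intensities or ``nearest`` for masks; out-of-domain pixels are 0.
    """
    if not t.is_invertible:
        raise TransformError("cannot warp through a singular transform")
    if isinstance(img, ImageGrid):
        interp = "nearest" if img.channel_kind == "binary_mask" and interpolation == "linear" \
            else interpolation
        out = _warp_array(img.pixels, t, out_shape, interp)
        if img.channel_kind == "binary_mask":
            out = (out > 0.5).astype(np.float64)
        return ImageGrid(np.clip(out, 0.0, 1.0), modality=img.modality,
                         channel_kind=img.channel_kind)
    return _warp_array(np.asarray(img, dtype=np.float64), t, out_shape,
                       interpolation)


def _warp_array(arr: np.ndarray, t: AffineTransform2D,
                out_shape: tuple[int, int], interpolation: str) -> np.ndarray:
    inv = t.inverse().matrix
    # convert (x, y) convention to scipy's (row, col): row=y, col=x
    mat_rc = np.array([[inv[1, 1], inv[1, 0]],
                       [inv[0, 1], inv[0, 0]]])
    off_rc = np.array([inv[1, 2], inv[0, 2]])
    order = 0 if interpolation == "nearest" else 1
    if arr.ndim == 3:
        planes = [ndimage.affine_transform(arr[..., c], mat_rc, offset=off_rc,
                                           output_shape=out_shape, order=order,
                                           mode="constant", cval=0.0)
                  for c in range(arr.shape[2])]
        return np.stack(planes, axis=-1)
    return ndimage.affine_transform(arr, mat_rc, offset=off_rc,
                                    output_shape=out_shape, order=order,
                                    mode="constant", cval=0.0)


def validate_transform(result: RegistrationResult,
                       bounds: ValidityBounds | None = None,
                       h_threshold: float = DEFAULT_H_THRESHOLD) -> bool:
    """Gate a registration on peak height and plausibility bounds.

    True iff ``H > h_threshold`` (strict), the recovered scale lies in
    ``[scale_min, scale_max]``, ``|rotation| <= rot_max_deg`` and both shift
    components are at most ``shift_max_frac`` of the frame extent. With no
    recorded frame shape the shift bound is skipped.
    """
    bounds = bounds or ValidityBounds()
    t = result.transform
    if not np.all(np.isfinite(t.matrix)) or not t.is_invertible:
        return False
    if not result.peak_height > h_threshold:
        return False
    if not (bounds.scale_min <= t.scale <= bounds.scale_max):
        return False
    if abs(t.rotation_deg) > bounds.rot_max_deg:
        return False
    if result.frame_shape is not None:
        ext = max(result.frame_shape)
        if max(abs(t.shift_x), abs(t.shift_y)) > bounds.shift_max_frac * ext:
            return False
    return True


def _translation_stage(ref: np.ndarray, mov: np.ndarray, window: bool,
                       subpixel: bool):
    """PC translation of ``mov`` relative to ``ref`` (windowed)."""
    if window:
        w = hann_window(ref.shape)
        ref = ref * w
        mov = mov * w
    surf = phase_correlation(ref, mov, subpixel=subpixel)
    return surf.wrapped_shift, surf.peak_height


def register_affine(flu, vis, config: RegistrationConfig | None = None,
                    scale_factor: float = 1.0) -> RegistrationResult:
    """Full Fourier-Mellin registration of a FLU/VIS single-plane pair.

    Pads both images to a common frame, estimates rotation and isotropic
    scale from the log-polar magnitude spectra, resamples the FLU image
    accordingly, estimates the residual translation, and composes the
    similarity transform mapping FLU into VIS coordinates. The 180-degree
    rotation ambiguity of the magnitude spectrum is resolved by trying both
    candidates and keeping the one whose translation PC peak is higher.

    Degenerate inputs and non-finite transforms yield a failure result
    (``valid=False``, identity transform) rather than an exception.
    """
    cfg = config or RegistrationConfig()
    try:
        pf = _as_plane(flu)
        pv = _as_plane(vis)
        pf, pv = common_frame(pf, pv)
        frame = pf.shape
        center = _center(frame)
        diagnostics: dict = {}
        candidates: list[tuple[float, float]] = [(0.0, 1.0)]
        if cfg.estimate_rotation:
            rot, sc, h_rs = estimate_rotation_scale(pf, pv, window=cfg.window,
                                                    subpixel=cfg.subpixel)
            diagnostics["H_rotation_scale"] = h_rs
            alt = rot + 180.0 if rot <= 0 else rot - 180.0
            candidates = [(rot, sc), (alt, sc)]

        best = None
        for rot, sc in candidates:
            sim = AffineTransform2D.from_params(scale=sc, rotation_deg=rot,
                                               center=center)
            if not sim.is_invertible:
                continue
            moved = warp_image(pf, sim, frame, interpolation="linear")
            if not np.asarray(moved).any():
                continue
            (dx, dy), h = _translation_stage(moved, pv, cfg.window, cfg.subpixel)
            if best is None or h > best[0]:
                best = (h, rot, sc, dx, dy)
        if best is None:
            raise DegenerateInputError("no usable rotation/scale candidate")
        h, rot, sc, dx, dy = best
        t = AffineTransform2D.translation(dx, dy) @ AffineTransform2D.from_params(
            scale=sc, rotation_deg=rot, center=center)
        diagnostics["H_translation"] = h
        result = RegistrationResult(transform=t, peak_height=h, valid=False,
                                    scale_factor=scale_factor,
                                    frame_shape=frame, diagnostics=diagnostics)
        valid = validate_transform(result, cfg.bounds, cfg.h_threshold)
        return RegistrationResult(transform=t, peak_height=h, valid=valid,
                                  scale_factor=scale_factor, frame_shape=frame,
                                  diagnostics=diagnostics)
    except (DegenerateInputError, TransformError) as exc:
        return RegistrationResult(transform=AffineTransform2D.identity(),
                                  peak_height=0.0, valid=False,
                                  scale_factor=scale_factor, frame_shape=None,
                                  diagnostics={"error": str(exc)})
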