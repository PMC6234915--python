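# Methods

## Registration model

`phasefuse` models the FLU→VIS relation as a 2-D similarity transform
(isotropic scale `s`, rotation `θ`, translation `(tx, ty)`) — the family
that Fourier–Mellin phase correlation can recover. Shear and non-rigid
deformation are outside the model; non-uniform leaf motion is instead
handled downstream by mask integration. Transform matrices act on column
vectors `(x, y, 1)ᵀ` with `x` = column, `y` = row, origin at the top-left;
for reporting, the components are exposed under the row-vector naming
convention `T11` (diagonal), `T12` (off-diagonal), `T31`, `T32`
(translation).

### Phase correlation

`PC = F⁻¹(αβ*/|αβ*|)`. Implementation choices:

- **H normalization.** The surface is the plain `numpy.fft.ifft2` of the
  unit-modulus CPS, so identical images give a delta of height 1 and the
  reliability gate `H > 0.03` (strict) is interpreted on that scale. The
  gate's numeric value is tied to this normalization. It is also tied to
  image size: the expected peak height between *unrelated* images scales
  like `√(2 ln NM / NM)`, about 0.02 at 256×256 and far lower at
  camera-native megapixel sizes. At frames much below ~200 px the noise
  floor crosses 0.03 and the gate loses its meaning; the plausibility
  bounds below then carry more of the gating.
- **ε-guard.** CPS elements with `|αβ*| < 1e−12` are set to 0 instead of
  normalized, so spectral nulls contribute no arbitrary phase.
- **Peak handling.** Integer argmax; ties break to the lexicographically
  smallest (row, col). Peak coordinates above half the extent wrap to
  negative shifts. A 3×3 center-of-mass sub-pixel refinement exists but is
  off by default.
- **Windowing.** `register_affine` applies a Hann window before every FFT
  to suppress wrap-around edges of non-periodic scenes. The raw
  `phase_correlation` primitive is unwindowed, which keeps the shift
  theorem exact on circular shifts.

### Rotation/scale stage

The magnitude spectra (windowed, high-pass filtered with the radially
symmetric high-emphasis profile `(1 − X)(2 − X)`, `X = cos πfx · cos πfy`)
are resampled onto a log-polar grid: angle bins = max image side covering
[0°, 180°) (the magnitude spectrum is symmetric under 180° rotation),
radial bins = half that, geometric radii spanning [1, min(N, M)/2]. On this
grid a rotation of `+θ` shifts the angle axis by `+θ` bins and an upscaling
by `s` shifts the log-radius axis by `−log_base s` bins; both conversions
were fixed against ground-truth similarity warps. The 180° ambiguity is
resolved by running the subsequent translation stage for both candidates
and keeping the higher translation peak. Rotation/scale resolution is
therefore one angular bin (≈ 0.7° at 256 px) and one radial bin
(≈ 4–5 % in scale) — error bars inherited by everything downstream.

### Validity gating

A registration is *valid* iff `H > 0.03` **and** `s ∈ [0.5, 2]`,
`|θ| ≤ 30°`, `|shift| ≤ 0.5 ×` frame extent. The bounds encode that the
two exposures are seconds apart on the same facility; they are package
defaults, configurable per run.

## Scale sweep and mask integration

Both preprocessed images are downscaled by each factor in
`0.1, 0.12, …, 1.0` (46 factors; anti-aliased area resampling, since the
smoothing effect of downscaling is the point), registered single-step, and
the transform mapped back to full resolution (translation ÷ factor).
Scales at which an image would fall below 16 px a side are skipped with a
log message. The FLU plant mask — Otsu-thresholded from the FLU grayscale
unless supplied — is warped (nearest-neighbour) by every valid transform
and the warps are OR-combined into the integrated mask. A majority-vote
rule is available behind `integration="majority"`; union is the default
because coverage, not consensus, is the goal. Invalid registrations are
excluded and logged.

## Preprocessing

Eight variants: {grayscale, color-edge} × {full, cropped} × {raw,
blue-filtered}. Grayscale uses Rec. 601 luma weights. The color-edge
operator is per-channel Sobel magnitude combined by per-pixel maximum and
min-max rescaled — a deterministic stand-in for published color-edge
detectors, chosen because phase correlation keys on edge structure;
equivalence with any particular published operator is not claimed. Blue-mat
removal zeroes pixels with `B > R + δ` and `B > G + δ` (δ = 0.05). FLU
images are uniformly pre-scaled to the VIS height (width = rounded
proportional, bilinear for intensities, nearest for masks) *after* any
background filtering — the order is fixed and documented here because both
orders are defensible. **The sweep default is the edge variant**: on
unsegmented multi-modal pairs the grayscale images differ mostly by
modality-specific intensity statistics, while edge images retain the
structure the modalities share; the grayscale variant remains available
and is the better choice for already-segmented inputs.

## Synthetic scenes

The generator builds plant geometry (elliptical leaves around a base point,
optional thin stem) in the VIS frame, maps it analytically through the
inverse of the true similarity transform into a FLU frame at 0.6× linear
resolution (echoing real camera gaps), and rasterizes exactly — ground
truth is geometric, not resampled. FLU renders bright-on-dark with a
fluorescence-like tint; VIS renders a green plant that is darker than the
mat in luma, with VIS-only clutter (carrier-edge lines, small bright marks,
a smooth illumination gradient) and optional blue mat. Both get additive
Gaussian noise (σ = 0.05 default). Per-leaf motion rotates selected leaves
about the plant base in the VIS exposure only; the `nonuniform_motion`
preset moves 2 of 5 leaves by 4–10° in magnitude with random sign —
pronounced but plausible inertial sway. Scenes are 256×256 by default, a
size at which each full sweep takes well under two seconds.

What the scenes do **not** emulate: 3-D geometry and perspective,
occlusion, specular reflection, texture, illumination drift between
exposures, and real sensor noise. Passing tests demonstrate the
registration mathematics under controlled structural differences, not
performance on any particular facility's imagery.

## Numerical and degenerate-input behavior

All-zero or constant images raise a degenerate-input error from the
spectral primitives; `register_affine` converts any such failure into a
`valid=False` result so batch runs continue. Singular transforms are
rejected at construction (determinant tolerance 1e−9). Mask warps binarize
at 0.5 after interpolation. Scale-grid arithmetic rounds to 12 decimals so
the factor list is clean despite float accumulation, and the upper end of
the grid is always included.

## Known limitations

- Full coverage of strongly moved leaves requires that some per-scale
  registration locks onto them. With one PC maximum per scale the recovered
  rotations cluster within a few degrees of the global pose, so on scenes
  with ~10° leaf motion the integrated mask typically covers 95–100 % of
  the true plant region rather than exactly 100 %; a multi-peak search in
  each PC surface would close the gap but is deliberately out of scope.
- The mask-transfer resolution is bounded by the coarser FLU raster: at
  256 px canvases the FLU→VIS resampling slack alone costs a few percent of
  boundary overlap, shrinking roughly linearly with resolution.
- The `H > 0.03` gate does not transfer to other PC normalizations or to
  very small frames (see above).
- Thin, featureless shoots (the `young_thin_line` preset) remain the
  hardest case: their spectra resemble those of carrier edges, and
  single-step success rates are accordingly lower — the qualitative
  difficulty ordering the evaluation suite asserts.
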