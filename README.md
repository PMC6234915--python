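# phasefuse

Integrative Fourier–Mellin phase-correlation registration of multi-modal
plant images.

High-throughput plant phenotyping chambers photograph the same plant with
different cameras seconds apart — typically a fluorescence (FLU) image, in
which chlorophyll makes the shoot stand out against a dark background, and a
visible-light (VIS) image, which is cluttered with carriers, walls and mats
and is hard to segment directly. If the FLU image can be aligned onto the
VIS image, the easily obtained FLU plant mask segments the VIS image for
free (*segmentation via registration*). The catch: the two images differ
not only by translation, rotation and scale but also *structurally* —
background objects appear in one modality only, and individual leaves sway
between the two exposures, a non-rigid motion that no single affine
transform can compensate.

`phasefuse` implements a frequency-domain registration pipeline for this
problem, aimed at image-analysis developers and phenotyping researchers who
need automated FLU→VIS mask transfer:

- **Phase correlation (PC).** For images `A`, `B` with Fourier transforms
  `α = F(A)`, `β = F(B)`, the normalized cross-power spectrum is
  `CPS = αβ* / |αβ*|` and `PC = F⁻¹(CPS)`. For a pure shift
  `B(x, y) = A(x − Δx, y − Δy)` the PC surface is a delta at `(Δx, Δy)`;
  the height `H` of its maximum is a reliability score, gated at
  `H > 0.03`.
- **Fourier–Mellin extension.** Applying PC to log-polar resamplings of the
  two magnitude spectra turns rotation and isotropic scale into
  translations, so a full similarity transform (scale, rotation, shift) is
  recovered in two PC stages.
- **Scale sweep + integrated mask.** The pair is registered at downscaling
  factors 0.1–1.0 (step 0.02). Downscaling acts as smoothing, so different
  scales lock onto different locally-optimal alignments (e.g. different
  subsets of leaves). The FLU plant mask warped by every *valid*
  registration is OR-combined into a single integrated mask (IM) that
  covers plant parts no single transform reaches.
- **Evaluation.** Success rate `SR = ns/n` (fraction of pairs passing the
  validity gate) and overlap ratio `OR = ar/a` (fraction of the reference
  plant region covered by the registered mask).
- **Synthetic benchmark scenes** with exact ground truth: self-similar
  rosettes, thin young shoots, VIS-only clutter, and per-leaf motion.

## Worked example

```python
from phasefuse import (ScaleSweepConfig, generate_pair, make_scene,
                       overlap_ratio, register_integrative)

pair = generate_pair(make_scene("nonuniform_motion", seed=7))
print("leaf motions (deg):", [round(d, 1) for d in pair.spec.leaf_motions])

outcome = register_integrative(pair.flu, pair.vis, ScaleSweepConfig())
print(f"valid registrations: {outcome.n_valid}/{len(outcome.results)}")
best = max(outcome.valid_results, key=lambda r: r.peak_height)
print(f"best peak height H = {best.peak_height:.3f} "
      f"at scale factor {best.scale_factor:.2f}")
print(f"integrated-mask overlap ratio OR = "
      f"{overlap_ratio(outcome.integrated_mask, pair.vis_mask):.4f}")
```

prints

```
leaf motions (deg): [0.0, 0.0, 0.0, 9.9, 5.3]
valid registrations: 27/46
best peak height H = 0.662 at scale factor 0.10
integrated-mask overlap ratio OR = 0.9891
```

Two of the five leaves moved by 9.9° and 5.3° between the exposures; 27 of
the 46 per-scale registrations passed the `H > 0.03` + plausibility gate,
and their union covers 98.9 % of the true VIS plant region — more than any
single registration achieves on this pair.

The same pipeline is available from the shell:

```sh
phasefuse simulate --preset nonuniform_motion --seed 7 --out pair/
phasefuse sweep --flu pair/flu.png --vis pair/vis.png --out sweep/
phasefuse register --flu pair/flu.png --vis pair/vis.png --out transform.json
phasefuse evaluate --pairs manifest.csv --out report.csv
```

`sweep/` receives one transform JSON per scale, `sweep_report.csv`
(columns `scale, H, valid, T11, T12, T31, T32`) and `integrated_mask.png`.

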