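# corneatopo

Dynamic anterior corneal curvature topography from air-puff Scheimpflug
(Corvis ST-style) image sequences.

During a non-contact tonometry measurement, an air puff deforms the cornea
while an ultra-high-speed Scheimpflug camera films a cross-section of the
anterior eye (140 frames of 200 × 576 px, 0.016 mm/px). The cornea moves
inward, passes through a point of highest concavity, and rebounds. Static
instruments report the anterior corneal curvature (ACC) only at rest;
`corneatopo` recovers it per column and per frame, and renders the whole
deformation cycle as a pseudo-color curvature video fused into the original
gray frames — the kind of dynamic readout that is informative for corneal
biomechanics and keratoconus screening.

## Method

The pipeline has three stages:

1. **Segmentation.** Eyelash/tear artifacts are removed by a morphological
   closing (10 × 60 px element) followed by a connected-component area filter
   (keep components ≥ 1/3 of the largest). Boundaries are then traced on
   *local-phase* feature maps computed from a log-Gabor quadrature filter
   bank: phase symmetry (ridge detector, even responses dominate)

   Sym(x) = Σₙ ⌊|eₙ(x)| − |oₙ(x)| − T⌋ / (Σₙ Aₙ(x) + ε)

   highlights the corneal midline, and phase asymmetry (the same expression
   with |oₙ| − |eₙ|, a step-edge detector) highlights the anterior and
   posterior surfaces. Per column, the midline is the median of
   supra-threshold symmetry rows (τ = 0.1), and the two boundary points are
   the bright asymmetry points nearest the midline on either side; each curve
   is smoothed with a degree-5 polynomial least-squares fit.
2. **Curvature.** For every column, a window of 27 px on each side of the
   target point on the anterior curve is fit with a circle by minimizing the
   squared *area* error

   J = Σᵢ [πR² − π((xᵢ−x_c)² + (yᵢ−y_c)²)]²

   which becomes linear in (R² − x_c² − y_c², 2x_c, 2y_c) and solves in
   closed form — no initial guess, no iteration. The signed radius (positive
   convex toward the camera, negative during concavity) is reported in mm.
3. **Visualization.** Signed radii are mapped to [0, 1] by a fixed piecewise
   normalization (breakpoints −35/7/10/35 mm; the steep central branch spans
   the physiological 7–10 mm range), pseudo-colored with a blue→red rainbow
   palette, and fused into a 21-px strip along the anterior boundary in
   CIECAM02 appearance space: lightness J from the gray frame, hue quadrature
   H and saturation s from the pseudo-color, then inverse-transformed to
   sRGB. One palette serves the whole video, so colors are comparable across
   deformation stages.

A synthetic acquisition generator (`corneatopo.synthetic`) renders
Corvis-like frames — circular-arc band, uneven illumination, speckle noise,
eyelash strokes, raised-cosine deformation pulse — with exact analytic ground
truth, so every stage is validated without any patient data.

## Worked example

```python
import numpy as np
from corneatopo import (SyntheticConfig, make_frame, process_frame,
                        PipelineConfig, normalize_radius)
from corneatopo.metrics import cct

config = PipelineConfig()
scene = SyntheticConfig(anterior_radius_mm=7.8, cct_mm=0.55, noise_sigma=0.01)
frame, truth = make_frame(scene, t=0)          # rest-phase frame

seg, profile = process_frame(frame, config)    # segment + sliding circle fit
center = scene.n_cols // 2
print(f"anterior radius at apex : {profile.radius_mm[center]:.3f} mm")
print(f"central corneal thickness: {cct(seg, 0.016):.3f} mm")
print(f"normalized radius R_new : {normalize_radius(profile.radius_mm[center]):.4f}")
```

prints

```
anterior radius at apex : 7.962 mm
central corneal thickness: 0.536 mm
normalized radius R_new : 0.5043
```

against a ground truth of 7.800 mm radius and 0.550 mm thickness: the
curvature is recovered to ~2 % and the thickness to under a pixel
(0.016 mm/px), at the accuracy level the method is designed for.

The command line drives the same pipeline end to end:

```
corneatopo simulate --seed 1 --output runs/sim          # synthetic acquisition
corneatopo topography --input runs/sim/sequence.tif --output runs/topo
corneatopo agree --a runs/topo/boundaries.csv --b other/boundaries.csv
```

`topography` writes per-frame fused PNGs, the shared colorbar, boundary and
metrics CSVs (central corneal thickness, deformation amplitude, peak
distance, stage labels), and a run manifest.

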