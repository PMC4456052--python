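# Methods

This note records the models, parameter choices and numerical decisions
behind `corneatopo`, and what the synthetic validation does and does not
demonstrate.

## Imaging model and coordinates

Frames are float grids in [0, 1], 0-based, with the row index increasing
downward and the column index rightward; boundary curves are functions
row(column). The default geometry follows the Corvis ST acquisition: 140
frames of 200 × 576 px at 0.016 mm/px. The signed radius convention is
positive where the anterior surface is convex toward the camera (osculating
center at larger row than the surface) and negative where concave; this is
the only convention under which the radius-normalization breakpoints at
negative R are reachable, since the surface is concave only during peak
deformation.

## Synthetic acquisition generator

The generator is the test oracle, so its geometry is analytic end to end.

* **Rest surface**: a circular arc of radius `anterior_radius_mm`
  (default 7.8 mm ≈ 487.5 px); the posterior boundary is the anterior plus a
  constant `cct_mm` (default 0.55 mm) in rows. Per-column ground-truth radius
  follows from the closed-form first and second derivatives of the boundary
  function and equals the arc radius exactly at rest.
* **Deformation**: a Gaussian-in-column indentation, amplitude driven by a
  raised-cosine pulse in time peaking at `concavity_frame` (default 70, half
  width 35 frames). Defaults: amplitude 1.0 mm — a typical air-puff
  deformation amplitude — and column width σ = 100 px (1.6 mm), which yields
  flanking forward apexes ≈ 4.6 mm apart at peak concavity, inside the range
  reported for air-puff tonometry. The central curvature changes sign
  (convex → concave → convex) whenever the indentation curvature exceeds the
  arc curvature, and frame stage labels (before/during/after) come from
  thresholding apex displacement at 0.05 mm.
* **Band rendering**: the bright band has a flat top with Gaussian-CDF edges
  (σ = 3 px) located exactly on the boundary curves, so the steepest
  gradient sits on the ground-truth boundary and the per-column intensity
  argmax sits on the midline. Intensity is scaled by a left-right
  illumination ramp (0.7 → 1.0), additive Gaussian noise (σ = 0.02 by
  default, 0.01 in most tests) and clipped to [0, 1].
* **Artifacts**: eyelashes/tear debris are 2–4 px wide quadratic Bezier
  strokes above the band, optionally touching it. Randomly placed strokes
  keep ≥ 80 columns of lateral separation so they model *distinct* lashes;
  without that, strokes falling within one closing-element width merge into
  a single large component that legitimately defeats a pure area filter
  (clumped debris is a different scenario, still constructible by passing
  explicit strokes).

What the generator does **not** emulate: Scheimpflug optical distortion and
depth-dependent blur, specular reflexes, motion blur, intensity decay along
the band from oblique sectioning, and real eyelid/tear-film texture. Passing
tests therefore demonstrate algorithmic correctness on an idealized band
with realistic gross structure, not clinical-grade accuracy.

## Segmentation

Preprocessing binarizes with Otsu's global threshold (the method's source
does not fix a binarization rule; it is config-exposed), closes illumination
gaps with a 10 × 60 px rectangular element (applied to the binary mask by
default; a grayscale-closing variant is available), and keeps 8-connected
components with area ≥ 1/3 of the largest.

Phase maps come from a log-Gabor bank, defaults: 4 scales, 6 orientations,
minimum wavelength 4 px, scale multiplier 2.1, σ/f = 0.55 — conventional
phase-congruency settings, all config-exposed. The scale-specific noise
floor T is estimated per orientation from the median amplitude of the
smallest-scale response (Rayleigh model: τ = median/√ln4, threshold
τ(√(π/2) + k·√((4−π)/2)) with k = 2), attenuated geometrically for coarser
scales. ε (default 10⁻⁴) guards the amplitude normalization.

Two implementation details matter and were found empirically:

* **Feathered masking.** Multiplying the frame by the hard binary mask
  creates a sharp step 1–2 px outside each boundary; the fine-scale odd
  responses lock onto that artificial edge and bias thickness estimates.
  The mask is therefore dilated (6 px) and blurred (Gaussian σ = 3) before
  multiplication, which suppresses artifacts without adding edges.
* **Boundary point selection.** Per column, candidates are *local maxima* of
  the asymmetry profile above threshold (τ = 0.1, mirroring the symmetry
  threshold) inside a window of ±0.75 × the mask-derived band thickness
  around the per-column raw median center. Among candidates on one side, the
  one nearest the center line wins after discarding those below 50 % of that
  side's maximum response. The relative gate rejects weak odd-dominant
  responses inside the band; the nearest-to-center rule rejects bright edges
  of eyelashes attached above it. A window of exactly ±0.5 × thickness
  equals the center-to-edge distance and clips the true edge whenever the
  center estimate is slightly off, hence the 0.75 default.

The center line and both boundaries are smoothed with degree-5 polynomial
least-squares fits; the center fit is weighted by the symmetry intensity at
each raw point (uniform weighting is a config switch). The outer 1/6 of
columns at each end are flagged low-confidence — phase responses fade where
illumination drops — and all accuracy statements apply to the central
two-thirds.

Known limitation: a quintic cannot represent a sharply indented boundary.
At peak concavity with the default indentation the best achievable quintic
residual is ≈ 1.5–2 px in the central two-thirds, which dominates
segmentation error there and widens the apparent spacing of the flanking
apexes; thickness at the central column is much less affected (both
boundaries shift together). Boundary errors at rest are ≈ 0.15 px mean.

## Curvature estimation

The area-error objective J = Σ(πR² − πrᵢ²)² is linear after substituting
B = R² − x_c² − y_c²; the 3 × 3 normal equations are solved directly (points
are centered on their centroid for conditioning; the fit is
translation-equivariant and rotation-invariant). Degenerate windows —
collinear points (singular or condition number > 10¹²) or non-positive R² —
are reported as invalid columns. The 27-px-per-side window slides over the
*fitted* boundary curve (raw candidates fluctuate by ±1 px, which is fatal
for a 55-px chord of a ~490 px circle); windows truncated by the valid-range
ends are not fit.

The algebraic fit has the known small-arc bias: with raw noise of 0.5 px on
a 55-px window of a 500 px circle it collapses (the sagitta, 0.8 px, is
inside the noise), and even at 0.05 px noise it underestimates the radius by
≈ 1–2 % relative to a geometric (orthogonal-distance) fit. A comparison test
documents this rather than hiding it; operating on the smoothed curve keeps
the pipeline out of the biased regime (end-to-end median radius error
≈ 0.1 mm at 7.8 mm).

## Radius normalization and fusion

The piecewise-linear normalization (0 below −35 mm; slopes 0.009, 0.1333,
0.009 between breakpoints −35/7/10/35 mm; 1 above 35 mm; offsets 0.3761 and
0.7761) is implemented with its published constants verbatim, including the
small junction discontinuities they imply — notably a 0.0019 *downward* step
across R = 7 (0.378 vs 0.3761). Monotonicity therefore holds per branch
interior, not globally; a `continuous_normalization` flag rescales the outer
branches to meet exactly for users who prefer a continuous map. Values are
clamped to [0, 1] (the fourth branch reaches 1.0011 at R = 35).

The palette is a fixed 256-entry blue→red table (HSV hue 240°→0°, full
saturation and value), linearly interpolated; one table serves an entire
video so equal radii render equal colors in every frame.

CIECAM02 is implemented from the CIE 159:2004 equations (CAT02 adaptation,
Hunt–Pointer–Estevez response compression, hue-quadrature interpolation
through the unique-hue table), forward and inverse, vectorized. The inverse
recovers the opponent pair in closed form: with u = A/N_bb + 0.305 the
achromatic sum R′a + G′a + 1.05 B′a equals u − (671a + 6588b)/1403, and the
definition of t then gives the chromatic radius along the known hue
direction. Default viewing conditions: D65 white, adapting luminance
60 cd/m², background luminance 20, average surround. The illuminant is
*discounted* (D = 1) by default: the input is display-referred, and partial
adaptation would leave neutral grays with saturation ≈ 9, bleeding hue into
the fused strip; with D = 1 grays are achromatic (s ≈ 0.5, the residual
coming from rounding in the published matrices). Round-trip accuracy is
≈ 10⁻¹⁴ per channel.

Fusion takes J from the gray pixel (treated as achromatic sRGB through the
full forward model, not a luma shortcut) and H and s from the pseudo-color
(chroma C instead of s is a config switch); out-of-gamut inverse results are
channel-clipped and the clip fraction is reported per frame. Lightness is
preserved within 0.5 J for in-gamut pixels; clipped pixels necessarily lose
lightness, which in practice affects < 1 % of strip pixels on corneal
frames. The 21-px strip is centered on the rounded anterior boundary;
columns without a valid radius stay gray, and pixels outside the strip are
bit-identical to the input frame.

## Metrics

Central corneal thickness (CCT) is the boundary separation at the valid
column nearest the image midline times the pixel pitch; deformation
amplitude is the anterior-boundary displacement at that column against a
reference frame; the highest-concavity frame maximizes amplitude (earliest
frame on ties). Peak distance (PD) is the Euclidean distance between the two
most prominent local minima of the fitted anterior boundary (prominence
threshold 1 px, config-exposed) — the forward bulges flanking the central
depression — and is undefined on a convex boundary. Bland–Altman agreement
reports the mean paired difference with mean ± 2·SD limits (sample SD) and
the fraction outside; Pearson r uses the standard product-moment form.

Pipeline-recovered CCT carries a systematic ≈ −0.5 to −0.9 px offset: the
coarse band-scale filters pull both detected edges slightly into the band.
Sub-pixel (parabolic) peak refinement was evaluated and rejected — the edge
response profile is skewed toward the band interior, so the parabola adds
bias rather than removing it. PD through the full pipeline inherits the
quintic's apex-position error at peak concavity (≈ 0.5 mm); PD computed from
the ground-truth boundary is exact to the pixel grid, which is what the
metric-recovery tests assert.

## Problem sizes and determinism

Tests run the full-resolution default geometry throughout. Per-frame
processing is ≈ 0.6 s; batch validations use 20 seeded rest frames
(segmentation recovery) and a full 140-frame sequence processed at the rest
and highest-concavity frames plus every 10th frame for agreement statistics.
All randomness flows through explicit `numpy` generators seeded per frame
from the scene seed, so identical configurations are bit-reproducible; the
filter bank is cached per (config, shape).

## I/O

Sequences are read from 8/16-bit grayscale TIFF stacks or PNG/TIFF
directories (lexicographic order) and normalized by the dtype maximum —
never per-frame min-max, which would break palette comparability. Outputs
are per-frame PNGs (the bit-exact record), a grayscale TIFF stack, CSV
tables and a JSON manifest (config hash, frame count, failures, package
version). Compressed video containers (AVI/MP4) are not read or written in
this build; convert externally if needed.
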