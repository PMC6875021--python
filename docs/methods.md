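# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `annuseg`, and what the phantom-based validation does and does not
demonstrate.

## Problem and pipeline

The aortic annulus is the virtual ring at the base of the aortic valve
leaflets; its cross-sectional area and perimeter on the annular plane
determine the prosthesis size in TAVI planning (area for the
balloon-expandable Sapien 3, perimeter for the self-expanding Evolut).
`annuseg` starts from an already-extracted 2-D annular plane in Hounsfield
units with pixel-spacing metadata and an annulus-centre coordinate;
identifying the annular plane inside a 3-D MDCT volume is out of scope.

The pipeline is: dual-resolution preprocessing → one segmentation network
per resolution → probability fusion → canny contour extraction →
planimetry → chart lookup.

## Preprocessing

Planes are resampled to isotropic grids with a separable bicubic spline
(`scipy.interpolate.RectBivariateSpline`), which reproduces constants
exactly and affine HU ramps to machine precision, so Hounsfield units are
preserved rather than renormalised. Resampling never extrapolates: the
output grid covers the source extent, and padding happens only at the clip
step. A 128 × 128 window is then clipped around the annulus centre at
1.0 mm and at 0.5 mm; the pixel nearest the annulus centre lands at index
(64, 64), and out-of-extent pixels are filled with −1024 HU (air). The
0.5 mm window therefore covers the central 64 × 64 mm of the 1.0 mm
window's 128 × 128 mm field of view. We resample before clipping; the
order matters only within a pixel of the border.

Ground-truth masks are rasterised with a pixel-centre rule: a pixel is
true iff its centre lies strictly inside the contour polygon (even-odd
rule; equivalent to strict interior membership for the simple polygons
accepted). Mask area (count × spacing²) converges to the analytic area as
spacing shrinks; tests pin this at 2, 1 and 0.5 mm.

## Segmentation network

The segmentation model is a U-shaped encoder–decoder with residual blocks,
written directly in NumPy (channels-last tensors, im2col convolutions
executed as nine accumulated GEMMs, hand-derived backpropagation verified
against float64 central differences). Per level: a channel-expanding
3 × 3 convolution + batch norm + ReLU, one residual block
(conv-BN-ReLU-conv-BN + identity, ReLU), then 2 × max pooling; the decoder
mirrors this with nearest-neighbour upsampling, a halving convolution and
concatenated same-scale skip connections; a 1 × 1 convolution and sigmoid
produce per-pixel probabilities.

Defaults (all overridable via `ModelConfig`):

| parameter | default | rationale |
|---|---|---|
| depth | 3 | bottleneck 16 × 16 on 128 × 128 input; receptive field spans the annulus |
| base channels | 4 (doubling per level) | the phantom task saturates at this capacity; keeps single-core training at minutes |
| residual blocks / level | 1 | same |
| loss | soft Dice + BCE, equal weight | region overlap objective with well-behaved gradients near empty masks |
| optimiser | Adam, lr 3 × 10⁻³, batch 8 | converges in ≈ 250 steps on phantom cohorts |
| epochs | 10 | validation Dice plateaus by epoch ~8 at cohort size 200 |

Inputs are standardised by a fixed affine map: clamp to [−1024, 1500] HU,
rescale to [−1, 1]. Training augmentation (training samples only):
rotation ±30°, horizontal/vertical flips, integer translation ±5 px,
global intensity shift of σ = 25 HU — generic CT perturbations. The model
returned is the checkpoint of the epoch with the best validation Dice
(threshold 0.5). One model is trained per resolution (1.0 and 0.5 mm);
both share the architecture. Everything is seeded: weight initialisation,
shuffling and augmentation derive from `ModelConfig.seed`, and two runs
with identical data and config produce bit-identical weights and history.

## Detection

The coarse map is resampled onto the fine 0.5 mm grid (bilinear, exact on
constants) and averaged with the fine map, clamped to [0, 1]. We read
"combined and normalised" as clamped averaging, which preserves
probability semantics; per-map min–max rescaling before averaging is
available as `fusion_mode="minmax"`. Annuli larger than the fine field of
view are not supported (the fused grid is the fine grid); the pipeline
errors rather than silently truncating.

Contour extraction runs canny (Gaussian σ = 1 px, hysteresis thresholds
0.1/0.2 on the gradient-magnitude scale of the [0, 1] map; configurable)
on the fused map. Edge pixels are grouped into 8-connected components; a
component is a closed loop if hole-filling encloses pixels, and the loop
enclosing the greatest area is kept. If the ridge does not close around
the detected region, one-pixel gaps are linked by a 3 × 3 morphological
closing and the search repeats — an explicit edge-linking step; without it
a single missing ridge pixel would abort an otherwise clean detection. An
empty map (no probability ≥ 0.5) raises "no annulus detected"; an
unclosable edge set raises "open contour".

The contour polygon is the loop's edge-pixel centres ordered
counterclockwise by angle around the enclosed region's centroid, with a
5-vertex periodic moving average of the radius. The smoothing matters for
the perimeter: a polygon through raw digitised pixel centres overestimates
a circle's circumference by ~8–13 % (the classic staircase bias), while
the smoothed polygon is within ~0.3 % on a 10 mm disc at 0.5 mm spacing,
and area error stays below ~1 %. Angle-ordering assumes the contour is
star-convex about its centroid — true for the near-elliptical annulus and
for all phantoms, and a documented limitation for pathological shapes.
Vertices stay at pixel resolution; no subpixel refinement is attempted.

Area is the absolute shoelace sum, perimeter the closed polyline length.
Every returned measurement must satisfy the isoperimetric inequality
P² ≥ 4πA (with 0.5 % slack so that near-circular measurements quoted at
0.1 mm precision pass); violations indicate a pathological contour and
raise instead of returning silently wrong numbers.

## Sizing

Charts are ordered, contiguous, non-overlapping bands with half-open
[lower, upper) intervals — a boundary value belongs to the larger size.
Overlapping or gapped charts are rejected at load. Out-of-range values
return explicit sentinels, never the nearest size. The shipped YAML
defaults are transcriptions of the public manufacturer sizing documents
(Sapien 3 area bands; Evolut native-diameter windows 18–20 / 20–23 /
23–26 / 26–30 mm converted to perimeter by π·d), with the published
charts' slight overlaps resolved to contiguity; they are editable data,
not clinical ground truth, and any chart with the same schema can be
substituted.

## Statistics

Paired differences are reported as mean ± sample SD (n−1 denominator).
Bland–Altman limits of agreement use bias ± 1.96 σ. The Wilcoxon
signed-rank test is two-sided, handles zeros by Pratt's method and ties by
average ranks, uses the exact sign-flip null (dynamic-programming
convolution on a doubled-rank lattice) for n ≤ 25 and a tie- and
zero-corrected normal approximation with continuity correction above;
the exact branch is pinned against full 2ⁿ enumeration. Pearson
correlation and Shapiro–Wilk (Royston AS R94) come from scipy. An
all-zero difference vector is flagged degenerate with p = 1 rather than
erroring, so self-comparisons evaluate cleanly. Device-size agreement is
the fraction of exactly equal labels, with a full confusion table and
under/over-estimation counts from the label ordering (sentinels sort
below/above all numeric sizes).

## Phantoms: what they emulate and what they do not

Each phantom is a noise-free painting of analytic regions — background,
elliptical wall ring (the lumen ellipse dilated by the wall thickness),
elliptical lumen, calcification discs of 1–3 mm radius centred on the
lumen boundary — followed by i.i.d. Gaussian noise. Default intensities
(lumen 400 HU, wall 120 HU, background 40 HU, calcium 900 HU) are
plausible contrast-CT values; only the relative contrast matters to the
pipeline. Cohort draws sample every generator field uniformly from ranges
chosen to span clinically plausible annuli (semi-axes 9–14 × 7–12 mm,
area ≈ 200–530 mm², perimeter ≈ 51–82 mm) with noise SD 10–30 HU and
native spacing 0.6–0.9 mm. The ground truth is exact: area πab, perimeter
4aE(e²) via the complete elliptic integral (cross-checked against
arc-length quadrature and Ramanujan's approximation), contour sampled at
720 vertices (polygonal area within 0.001 % of πab).

Phantoms do **not** emulate: non-elliptical or bicuspid annulus shapes,
anatomical context (coronary ostia, left ventricular outflow tract,
adjacent structures), partial-volume and beam-hardening artefacts,
inter-observer annotation noise, or the intensity statistics of any real
cohort. Passing the parameter-recovery experiment therefore demonstrates
that the pipeline is implemented correctly and can recover known geometry
through segmentation, fusion and contour extraction under noise and
calcification — it does not certify clinical accuracy on patient MDCT
data, whose headline agreement numbers require the (private) cohorts they
were measured on.

## Validation scales

The parameter-recovery experiment trains both models on 200 phantoms
(170 train / 30 validation) and detects 50 held-out phantoms; this takes
roughly five minutes on one CPU core and recovers mean Dice ≈ 0.99 with
mean absolute area and perimeter errors near 1 %. The geometry oracle
suite exercises 50 random ellipses per run. These sizes are the package's
test conditions; the module APIs accept arbitrary cohort sizes.

## Known limitations

- Star-convexity assumption in contour ordering (above).
- The NumPy training loop is single-threaded and desk-scale; it is not a
  general-purpose deep-learning framework and offers no GPU path.
- `resample_plane` requires at least a 4 × 4 raster (bicubic support).
- Fusion assumes the two windows are concentric within one coarse pixel,
  which `prepare_sample` guarantees; independently produced maps must
  satisfy it.
- Sizing-chart boundary assignment (half-open upward) is a convention;
  published charts disagree on boundary handling, and the chart files are
  the place to encode a site's policy.
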