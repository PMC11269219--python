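# Methods

## Problem setting

A germination assay images a 25 cm × 25 cm tray holding a 6×6 grid of
seeds at 1500×1500 px, once per hour. An instance-segmentation model
outputs one binary mask per detected radicle. The quantity of interest
is each radicle's physical length over time, from which per-seed growth
rates and vigour assessments follow. `radiclemorph` implements the
measurement chain (mask merging → edge detection → calibrated length),
the time-series analysis, the evaluation arithmetic, and a synthetic
generator that provides exact ground truth.

## Half-perimeter length model

A radicle is a thin, curved structure. Its closed edge contour consists
of two near-parallel boundary lines plus two short end caps, so the
contour's pixel count is approximately twice the centerline length:

    R = actual_length_cm / image_side_px          (cm per pixel)
    length_cm = sum_pixels / 2 × R

R is carried unrounded (25/1500 = 1/60 cm/px for the standard frame).
Each edge pixel counts exactly 1; the half-perimeter is applied per
8-connected contour, so multiple seeds in one image each get a length.

### Error model

Three effects separate the half-perimeter estimate from the true
centerline arc length. They are properties of the pixel-count method
itself, quantified here with the synthetic generator:

1. **Thickness bias, +t/2·R.** The contour wraps around the disc-swept
   ends, adding roughly the thickness t to the perimeter. For a
   horizontal 240 px bar of thickness 4 at R = 1/60 the chain reports
   4.117 cm against a 4.000 cm truth. No correction is applied in the
   measurement path (the rule is used as stated); tests subtract the
   analytic t/2·R when assessing recovery.

2. **Curvature.** For a curved radicle the outer boundary is longer and
   the inner shorter by the same first-order amount; averaging in the
   half-perimeter cancels the effect. Bounded-curvature radicles show
   no measurable curvature term beyond sampling noise.

3. **Orientation bias — the dominant term.** Discrete 4-bin
   non-maximum suppression keeps, for a diagonal edge, both pixels that
   straddle the gradient peak: the two lie on *different* anti-diagonal
   scan lines and are never compared against each other, so diagonal
   boundary responses are two pixels wide (a 4-connected Manhattan
   chain). The edge-pixel count per unit boundary length is therefore
   approximately

       max(|cos θ|, |sin θ|)   for edges within 22.5° of an axis (≈ 1),
       |cos θ| + |sin θ|       for diagonal edges (up to √2 ≈ 1.414),

   measured on straight bars as 1.03 at 0°, 1.05 at 20°, 1.42 at 45°.
   An interpolated-NMS detector (e.g. scikit-image's) shows the same
   factors on thin bars. Over radicles of uniform random orientation
   the expected factor is ≈ 1.18, i.e. unit-weight pixel counting
   *overestimates* diagonal radicles by up to ~42% and a typical curved
   radicle by ~15–20%. The acceptance statistics report this honestly:
   on 50 random bounded-curvature radicles (thickness 3 px, lengths
   30–300 px) the signed error after the t/2·R correction has mean
   ≈ +19% and maximum ≈ +43%, with a positive bias on every radicle.
   Correcting it would require √2-weighting diagonal steps or skeleton
   (medial-axis) length, both deliberately outside this package's
   scope: the pixel-count rule is implemented as practised, and its
   bias is documented rather than silently patched.

## Canny chain

Implemented from scratch because the edge map's exact pixel content is
the measurement input. Stages: normalized sampled Gaussian (default
σ = 1.4, 5×5), 3×3 Sobel with reflected borders, magnitude = Euclidean
norm, direction quantized to 4 bins with ties kept (≥ both neighbours;
out-of-bounds neighbours count as zero), and 8-connected hysteresis
(strong ≥ high; weak in [low, high) kept when transitively connected to
a strong pixel). Defaults low = 50, high = 150 apply to the raw Sobel
magnitude of the smoothed 8-bit image (a full-contrast step reaches
~1000, so binary masks clear the high threshold comfortably); all
parameters are configurable. The chain is verified pixel-for-pixel
against an independently written naive-loop reference on 300 random
images over three parameter sets.

Tie-keeping means intensity inversion (I → 255 − I) preserves the edge
*count* but may swap which side of an exactly tied two-pixel ridge
survives; this is asserted as a count invariant.

## MSCA numerics

The attention block is pure inference numerics on (C, H, W) arrays:
depthwise 5×5 aggregation, three separable strip branches (1×k then
k×1, k ∈ {7, 11, 21}) applied to the aggregated map, a skip branch, a
1×1 channel mixer, and elementwise gating with the input. All
convolutions use reflected borders, avoiding the dark-frame attention
artefacts zero padding would create at image edges; no nonlinearity is
inserted between branches. The map is linear up to the gate, hence
homogeneous of degree 2 — a property the tests exploit. The
downsampling block is a stride-2 3×3 convolution (reflect padding 1,
output ⌈H/2⌉×⌈W/2⌉) followed by per-channel normalization
(x − mean)/√(var + ε)·gain + bias. Strip/dense equivalence
(1×k ∘ k×1 ≡ dense k×k outer product) and forward-pass agreement with a
naive composition hold to < 1e-9. Training, initialization, and any
detector integration are out of scope.

## Evaluation arithmetic

AP uses greedy matching in descending confidence with each ground truth
consumable once, and all-points interpolation: the precision envelope
is made monotone from the right and integrated over recall steps. This
evaluates the continuous P(R) integral exactly for finite data; users
comparing with COCO's 101-point sampling should expect small
differences. mAP₅₀₋₉₅ averages the 10 thresholds 0.50:0.05:0.95, with
per-threshold class averaging (n_c = 1 in the single-class radicle
setting). Boxes are continuous and half-open (no +1 convention).
Complexity formulas are exact integer arithmetic; FLOPS counts 2 ops
per multiply-accumulate including the bias slot. Agreement analysis is
closed-form OLS of machine on manual lengths with R² = 1 − SSres/SStot
plus per-series mean/median/min/max.

## Time-series analysis

Seeds are physically fixed in the tray, so tracks are formed by
grid-cell association (centroid → equal-cell grid), not
nearest-neighbour matching; this avoids identity switches when a long
radicle crosses a cell border marginally. At most one contour per cell
per frame is kept (largest pixel count wins; losers are logged). Early
frames may lack a detectable radicle; these are recorded as missing,
never interpolated, and growth rates simply span the longer interval.
The amplify transform (x − offset)·scale defaults to offset 1 cm,
scale 2 — the convention used for germination curves — and is exposed
as parameters since it is a visualization aid. Overlay export scales
pixel coordinates by R into axis units of 0.1 cm and lays frames side
by side in time order.

## Synthetic generator

Centerlines are uniform Catmull-Rom splines through control points with
reflected end tangents (a 2-point spline is exactly a straight
segment). Ground-truth length is the spline arc length by adaptive
polyline refinement (tolerance 1e-3 px). Rasterization uses half-open
pixel coverage — an axis-aligned run of integer length L covers exactly
L pixels — followed by dilation with a disc of radius ⌊thickness/2⌋,
which makes straight-bar perimeters analytically predictable. Random
radicles follow a bounded-turn heading walk (default ≤ 0.35 rad per
20 px step, steering back from borders), emulating the bending and
intertwining of real radicles; thickness is a free parameter (default
3 px) since real radicle width in pixels varies with optics. Growth
series truncate the centerline to scheduled arc lengths; the default
three-phase schedule (6, 0.5, 25 px/h for 3 h each, hourly frames)
mirrors the observed germination pattern of moderate early elongation,
a plateau, then a burst.

What the generator does *not* emulate: photometric texture, soft mask
boundaries, segmentation errors (false merges/splits), or seed-coat
occlusion. Passing tests therefore validate the measurement arithmetic
and its geometric error model, not robustness to segmentation noise.

## Problem sizes and numerical choices

Test and acceptance runs use 32×32 random images for oracle
equivalence (300 images × 3 parameter sets), 400×400 canvases for the
50-radicle recovery study, 4×16×16 / 3×12×12 feature maps for MSCA
oracles, and 8×8-bounded exhaustive sets for merge properties — sizes
at which the naive-loop oracles are exact and fast while exercising
every code path. Mask resizing is nearest-neighbour so masks stay
binary; merge clamping is (sum > 0) → 255, exactly representable in
uint8. Rotation by non-multiples of 90° uses nearest-neighbour
resampling for the same reason. Contours are ordered by bounding-box
(row_min, col_min) for deterministic output; AP confidence ties
resolve by input order.
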