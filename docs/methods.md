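# Methods

## Overview

spinemorph implements the geometric measurement stage of an automated
lumbar-spine assessment pipeline. Its inputs are what a detector and a
segmenter produce on a head-up mid-sagittal slice: per-vertebra
instance masks (integer label image, background 0, L1–L5 and the first
sacral vertebra S as labels 1–6) and/or YOLO-format bounding boxes at a
nominal 320 × 320 resolution. From these it measures the lumbar
lordotic angle (LLA), the lumbosacral angle (LSA), a lordosis grade,
and a centroid-polygon area statistic, and it scores detections and
grades against ground truth.

## Coordinate and raster conventions

Continuous image coordinates, origin top-left, x right, y down.
Integer pixel (r, c) occupies the square [c, c+1) × [r, r+1) with
center (c + 0.5, r + 0.5); tight boxes over pixel sets are half-open,
so a rectangle's mask area equals its box area. Polygon rasterization
(phantom bodies, region area, calibration templates) marks a pixel
when its center lies inside the polygon or on its boundary. This
center-sampling rule is symmetric — no edge direction is systematically
over-drawn — which matters for unbiased corner localization (below);
zero-area polygons degrade to the set of pixel squares the boundary
line passes through. Superior means smaller row index; vertebra
identity is assigned geometrically by sorting the six boxes by centroid
y (tie-break: centroid x), because detection is single-class.

## Corner detection

Per vertebra: crop its binary mask with a margin of 4 × window_sigma
(padding with background beyond the image border so edge-flush
vertebrae keep their gradients), smooth with a Gaussian (σ = 1 px,
truncated at 4σ, reflective boundaries), compute the Harris response
R = det(M) − k·tr(M)² with gradients by central differences and the
structure tensor M windowed by a Gaussian of window_sigma, then keep
local maxima above 5% of the peak response under greedy non-maximum
suppression (radius 5 px, strongest first, row-major tie-break).

Anatomical labeling assigns each candidate to a quadrant relative to
the mask centroid — evaluated after de-rotating by the mask's
principal-axis orientation (second central moments), so the strongly
tilted sacrum is labeled correctly; per quadrant the strongest response
wins, and an empty quadrant is an error naming the quadrant.

**Localization bias.** The Harris response of a smoothed binary corner
peaks a fixed distance *inside* the corner (≈1.4 px per axis at the
default sigmas). Rather than sub-pixel refinement, the detector applies
a constant systematic-bias compensation: the offset is calibrated once
per parameter set on an ideal rasterized right-angle template, averaged
over a 5 × 5 grid of sub-pixel placements, cached, and subtracted along
each corner's two interior edge directions. This reduces mean recovery
error on noise-free phantoms from ≈1.3 px to ≈0.55 px (worst case
≈1.6 px). It is a property of the operator, not of any particular
image, and can be disabled (`CornerParams.bias_correction=False`).

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| smooth_sigma | 1.0 | px | mask smoothing before differentiation |
| harris_k | 0.05 | — | corner/edge sensitivity (classic range 0.04–0.06) |
| window_sigma | 1.2 | px | structure-tensor window |
| nms_radius | 5 | px | minimum corner separation |
| rel_threshold | 0.05 | — | candidate cut as fraction of max response |
| max_candidates | 12 | — | candidate cap |

window_sigma defaults to 1.2: wide enough to stabilize the response on
these mask sizes, narrow enough to keep the (pre-compensation) peak
bias small; larger windows (e.g. 2) raise the bias and the recovery
error without improving robustness on segmentation-quality masks.

## Angles and grading

Endplate lines pass through superior (or inferior) corner pairs. The
angle between lines with slopes m₁, m₂ is arctan |(m₁−m₂)/(1+m₁m₂)|,
evaluated via atan2 of direction-vector cross and dot products, making
vertical slopes and perpendicular pairs exact; the result is the
unsigned acute angle in [0, 90]. LLA uses L1-superior vs S-superior;
LSA uses L5-inferior vs S-superior. Grading by LLA: < 39° hypo,
39–53° normal (both boundaries normal, matching the stated normal
*range*), > 53° hyper. LSA is reported but not used for grading.

## Region-area method

The six box centroids ((xmin+xmax)/2, (ymin+ymax)/2), connected in
anatomical order and closed, are rasterized with the same fill rule and
the nonzero pixels counted (pixel pitch 1). Grading needs two area
cut-points; since no published cut-points exist, they are calibrated on
labeled cases by exhaustive search over midpoints between consecutive
sorted distinct areas (plus guard cuts beyond the data range),
maximizing training accuracy under the hypo < normal < hyper area
ordering, ties broken toward the widest separating margins. Boundary
convention mirrors the angle rule (upper boundaries inclusive to
normal).

## Detection metrics

EU is the centroid distance scaled by pixel spacing (default
1 mm/px — configurable, since spacing depends on acquisition); MEU its
mean. IOU is computed on continuous coordinates; degenerate unions give
0. Detection post-processing: confidence floor 0.65, then greedy NMS at
IOU 0.3, then greedy matching in descending confidence, each prediction
taking its highest-IOU free ground-truth box at IOU ≥ 0.5. Precision
with zero predictions is defined as 1 (PR curves start at (0, 1)).
AP is the area under the all-point-interpolated (monotone-envelope)
PR curve of the pooled confidence-ranked detections, single class;
mAP@0.5:0.95 averages thresholds 0.50 … 0.95 in steps of 0.05.
Grading agreement is summarized by a 3 × 3 confusion matrix
(rows true, columns predicted, order hypo/normal/hyper) and its
trace/total accuracy.

## The phantom generator

Each phantom is six isosceles trapezoids (inferior endplate 0.9 × the
superior width — vertebral bodies are near-quadrilateral in mid-sagittal
view) stacked down a gently bowed column (horizontal sine offset,
amplitude 18 px) on a 320 × 320 canvas, each tilted by a per-vertebra
endplate angle; the default tilt profile (0, 5, 10, 18, 28, 48)°
makes the sacrum the most tilted element, as it is anatomically. The
whole column is placed at a random sub-pixel phase, as real anatomy
lands on the scanner grid at arbitrary fractional offsets. Vertical
spacing accounts for each body's rotated extent plus a 6 px gap;
placement overflow or overlap raises a generation error (a few jitter
re-draws are attempted first).

Ground truth is analytic: true LLA is the acute angle between the L1
and S superior-endplate directions (= the S-vs-L1 tilt difference for
the default profile), true LSA likewise for L5-inferior vs S-superior,
the grade is the grading function applied to the true LLA, and the
stored corners are the exact polygon vertices used for rasterization.
Boundary jitter perturbs the vertices uniformly (±jitter px) *before*
rasterization while the analytic truth stays fixed — it is measurement
noise for the pipeline to overcome, mirroring a ground-truth-vs-
measured evaluation. Salt & pepper noise applies only to the optional
grayscale render; label rasters are always clean.

Cohorts target a grade mix (default 6/51, 19/51, 26/51, the clinical
test split the grading tables refer to) via largest-remainder
allocation; per case the S-vs-L1 tilt difference is drawn uniformly
within the target class's angle interval (hypo [5, 39), normal
[39, 53], hyper (53, 85]), padded 2% off the class boundaries so
jitter cannot flip the true grade, and intermediate tilts follow the
default profile's fractions. Everything is deterministic under the
cohort seed.

**What the phantom does and does not emulate.** It reproduces the
geometry that the measurement pipeline actually consumes — per-vertebra
instance masks with realistic sizes, tilts, curvature, boundary noise
and discretization. It does not emulate MRI appearance, segmentation-
network failure modes (merged or broken masks, osteophytes, partial
volume), intervertebral discs, or anatomical shape variation beyond
the trapezoid family. Passing phantom tests therefore validates the
geometric measurement chain, not robustness to real segmentation
errors.

## Numerical choices and degenerate inputs

- Slopes use a vertical sentinel at |Δx| < 1e-12; all angle math goes
  through direction vectors, so no slope singularities arise.
- Corner candidates and NMS break response ties by row-major position;
  vertebra ordering breaks centroid-y ties by centroid x.
- Zero-area boxes are legal (IOU 0, centroid defined); empty label
  images yield an empty box list with a warning.
- YOLO floats are written with 6 decimals (≈1e-6 normalized
  quantization, ≈3e-4 px at 320); a second round trip is byte-stable.
- A failing case in a batch run is flagged and logged, never fatal to
  the batch.

## Problem sizes

The test suite and the acceptance script run on generated cohorts of
10–51 cases (50 for corner recovery), which gives 1 200–1 224 corner
measurements per check — enough for stable means at a few seconds of
runtime; the full suite plus acceptance completes in well under a
minute.

## Known limitations

- Corner detection assumes one connected, roughly trapezoidal mask per
  vertebra; severely fragmented segmentations surface as
  corner-assignment errors rather than being repaired.
- The principal-axis de-rotation is ambiguous for near-square masks
  (axis ratio → 1); vertebral bodies are reliably elongated, so this
  does not arise in practice.
- Area-grading cut-points are resolution- and framing-dependent; they
  must be recalibrated for a different field of view (an optional
  diagonal² normalization hook exists but is off by default).
- The centroid polygon uses straight segments between centroids; a
  fitted-curve variant is a possible extension and would change the
  absolute areas but not the ordering logic.
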