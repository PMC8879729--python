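# spinemorph

Geometric morphometry of the lumbar spine from segmentation masks and
detection boxes: vertebral endplate corner detection, lumbar lordotic /
lumbosacral angle measurement, lordosis grading, a centroid-polygon
region-area grading alternative, and the standard detection metrics —
plus a synthetic spine-phantom generator that makes the whole pipeline
testable end-to-end without any imaging data.

## Who this is for

Researchers building automated lumbar-spine assessment pipelines
(detector → segmenter → geometric measurement) who need the *geometric
back half* of that pipeline as a tested, reusable library: given
per-vertebra instance masks (L1–L5 and the first sacral vertebra S) or
YOLO-format bounding boxes on a mid-sagittal slice, produce clinical
angles, grades and evaluation metrics.

## The measurements

**LLA (lumbar lordotic angle)** — the angle between the superior
endplate of L1 and the superior endplate of S.
**LSA (lumbosacral angle)** — the angle between the inferior endplate
of L5 and the superior endplate of S.

Endplates are lines through the two endplate corners of a vertebra.
Corners are found by smoothing the vertebra's binary mask with a
Gaussian (σ = 1 px), computing the Harris corner response
R = det(M) − k·tr(M)² over the Gaussian-windowed structure tensor M,
applying non-maximum suppression, and labeling the four survivors
(superior/inferior × left/right) by quadrant in the vertebra's
principal-axis frame. For endplate lines with slopes m₁, m₂ the angle
is

    θ = arctan |(m₁ − m₂) / (1 + m₁ m₂)|

evaluated through direction vectors so vertical and perpendicular
configurations are exact. Lordosis is graded from the LLA: below 39°
hypolordosis, 39–53° normal, above 53° hyperlordosis.

The **region-area** alternative needs only bounding boxes: connect the
six box centroids L1 → L2 → … → S → L1 and count the pixels of the
enclosed region (hypo < normal < hyper in area); two calibrated area
cut-points turn the area into a grade.

**Evaluation** covers centroid Euclidean distance (EU/MEU), box IOU,
mean absolute angle error (ME), confidence/NMS detection filtering
(defaults 0.65 / 0.3), precision–recall, all-point-interpolated AP and
mAP@0.5:0.95, and 3-class grading confusion matrices.

## Worked example

`examples/02_measure_angles.py` generates a phantom with known geometry
and measures it back:

```
              measured      true
LLA (deg)        50.02     48.00
LSA (deg)        21.27     20.00
grade           normal    normal
region area = 2641 px^2 (centroid hexagon)

L1 corners (superior-left, superior-right, inferior-left, inferior-right):
  detected ( 134.0,   26.1)   true ( 133.6,   25.9)
  detected ( 188.1,   25.1)   true ( 187.6,   25.9)
  detected ( 136.2,   51.9)   true ( 136.3,   51.9)
  detected ( 184.7,   51.9)   true ( 184.9,   51.9)
```

The phantom's sacrum is tilted 48° against L1, so the true LLA is 48°;
the pipeline recovers it within ~2° from the rasterized masks alone,
corner positions within ~1 px, and both land in the *normal* grade.
The other examples cover phantom generation (`01`), region-area
grading under boundary noise (`03`, where the corner method keeps
100% accuracy while the area proxy drops to ~82%), and detection
metrics on perturbed boxes (`04`).

A thin CLI wraps the same functions:

```sh
spinemorph phantom --out cohort/ --n 51 --seed 0
spinemorph measure --in cohort/ --out measured.csv
spinemorph evaluate --gt cohort/ --pred detections/ --out metrics.json
spinemorph calibrate-area --measured measured.csv --truth cohort/manifest.csv --out area.json
```

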