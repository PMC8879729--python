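"""Score simulated detections against ground truth.

Builds a small phantom cohort, perturbs the ground-truth boxes into
mock detections (shifted, with confidences, one duplicate), and reports
the localization metrics: mean centroid distance (MEU), IOU, precision/
recall after confidence + NMS filtering, and mAP.
"""

from dataclasses import replace

import numpy as np

from spinemorph import (
    centroid,
    euclidean_distance,
    generate_cohort,
    iou,
    map_over_thresholds,
    match_detections,
    mean_eu,
    precision_recall,
)
from spinemorph.workflow import DEFAULT_GRADE_MIX

rng = np.random.default_rng(5)
cases = generate_cohort(10, DEFAULT_GRADE_MIX, seed=5)
gt_sets = [list(c.boxes) for c in cases]

pred_sets = []
for boxes in gt_sets:
    preds = []
    for b in boxes:
        dx, dy = rng.normal(0, 1.5, 2)
        preds.append(replace(b.shifted(dx, dy), confidence=float(rng.uniform(0.7, 1.0))))
    # one low-confidence duplicate per image, to be filtered/NMS'd away
    preds.append(replace(boxes[0].shifted(1.0, 1.0), confidence=0.5))
    pred_sets.append(preds)

distances, ious, tps, fps, fns = [], [], 0, 0, 0
for gt, pred in zip(gt_sets, pred_sets):
    m = match_detections(gt, pred)
    tps, fps, fns = tps + m.tp, fps + m.fp, fns + m.fn
    for g, p, v in m.pairs:
        distances.append(euclidean_distance(centroid(g), centroid(p)))
        ious.append(v)

maps = map_over_thresholds(gt_sets, pred_sets)
print(f"matched {tps} boxes ({fps} false positives, {fns} misses)")
print(f"MEU  = {mean_eu(distances):.2f} px   (mean centroid distance)")
print(f"IOU  = {np.mean(ious):.3f} mean      (box overlap of matched pairs)")
print(f"mAP@0.5      = {maps['map50']:.3f}")
print(f"mAP@0.5:0.95 = {maps['map5095']:.3f}")
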