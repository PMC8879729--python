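"""Detection and grading metrics.

Covers everything needed to score a vertebra-localization + angle
pipeline against ground truth: centroid Euclidean distance (EU) and its
mean (MEU), box intersection-over-union (IOU), mean absolute angle error
(ME), confidence/NMS post-filtering and greedy matching of detections,
precision/recall, average precision (all-point interpolated PR curve)
and mAP over IOU thresholds 0.5:0.95, and the 3-class lordosis confusion
matrix with its accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .angles import GRADES
from .io import BoundingBox, Point, centroid


@dataclass(frozen=True)
class MatchParams:
    """Detection post-filter and matching parameters: confidence floor
    0.65, NMS IOU 0.3, and the usual 0.5 IOU for a true positive."""

    conf_threshold: float = 0.65
    nms_iou: float = 0.3
    match_iou: float = 0.5


@dataclass
class DetectionMatch:
    """Result of matching predictions to ground truth on one image."""

    pairs: list[tuple[BoundingBox, BoundingBox, float]] = field(default_factory=list)
    unmatched_gt: list[BoundingBox] = field(default_factory=list)
    unmatched_pred: list[BoundingBox] = field(default_factory=list)
    params: MatchParams = field(default_factory=MatchParams)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


def euclidean_distance(gt: Point, pred: Point, pixel_spacing_mm: float = 1.0) -> float:
    """Distance between two centroids, scaled to millimetres by the
    pixel spacing (default 1 mm/px)."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be > 0")
    return pixel_spacing_mm * math.hypot(pred.x - gt.x, pred.y - gt.y)


def mean_eu(distances: Sequence[float]) -> float:
    """Mean of centroid distances (MEU)."""
    if len(distances) == 0:
        raise ValueError("mean of empty distance list")
    return float(np.mean(distances))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes on continuous coordinates;
    0 for disjoint or zero-union (degenerate) pairs."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def mean_error(pred_angles: Sequence[float], orig_angles: Sequence[float]) -> float:
    """Mean absolute error between predicted and ground-truth angles."""
    if len(pred_angles) != len(orig_angles) or len(pred_angles) == 0:
        raise ValueError("angle lists must be equal-length and non-empty")
    return float(np.mean(np.abs(np.asarray(pred_angles) - np.asarray(orig_angles))))


def nms(boxes: Sequence[BoundingBox], iou_threshold: float) -> list[BoundingBox]:
    """Greedy non-maximum suppression, highest confidence first; a box
    is dropped when it overlaps a kept box above the IOU threshold."""
    ordered = sorted(
        boxes, key=lambda b: (-(b.confidence or 0.0), b.ymin, b.xmin)
    )
    kept: list[BoundingBox] = []
    for b in ordered:
        if all(iou(b, k) <= iou_threshold for k in kept):
            kept.append(b)
    return kept


def match_detections(
    gt: Sequence[BoundingBox],
    pred: Sequence[BoundingBox],
    params: MatchParams = MatchParams(),
) -> DetectionMatch:
    """Post-filter predictions and match them to ground truth.

    Predictions below the confidence threshold are dropped, survivors go
    through greedy NMS, and the rest match greedily in descending
    confidence order, each taking its highest-IOU still-free ground
    truth provided IOU >= ``match_iou``.
    """
    for p in pred:
        if p.confidence is None:
            raise ValueError("predictions must carry confidence scores")
    confident = [p for p in pred if p.confidence >= params.conf_threshold]
    survivors = nms(confident, params.nms_iou)

    free = list(gt)
    result = DetectionMatch(params=params)
    for p in sorted(survivors, key=lambda b: -b.confidence):
        best_iou, best_g = 0.0, None
        for g in free:
            v = iou(g, p)
            if v > best_iou:
                best_iou, best_g = v, g
        if best_g is not None and best_iou >= params.match_iou:
            result.pairs.append((best_g, p, best_iou))
            free.remove(best_g)
        else:
            result.unmatched_pred.append(p)
    result.unmatched_gt = free
    return result


def precision_recall(match: DetectionMatch) -> tuple[float, float]:
    """(P, R) of a match.  With zero predictions P = 1 by convention
    (the PR curve starts at precision 1); with zero ground truth R = 1."""
    tp, fp, fn = match.tp, match.fp, match.fn
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return p, r


def _pr_points(
    gt_sets: Sequence[Sequence[BoundingBox]],
    pred_sets: Sequence[Sequence[BoundingBox]],
    iou_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Confidence-ranked cumulative precision/recall over the pooled set."""
    n_gt = sum(len(g) for g in gt_sets)
    if n_gt == 0:
        raise ValueError("no ground truth boxes; AP undefined")
    pooled = []
    for img_idx, preds in enumerate(pred_sets):
        for order, p in enumerate(preds):
            if p.confidence is None:
                raise ValueError("predictions must carry confidence scores")
            pooled.append((-p.confidence, img_idx, order, p))
    pooled.sort(key=lambda t: t[:3])

    free: list[list[BoundingBox]] = [list(g) for g in gt_sets]
    tps = np.zeros(len(pooled))
    for rank, (_, img_idx, _, p) in enumerate(pooled):
        best_iou, best_g = 0.0, None
        for g in free[img_idx]:
            v = iou(g, p)
            if v > best_iou:
                best_iou, best_g = v, g
        if best_g is not None and best_iou >= iou_threshold:
            tps[rank] = 1.0
            free[img_idx].remove(best_g)
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1.0 - tps)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    recall = tp_cum / n_gt
    return precision, recall


def average_precision(
    gt_sets: Sequence[Sequence[BoundingBox]],
    pred_sets: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
) -> float:
    """AP for the single vertebra class at one IOU threshold.

    Area under the all-point interpolated (monotone-envelope) PR curve
    of the confidence-ranked pooled detections.
    """
    if not any(len(p) for p in pred_sets):
        return 0.0
    precision, recall = _pr_points(gt_sets, pred_sets, iou_threshold)
    mrec = np.concatenate([[0.0], recall])
    mpre = np.concatenate([[1.0], precision])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def map_over_thresholds(
    gt_sets: Sequence[Sequence[BoundingBox]],
    pred_sets: Sequence[Sequence[BoundingBox]],
    thresholds: Sequence[float] | None = None,
) -> dict[str, float]:
    """mAP at 0.5 and averaged over 0.50:0.95 (step 0.05)."""
    if thresholds is None:
        thresholds = [0.5 + 0.05 * i for i in range(10)]
    aps = {t: average_precision(gt_sets, pred_sets, t) for t in thresholds}
    return {
        "map50": aps[min(aps, key=lambda t: abs(t - 0.5))],
        "map5095": float(np.mean(list(aps.values()))),
        "per_threshold": {f"{t:.2f}": v for t, v in aps.items()},
    }


def confusion_and_accuracy(
    true_grades: Sequence[str], pred_grades: Sequence[str]
) -> tuple[np.ndarray, float]:
    """3x3 confusion matrix (rows true, cols predicted, order hypo /
    normal / hyper) and its accuracy (trace over total)."""
    if len(true_grades) != len(pred_grades) or len(true_grades) == 0:
        raise ValueError("grade lists must be equal-length and non-empty")
    index = {g: i for i, g in enumerate(GRADES)}
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_grades, pred_grades):
        if t not in index or p not in index:
            raise ValueError(f"unknown grade in ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    accuracy = float(np.trace(counts) / counts.sum())
    return counts, accuracy
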