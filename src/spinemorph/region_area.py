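"""Centroid-polygon region area and area-based lordosis grading.

An alternative to corner-based angle measurement that needs only the six
bounding-box centroids: connect the centroid of L1 to L2, L2 to L3, …,
L5 to S, and close S back to L1.  The enclosed region's pixel-fill area
tracks the spinal curvature — a hypolordotic (flat) spine encloses a
thin sliver, a hyperlordotic one a fat crescent — so the area alone can
grade lordosis once two area cut-points are calibrated against cases of
known grade.  Ordering assumption: hypo areas < normal areas < hyper
areas.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError
from .io import BoundingBox, Point, VERTEBRA_NAMES, centroid, fill_polygon


@dataclass(frozen=True)
class AreaThresholds:
    """Calibrated area cut-points (pixels²) between the three grades."""

    low_cut: float
    high_cut: float

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError(f"require 0 < low_cut < high_cut, got {self}")


@dataclass(frozen=True)
class RegionAreaResult:
    """Area of the centroid polygon and its (possibly uncalibrated) grade."""

    area_px: float
    polygon: tuple[Point, ...]
    grade: str = "uncalibrated"


def centroid_polygon(boxes: Sequence[BoundingBox]) -> list[Point]:
    """Box centroids ordered L1, L2, L3, L4, L5, S (the closed polygon's
    vertex order).  Requires exactly one box per vertebra label."""
    by_label = {}
    for b in boxes:
        if b.label in by_label:
            raise ValueError(f"duplicate label {b.label!r}")
        by_label[b.label] = b
    missing = [n for n in VERTEBRA_NAMES if n not in by_label]
    if missing:
        raise ValueError(f"missing vertebra labels: {missing}")
    return [centroid(by_label[n]) for n in VERTEBRA_NAMES]


def region_area(
    polygon: Sequence[Point],
    image_height: int,
    image_width: int,
    normalize: bool = False,
) -> float:
    """Pixel-fill area of the closed centroid polygon.

    The polygon is rasterized onto the image canvas with even-odd fill
    and boundary pixels included: a pixel counts when its center lies
    inside the polygon or on its boundary.  The return value is the
    nonzero-pixel count times the squared pixel pitch (1 px), so a
    degenerate (collinear) polygon still yields its boundary-line pixel
    count.  With ``normalize=True`` the count is divided by the squared
    image diagonal, making areas comparable across fields of view
    (off by default: the pipeline works at a fixed resolution).

    Raises
    ------
    ValueError
        If any vertex falls outside the canvas.
    """
    xs = np.array([p.x for p in polygon])
    ys = np.array([p.y for p in polygon])
    if xs.min() < 0 or ys.min() < 0 or xs.max() > image_width or ys.max() > image_height:
        raise ValueError("polygon extends outside the image canvas")
    mask = fill_polygon(xs, ys, (image_height, image_width))
    count = float(np.count_nonzero(mask))
    if normalize:
        count /= float(image_height**2 + image_width**2)
    return count


def shoelace_area(polygon: Sequence[Point]) -> float:
    """Exact (continuous) polygon area by the shoelace formula."""
    xs = np.array([p.x for p in polygon])
    ys = np.array([p.y for p in polygon])
    return float(abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))) / 2.0)


def grade_by_area(area_px: float, thresholds: AreaThresholds) -> str:
    """Grade from area: ``area < low_cut`` hypo, ``<= high_cut`` normal,
    else hyper (upper boundaries inclusive, mirroring the angle rule)."""
    if area_px < thresholds.low_cut:
        return "hypo"
    if area_px <= thresholds.high_cut:
        return "normal"
    return "hyper"


def calibrate_area_thresholds(
    areas: Sequence[float], grades: Sequence[str]
) -> AreaThresholds:
    """Fit the two area cut-points on labeled training cases.

    Exhaustive search over candidate cut pairs — midpoints between
    consecutive sorted distinct areas — maximizing training accuracy
    under the hypo < normal < hyper area ordering; ties break toward the
    pair with the widest separating margins (sum of the two gap
    half-widths).

    Raises
    ------
    CalibrationError
        Unless all three grades are represented with finite areas.
    """
    areas = np.asarray(areas, dtype=float)
    if len(areas) != len(grades):
        raise CalibrationError("areas and grades length mismatch")
    if not np.all(np.isfinite(areas)):
        raise CalibrationError("non-finite area in training data")
    present = set(grades)
    if present != {"hypo", "normal", "hyper"}:
        raise CalibrationError(f"need all three grades in training data, got {present}")

    distinct = np.unique(areas)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    gaps = (distinct[1:] - distinct[:-1]) / 2.0
    # guard cuts beyond the data range so boundary classes stay reachable
    lo_guard = max(distinct[0] / 2.0, distinct[0] - 1.0)
    hi_guard = distinct[-1] + 1.0
    candidates = np.concatenate([[lo_guard], mids, [hi_guard]])
    margins = np.concatenate([[0.0], gaps, [0.0]])

    truth = np.asarray(grades)
    best: tuple[float, float, AreaThresholds] | None = None
    for i, j in itertools.combinations(range(len(candidates)), 2):
        low, high = candidates[i], candidates[j]
        if low <= 0:
            continue
        pred = np.where(areas < low, "hypo", np.where(areas <= high, "normal", "hyper"))
        acc = float(np.mean(pred == truth))
        margin = float(margins[i] + margins[j])
        if best is None or (acc, margin) > (best[0], best[1]):
            best = (acc, margin, AreaThresholds(low_cut=float(low), high_cut=float(high)))
    assert best is not None
    return best[2]


def region_area_result(
    boxes: Sequence[BoundingBox],
    image_height: int,
    image_width: int,
    thresholds: AreaThresholds | None = None,
) -> RegionAreaResult:
    """Convenience wrapper: centroid polygon → area → (optional) grade."""
    poly = centroid_polygon(boxes)
    area = region_area(poly, image_height, image_width)
    grade = grade_by_area(area, thresholds) if thresholds is not None else "uncalibrated"
    return RegionAreaResult(area_px=area, polygon=tuple(poly), grade=grade)
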