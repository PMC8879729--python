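"""Endplate slopes, Cobb-type lumbar angles, and lordosis grading.

Two clinical angles are computed from vertebral endplate lines:

* **LLA** (lumbar lordotic angle) — the angle between the superior
  endplate of L1 and the superior endplate of the sacrum.
* **LSA** (lumbosacral angle) — the angle between the inferior endplate
  of L5 and the superior endplate of the sacrum.

An endplate line passes through the two corner points of that endplate.
The angle between two lines with slopes ``m1, m2`` is
``arctan |(m1 - m2) / (1 + m1 m2)|``; it is evaluated through direction
vectors (``atan2`` of cross and dot products) so vertical endplates and
near-perpendicular pairs (``1 + m1 m2 -> 0``) are handled exactly.  The
result is the unsigned acute angle in ``[0, 90]`` degrees, matching
clinical usage.

Lordosis is graded from the LLA: the normal range is 39-53 degrees
(boundaries inclusive); below it is hypolordosis, above it
hyperlordosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .corners import CornerSet
from .io import Point

#: Sentinel slope for vertical lines (infinite rise over zero run).
VERTICAL = "vertical"

Slope = Union[float, str]

#: The three lordosis grades, in increasing-angle order.
GRADES: tuple[str, ...] = ("hypo", "normal", "hyper")


@dataclass(frozen=True)
class GradeThresholds:
    """Lordosis class boundaries on the LLA, degrees.

    Defaults delimit the normal range 39-53; both boundaries belong to
    the normal class.
    """

    low: float = 39.0
    high: float = 53.0

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high < 90.0:
            raise ValueError(f"require 0 < low < high < 90, got {self}")


@dataclass(frozen=True)
class EndplateLine:
    """A line through the two corners of one endplate."""

    p1: Point
    p2: Point

    def __post_init__(self) -> None:
        if self.p1 == self.p2:
            raise ValueError("endplate corners coincide; line undefined")

    @property
    def slope(self) -> Slope:
        return slope(self.p1, self.p2)

    @property
    def direction(self) -> tuple[float, float]:
        return (self.p2.x - self.p1.x, self.p2.y - self.p1.y)


@dataclass(frozen=True)
class AngleReport:
    """Measured angles for one case, with intermediate slopes."""

    lla_deg: float
    lsa_deg: float
    m_l1_sup: Slope
    m_l5_inf: Slope
    m_s_sup: Slope
    grade: str


def slope(p1: Point, p2: Point) -> Slope:
    """Slope of the line through two points; :data:`VERTICAL` when the
    run is (numerically) zero.  Symmetric under argument swap."""
    if p1 == p2:
        raise ValueError("identical points have no slope")
    dx = p2.x - p1.x
    if abs(dx) < 1e-12:
        return VERTICAL
    return (p2.y - p1.y) / dx


def _direction(m: Slope) -> tuple[float, float]:
    if m == VERTICAL:
        return (0.0, 1.0)
    return (1.0, float(m))


def angle_between(m1: Slope, m2: Slope) -> float:
    """Acute angle in degrees between two lines given by slope.

    Computed as ``atan2(|cross|, |dot|)`` of the direction vectors,
    which coincides with ``arctan |(m1 - m2)/(1 + m1 m2)|`` wherever the
    latter is defined and extends it continuously to perpendicular and
    vertical cases.  Symmetric; range ``[0, 90]``.
    """
    v1, v2 = _direction(m1), _direction(m2)
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return math.degrees(math.atan2(abs(cross), abs(dot)))


def angle_between_lines(l1: EndplateLine, l2: EndplateLine) -> float:
    """Acute angle between two endplate lines, via direction vectors."""
    (ax, ay), (bx, by) = l1.direction, l2.direction
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    return math.degrees(math.atan2(abs(cross), abs(dot)))


def compute_lla(corners_l1: CornerSet, corners_s: CornerSet) -> tuple[float, Slope, Slope]:
    """Lumbar lordotic angle from the L1 and sacrum corner sets.

    Returns ``(lla_deg, m_L1_superior, m_S_superior)``.
    """
    line_l1 = EndplateLine(corners_l1.superior_left, corners_l1.superior_right)
    line_s = EndplateLine(corners_s.superior_left, corners_s.superior_right)
    return angle_between_lines(line_l1, line_s), line_l1.slope, line_s.slope


def compute_lsa(corners_l5: CornerSet, corners_s: CornerSet) -> tuple[float, Slope, Slope]:
    """Lumbosacral angle: L5 inferior endplate vs sacrum superior endplate.

    Returns ``(lsa_deg, m_L5_inferior, m_S_superior)``.
    """
    line_l5 = EndplateLine(corners_l5.inferior_left, corners_l5.inferior_right)
    line_s = EndplateLine(corners_s.superior_left, corners_s.superior_right)
    return angle_between_lines(line_l5, line_s), line_l5.slope, line_s.slope


def grade_lordosis(lla_deg: float, thresholds: GradeThresholds = GradeThresholds()) -> str:
    """Grade lordosis from the LLA.

    ``lla < low`` is hypolordosis, ``low <= lla <= high`` normal, and
    ``lla > high`` hyperlordosis; both boundaries are normal.
    """
    if not 0.0 <= lla_deg < 90.0:
        raise ValueError(f"LLA {lla_deg} outside [0, 90)")
    if lla_deg < thresholds.low:
        return "hypo"
    if lla_deg <= thresholds.high:
        return "normal"
    return "hyper"


def angle_report(
    corners_l1: CornerSet,
    corners_l5: CornerSet,
    corners_s: CornerSet,
    thresholds: GradeThresholds = GradeThresholds(),
) -> AngleReport:
    """Full per-case report: LLA, LSA, slopes, and the LLA-based grade."""
    lla, m_l1, m_s = compute_lla(corners_l1, corners_s)
    lsa, m_l5, _ = compute_lsa(corners_l5, corners_s)
    return AngleReport(
        lla_deg=lla,
        lsa_deg=lsa,
        m_l1_sup=m_l1,
        m_l5_inf=m_l5,
        m_s_sup=m_s,
        grade=grade_lordosis(lla, thresholds),
    )
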