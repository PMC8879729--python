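"""Vertebral endplate corner detection on segmentation masks.

Pipeline per vertebra: crop its binary mask with a margin, Gaussian
smoothing (sigma = 1 by default), Harris corner response on the smoothed
image, non-maximum suppression, then anatomical labeling of the four
strongest corners (superior/inferior x left/right) by quadrant relative
to the vertebra centroid, evaluated in the vertebra's own principal-axis
frame so that strongly tilted vertebrae (notably the sacrum) are labeled
correctly.

The Harris response is the classic ``R = det(M) - k * trace(M)^2`` over
the Gaussian-windowed structure tensor ``M`` of the image gradients;
gradients are central differences, and all smoothing uses reflective
boundaries.  Corners of a bright convex region give ``R > 0``; straight
edges give ``R <= 0``, so thresholding on a fraction of the maximum
response isolates true corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .errors import CornerAssignmentError
from .io import LabelImage, Point

#: Kernel truncation, in standard deviations, for every Gaussian here.
_TRUNCATE = 4.0


@dataclass(frozen=True)
class CornerParams:
    """Tunables of the corner detector.

    smooth_sigma
        Gaussian smoothing of the binary mask before differentiation,
        pixels (default 1).
    harris_k
        Harris sensitivity constant ``k`` (default 0.05).
    window_sigma
        Gaussian window of the structure tensor, pixels.  Default 1.2:
        wide enough to stabilize the response, narrow enough to keep the
        response peak within ~1 px of the geometric corner.
    nms_radius
        Minimum separation between accepted corners, pixels.
    rel_threshold
        Candidates must exceed this fraction of the maximum response.
    max_candidates
        Cap on candidates returned by detection.
    bias_correction
        The Harris response of a smoothed binary corner peaks a known
        distance *inside* the true corner.  When enabled (default),
        :func:`vertebra_corners` shifts each assigned corner back
        outward along its two interior edge directions by the peak
        offset of an ideal rasterized right-angle corner with the same
        sigmas, averaged over sub-pixel placements (calibrated once per
        parameter set and cached).  This is a constant systematic-bias
        compensation, not data-driven sub-pixel refinement.
    """

    smooth_sigma: float = 1.0
    harris_k: float = 0.05
    window_sigma: float = 1.2
    nms_radius: float = 5.0
    rel_threshold: float = 0.05
    max_candidates: int = 12
    bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be > 0")
        if not 0.0 < self.harris_k < 0.25:
            raise ValueError("harris_k must be in (0, 0.25)")
        if self.window_sigma <= 0:
            raise ValueError("window_sigma must be > 0")
        if self.nms_radius < 1:
            raise ValueError("nms_radius must be >= 1")
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError("rel_threshold must be in (0, 1)")
        if self.max_candidates < 4:
            raise ValueError("max_candidates must allow four corners")


class CornerCandidate(NamedTuple):
    """A detected corner with its Harris response."""

    point: Point
    response: float


@dataclass(frozen=True)
class CornerSet:
    """The four anatomically labeled corners of one vertebra.

    In the vertebra's own frame, superior corners lie above (smaller
    ``y``) the inferior ones and left corners left of the right ones;
    in image coordinates this may not hold for strongly tilted
    vertebrae.
    """

    superior_left: Point
    superior_right: Point
    inferior_left: Point
    inferior_right: Point
    responses: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def as_dict(self) -> dict[str, Point]:
        return {
            "sl": self.superior_left,
            "sr": self.superior_right,
            "il": self.inferior_left,
            "ir": self.inferior_right,
        }

    def points(self) -> tuple[Point, Point, Point, Point]:
        return (
            self.superior_left,
            self.superior_right,
            self.inferior_left,
            self.inferior_right,
        )


def gaussian_smooth(grid: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a 2-D grid (normalized kernel, truncated at 4
    sigma, reflective boundaries).  Preserves constants and total mass."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(grid, sigma=sigma, mode="reflect", truncate=_TRUNCATE)


def harris_response(image: np.ndarray, params: CornerParams = CornerParams()) -> np.ndarray:
    """Harris corner response of a real-valued grid.

    Gradients by central differences; structure-tensor components
    windowed by a Gaussian of ``params.window_sigma``;
    ``R = det(M) - k * trace(M)^2``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("need a 2-D grid of at least 3x3")
    gy, gx = np.gradient(image)

    def window(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(
            a, sigma=params.window_sigma, mode="reflect", truncate=_TRUNCATE
        )

    ixx, iyy, ixy = window(gx * gx), window(gy * gy), window(gx * gy)
    return (ixx * iyy - ixy**2) - params.harris_k * (ixx + iyy) ** 2


def detect_corners(
    response: np.ndarray, params: CornerParams = CornerParams()
) -> list[CornerCandidate]:
    """Pick corner candidates from a Harris response grid.

    Local maxima above ``rel_threshold * max(response)`` survive a
    greedy non-maximum suppression of radius ``nms_radius`` (strongest
    first; ties broken by row-major position).  At most
    ``max_candidates`` are returned, strongest first.  Points are placed
    at pixel centers (``col + 0.5, row + 0.5``).
    """
    response = np.asarray(response, dtype=float)
    if not np.all(np.isfinite(response)):
        raise ValueError("response grid contains non-finite values")
    rmax = response.max()
    if rmax <= 0:
        return []
    threshold = params.rel_threshold * rmax
    local_max = response == ndimage.maximum_filter(response, size=3, mode="reflect")
    rows, cols = np.nonzero(local_max & (response > threshold))
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -response[rows, cols]))
    rows, cols = rows[order], cols[order]
    values = response[rows, cols]

    kept: list[CornerCandidate] = []
    kept_rc: list[tuple[int, int]] = []
    r2 = params.nms_radius**2
    for r, c, v in zip(rows, cols, values):
        if any((r - kr) ** 2 + (c - kc) ** 2 <= r2 for kr, kc in kept_rc):
            continue
        kept.append(CornerCandidate(Point(c + 0.5, r + 0.5), float(v)))
        kept_rc.append((int(r), int(c)))
        if len(kept) >= params.max_candidates:
            break
    return kept


def assign_anatomical_corners(
    candidates: Sequence[CornerCandidate],
    vertebra_centroid: Point,
    axis_deg: float = 0.0,
) -> CornerSet:
    """Label candidates as superior/inferior x left/right corners.

    Each candidate falls in a quadrant relative to the centroid —
    evaluated after de-rotating offsets by ``axis_deg``, the
    orientation of the vertebra's long (endplate) axis, so quadrants
    stay anatomical for tilted vertebrae.  ``axis_deg = 0`` reduces to
    plain image-frame quadrants (``y < cy`` superior, ``x < cx`` left).
    Per quadrant the candidate with the largest Harris response wins.

    Raises
    ------
    CornerAssignmentError
        If any quadrant is empty (bad segmentation or over-smoothing).
    """
    if len(candidates) < 4:
        raise CornerAssignmentError(
            f"need at least 4 corner candidates, got {len(candidates)}"
        )
    t = math.radians(axis_deg)
    cos_t, sin_t = math.cos(t), math.sin(t)
    best: dict[tuple[bool, bool], CornerCandidate] = {}
    for cand in candidates:
        dx = cand.point.x - vertebra_centroid.x
        dy = cand.point.y - vertebra_centroid.y
        # rotate by -axis_deg into the vertebra frame
        x = cos_t * dx + sin_t * dy
        y = -sin_t * dx + cos_t * dy
        quad = (y < 0, x < 0)  # (superior?, left?)
        if quad not in best or cand.response > best[quad].response:
            best[quad] = cand
    names = {
        (True, True): "superior-left",
        (True, False): "superior-right",
        (False, True): "inferior-left",
        (False, False): "inferior-right",
    }
    for quad, name in names.items():
        if quad not in best:
            raise CornerAssignmentError(f"quadrant empty: {name}")
    sl, sr = best[(True, True)], best[(True, False)]
    il, ir = best[(False, True)], best[(False, False)]
    return CornerSet(
        superior_left=sl.point,
        superior_right=sr.point,
        inferior_left=il.point,
        inferior_right=ir.point,
        responses=(sl.response, sr.response, il.response, ir.response),
    )


@lru_cache(maxsize=16)
def _peak_bias(smooth_sigma: float, window_sigma: float, harris_k: float) -> float:
    """Per-axis inward offset of the Harris peak at an ideal right-angle
    corner of a rasterized binary rectangle, averaged over sub-pixel
    placements of the corner on the pixel grid.

    Calibrated numerically on a synthetic template (pixel-center
    rasterization of a solid rectangle, matching how solid regions are
    rasterized elsewhere in the package) over a 5x5 grid of fractional
    offsets; deterministic, cached per parameter set.
    """
    from .io import fill_polygon

    params = CornerParams(
        smooth_sigma=smooth_sigma,
        window_sigma=window_sigma,
        harris_k=harris_k,
        bias_correction=False,
    )
    n, side = 96, 40
    offsets = []
    for fx in np.linspace(0.1, 0.9, 5):
        for fy in np.linspace(0.1, 0.9, 5):
            x0, y0 = 30 + fx, 30 + fy
            img = fill_polygon(
                [x0, x0 + side, x0 + side, x0],
                [y0, y0, y0 + side, y0 + side],
                (n, n),
            ).astype(float)
            resp = harris_response(gaussian_smooth(img, smooth_sigma), params)
            top_left = resp[: int(y0) + side // 2, : int(x0) + side // 2]
            i, j = np.unravel_index(np.argmax(top_left), top_left.shape)
            offsets.append(((j + 0.5) - x0, (i + 0.5) - y0))
    return float(np.mean(offsets))


def _debias(corners: CornerSet, bias: float) -> CornerSet:
    """Shift each corner outward along its two interior edge directions
    (estimated from the corner set itself) by the calibrated bias."""
    d = corners.as_dict()
    neighbors = {"sl": ("sr", "il"), "sr": ("sl", "ir"),
                 "il": ("ir", "sl"), "ir": ("il", "sr")}

    def unit(p: Point, q: Point) -> tuple[float, float]:
        dx, dy = q.x - p.x, q.y - p.y
        norm = math.hypot(dx, dy)
        return (dx / norm, dy / norm) if norm > 0 else (0.0, 0.0)

    out = {}
    for key, (a, b) in neighbors.items():
        e1, e2 = unit(d[key], d[a]), unit(d[key], d[b])
        out[key] = Point(
            d[key].x - bias * (e1[0] + e2[0]),
            d[key].y - bias * (e1[1] + e2[1]),
        )
    return CornerSet(out["sl"], out["sr"], out["il"], out["ir"], corners.responses)


def mask_orientation(mask: np.ndarray) -> float:
    """Orientation of a binary mask's principal (long) axis, degrees in
    ``(-90, 90]``, measured from the image x-axis (y down)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    x = cols + 0.5 - (cols.mean() + 0.5)
    y = rows + 0.5 - (rows.mean() + 0.5)
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    deg = math.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return deg


def vertebra_corners(
    label_image: LabelImage,
    vertebra: str | int,
    params: CornerParams = CornerParams(),
    margin_sigmas: float = 4.0,
) -> CornerSet:
    """Detect and label the four corners of one vertebra.

    Crops the vertebra's binary mask with a margin of
    ``margin_sigmas * window_sigma`` pixels, runs smoothing, Harris
    response, candidate detection and anatomical assignment, and maps
    the corners back to whole-image coordinates.

    ``vertebra`` may be a label value or a vertebra name resolved
    through the image's label map.
    """
    value = label_image.value_of(vertebra) if isinstance(vertebra, str) else int(vertebra)
    mask = label_image.mask(value)
    if not mask.any():
        raise KeyError(f"vertebra {vertebra!r} absent from label image")
    rows, cols = np.nonzero(mask)
    margin = max(2, int(math.ceil(margin_sigmas * params.window_sigma)))
    # pad with background (zeros) even past the image border, so corners
    # of a vertebra flush against the edge still produce gradients
    r0 = int(rows.min()) - margin
    r1 = int(rows.max()) + 1 + margin
    c0 = int(cols.min()) - margin
    c1 = int(cols.max()) + 1 + margin
    crop = np.zeros((r1 - r0, c1 - c0))
    rr0, rr1 = max(r0, 0), min(r1, mask.shape[0])
    cc0, cc1 = max(c0, 0), min(c1, mask.shape[1])
    crop[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = mask[rr0:rr1, cc0:cc1]

    smoothed = gaussian_smooth(crop, params.smooth_sigma)
    response = harris_response(smoothed, params)
    candidates = detect_corners(response, params)

    cy, cx = ndimage.center_of_mass(crop)
    centroid = Point(cx + 0.5, cy + 0.5)
    axis = mask_orientation(crop > 0)
    corners = assign_anatomical_corners(candidates, centroid, axis_deg=axis)

    def to_image(p: Point) -> Point:
        return Point(p.x + c0, p.y + r0)

    result = CornerSet(
        superior_left=to_image(corners.superior_left),
        superior_right=to_image(corners.superior_right),
        inferior_left=to_image(corners.inferior_left),
        inferior_right=to_image(corners.inferior_right),
        responses=corners.responses,
    )
    if params.bias_correction:
        result = _debias(
            result, _peak_bias(params.smooth_sigma, params.window_sigma, params.harris_k)
        )
    return result
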