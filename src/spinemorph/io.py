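"""Reading/writing the pipeline's file formats and box/mask geometry.

Coordinate conventions
----------------------
Continuous image coordinates with the origin at the top-left corner,
``x`` increasing to the right (columns) and ``y`` increasing downward
(rows).  The integer pixel ``(r, c)`` occupies the continuous square
``[c, c+1) x [r, r+1)`` and has its center at ``(c + 0.5, r + 0.5)``.
Tight bounding boxes over pixel sets are therefore half-open: a single
pixel at row 5, column 5 yields the box ``(5, 5, 6, 6)``, whose area
equals the pixel count.

YOLO annotation format: one row per object, ``class cx cy w h [conf]``,
all box fields normalized to ``[0, 1]`` by image width/height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from PIL import Image

from .errors import VertebraCountError, YoloParseError

#: Anatomical order, superior to inferior, of the structures the pipeline
#: tracks: the five lumbar vertebrae and the first sacral vertebra.
VERTEBRA_NAMES: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5", "S")

#: Default mapping of label-image values to vertebra names (0 = background).
DEFAULT_LABEL_MAP: dict[int, str] = {i + 1: n for i, n in enumerate(VERTEBRA_NAMES)}


@dataclass(frozen=True)
class Point:
    """A point in continuous image coordinates (pixels)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous pixel coordinates.

    ``label`` is one of :data:`VERTEBRA_NAMES` once assigned (detections
    arrive unlabeled and are named by :func:`sort_vertebrae`).
    ``confidence`` is present on detections, absent on ground truth.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"inverted box {self}")
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError(f"negative coordinates in {self}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return replace(
            self,
            xmin=self.xmin + dx,
            xmax=self.xmax + dx,
            ymin=self.ymin + dy,
            ymax=self.ymax + dy,
        )


@dataclass
class LabelImage:
    """Integer raster of vertebra instance masks; background is 0."""

    pixels: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("label image must be integer-valued")
        if self.pixels.min() < 0:
            raise ValueError("label values must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def mask(self, value: int) -> np.ndarray:
        """Binary mask (bool) of one label value."""
        return self.pixels == value

    def value_of(self, name: str) -> int:
        for value, n in self.label_map.items():
            if n == name:
                return value
        raise KeyError(f"vertebra {name!r} not in label map")


def centroid(box: BoundingBox) -> Point:
    """Center of a box: the midpoint of its min/max corners."""
    return Point((box.xmin + box.xmax) / 2.0, (box.ymin + box.ymax) / 2.0)


def read_yolo(path: str | Path, image_height: int, image_width: int) -> list[BoundingBox]:
    """Parse a YOLO-format txt file into pixel-coordinate boxes.

    Rows with 5 fields are ground truth; rows with 6 carry a trailing
    confidence.  Normalized centers/sizes are de-normalized as
    ``xmin = (cx - w/2) * W`` etc.  Row order is preserved; anatomical
    labels are assigned later by :func:`sort_vertebrae`.

    Raises
    ------
    YoloParseError
        On a malformed row (wrong field count, non-numeric value, or a
        normalized value outside ``[0, 1]``), naming the line number.
    """
    boxes: list[BoundingBox] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise YoloParseError(
                f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}"
            )
        try:
            values = [float(v) for v in fields]
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        _, cx, cy, w, h = values[:5]
        conf = values[5] if len(values) == 6 else None
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not 0.0 <= v <= 1.0:
                raise YoloParseError(f"{path}:{lineno}: {name}={v} outside [0, 1]")
        if conf is not None and not 0.0 <= conf <= 1.0:
            raise YoloParseError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
        boxes.append(
            BoundingBox(
                xmin=(cx - w / 2) * image_width,
                ymin=(cy - h / 2) * image_height,
                xmax=(cx + w / 2) * image_width,
                ymax=(cy + h / 2) * image_height,
                confidence=conf,
            )
        )
    return boxes


def write_yolo(
    boxes: Sequence[BoundingBox],
    path: str | Path,
    image_height: int,
    image_width: int,
) -> Path:
    """Write boxes as YOLO rows (class 0, 6-decimal floats), inverse of
    :func:`read_yolo`.  Boxes are written as-is, never clamped."""
    lines = []
    for b in boxes:
        cx = (b.xmin + b.xmax) / 2.0 / image_width
        cy = (b.ymin + b.ymax) / 2.0 / image_height
        w = b.width / image_width
        h = b.height / image_height
        row = f"0 {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if b.confidence is not None:
            row += f" {b.confidence:.6f}"
        lines.append(row)
    path = Path(path)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def boxes_from_label_image(img: LabelImage) -> list[BoundingBox]:
    """Tight bounding box per label value present in the raster.

    The half-open pixel convention makes ``xmax = max column + 1`` (and
    likewise for rows), so a mask of an exact rectangle has box area
    equal to its pixel count.  Labels named in ``label_map`` but absent
    from the raster are skipped with a warning.
    """
    values = [v for v in np.unique(img.pixels) if v != 0]
    if not values:
        warnings.warn("label image contains no nonzero labels", stacklevel=2)
    boxes = []
    for v in values:
        rows, cols = np.nonzero(img.pixels == v)
        boxes.append(
            BoundingBox(
                xmin=float(cols.min()),
                ymin=float(rows.min()),
                xmax=float(cols.max()) + 1.0,
                ymax=float(rows.max()) + 1.0,
                label=img.label_map.get(int(v)),
            )
        )
    missing = set(img.label_map) - {int(v) for v in values}
    if missing and values:
        warnings.warn(f"labels with zero pixels omitted: {sorted(missing)}", stacklevel=2)
    return boxes


def sort_vertebrae(
    boxes: Sequence[BoundingBox], expected: int = 6
) -> list[BoundingBox]:
    """Order boxes superiorly-to-inferiorly and assign anatomical names.

    The detector sees a single class, so anatomy comes from geometry:
    in a head-up sagittal image the superior vertebra has the smaller
    centroid ``y``.  Ties in ``y`` break by centroid ``x`` ascending.

    Raises
    ------
    VertebraCountError
        If the number of boxes differs from ``expected`` (a missed or
        spurious detection upstream).
    """
    if len(boxes) != expected:
        raise VertebraCountError(f"expected {expected} vertebra boxes, found {len(boxes)}")
    ordered = sorted(boxes, key=lambda b: (centroid(b).y, centroid(b).x))
    names = VERTEBRA_NAMES if expected == 6 else tuple(f"V{i+1}" for i in range(expected))
    return [replace(b, label=name) for b, name in zip(ordered, names)]


def fill_polygon(
    xs: Sequence[float], ys: Sequence[float], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a closed polygon onto a boolean canvas.

    A pixel is set when its center lies inside the polygon or on its
    boundary (even-odd rule).  This center-sampling rule is symmetric:
    no edge direction is systematically over- or under-drawn, so a
    rectangle of continuous area A rasterizes to A pixels on average.
    Degenerate (zero-area) polygons reduce to their boundary line.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    area2 = np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))
    degenerate = abs(area2) <= 1e-9
    if degenerate:
        geom = shapely.LineString(list(zip(xs, ys)) + [(xs[0], ys[0])])
    else:
        poly = shapely.Polygon(zip(xs, ys))
        geom = shapely.union(poly, poly.boundary)
    mask = np.zeros(shape, dtype=bool)
    c0 = max(0, int(np.floor(xs.min() - 1)))
    c1 = min(shape[1] - 1, int(np.ceil(xs.max() + 1)))
    r0 = max(0, int(np.floor(ys.min() - 1)))
    r1 = min(shape[0] - 1, int(np.ceil(ys.max() + 1)))
    if c1 < c0 or r1 < r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    if degenerate:
        # a zero-area ring draws as a line: mark every pixel square the
        # line passes through (center sampling would mostly miss it)
        cells = shapely.box(cols.ravel(), rows.ravel(), cols.ravel() + 1, rows.ravel() + 1)
        hit = shapely.intersects(geom, cells).reshape(cols.shape)
        mask[r0 : r1 + 1, c0 : c1 + 1] = hit
    else:
        mask[r0 : r1 + 1, c0 : c1 + 1] = shapely.intersects_xy(geom, cols + 0.5, rows + 0.5)
    return mask


def write_label_png(img: LabelImage, path: str | Path) -> Path:
    """Save a label raster as an 8-bit single-channel PNG (values 0-6)."""
    if img.pixels.max() > 255:
        raise ValueError("label values exceed 8-bit range")
    path = Path(path)
    Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(path)
    return path


def read_label_png(
    path: str | Path, label_map: dict[int, str] | None = None
) -> LabelImage:
    """Load an 8-bit label PNG back into a :class:`LabelImage`."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int64)
    return LabelImage(arr, dict(label_map or DEFAULT_LABEL_MAP))


def write_pseudocolor_png(
    img: LabelImage,
    path: str | Path,
    palette: Sequence[tuple[int, int, int]] | None = None,
) -> Path:
    """Optional pseudo-color render of a label image.

    The palette maps label values 1..6 to RGB; the default is a fixed
    six-color qualitative palette (any dataset-specific coloring can be
    passed instead).
    """
    default = [
        (228, 26, 28), (55, 126, 184), (77, 175, 74),
        (152, 78, 163), (255, 127, 0), (255, 255, 51),
    ]
    palette = list(palette or default)
    rgb = np.zeros((*img.pixels.shape, 3), dtype=np.uint8)
    for value in np.unique(img.pixels):
        if value == 0:
            continue
        rgb[img.pixels == value] = palette[(int(value) - 1) % len(palette)]
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path
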