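"""Synthetic sagittal spine phantoms with known ground-truth geometry.

A phantom is a 2-D label image of six vertebral bodies — L1 through L5
and the first sacral vertebra S — stacked superior-to-inferior along a
gently curved column, each modeled as an isosceles trapezoid (a
near-rectangle whose inferior endplate is slightly shorter), tilted by a
per-vertebra endplate angle.  The sacrum carries the largest tilt by
default, as it does anatomically.  Because the geometry is constructed
analytically, every downstream quantity — bounding boxes, corner
positions, lumbar lordotic angle (LLA), lumbosacral angle (LSA), grade —
is known exactly and serves as ground truth for the measurement
pipeline.

Ground-truth angles come from the specified endplate tilts (LLA = acute
angle between the L1 and S superior-endplate directions; LSA = acute
angle between the L5 inferior and S superior directions).  Boundary
jitter perturbs the trapezoid vertices before rasterization and is thus
measurement noise the pipeline must overcome, while the analytic truth
stays fixed — mirroring a ground-truth-vs-measured evaluation.  Salt &
pepper noise applies only to an optional grayscale render; the label
raster is always clean.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as smio
from .angles import GradeThresholds, grade_lordosis
from .corners import CornerSet
from .errors import PhantomGenerationError
from .io import BoundingBox, LabelImage, Point, VERTEBRA_NAMES

#: Default per-vertebra endplate tilts, degrees from horizontal, L1..S.
#: A mildly lordotic column; the sacrum is the most tilted element.
DEFAULT_TILTS: tuple[float, ...] = (0.0, 5.0, 10.0, 18.0, 28.0, 48.0)

#: Tilt profile: each vertebra's tilt as a fraction of the S-vs-L1 tilt
#: difference, used when a cohort samples a target LLA.
TILT_PROFILE: tuple[float, ...] = tuple(t / DEFAULT_TILTS[-1] for t in DEFAULT_TILTS)

#: LLA intervals (degrees) sampled per grade when generating cohorts.
GRADE_INTERVALS: dict[str, tuple[float, float]] = {
    "hypo": (5.0, 39.0),
    "normal": (39.0, 53.0),
    "hyper": (53.0, 85.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise knobs: vertex jitter on the label geometry (pixels) and the
    salt & pepper fraction for the optional grayscale render."""

    boundary_jitter_px: float = 0.0
    salt_pepper_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.boundary_jitter_px < 0:
            raise ValueError("boundary_jitter_px must be >= 0")
        if not 0.0 <= self.salt_pepper_fraction <= 1.0:
            raise ValueError("salt_pepper_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic spine case.

    ``endplate_tilts`` are the tilts of each vertebra's long axis from
    horizontal, degrees, image convention (positive tilts the right end
    downward), ordered L1..S.  ``curve_offset_amplitude`` bows the
    column horizontally.  ``taper`` is the inferior/superior endplate
    width ratio of the trapezoidal bodies.
    """

    image_height: int = 320
    image_width: int = 320
    n_vertebrae: int = 6
    vertebra_height: int = 26
    vertebra_width: int = 54
    gap: int = 6
    endplate_tilts: tuple[float, ...] = DEFAULT_TILTS
    curve_offset_amplitude: float = 18.0
    taper: float = 0.9
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae != 6:
            raise ValueError("phantoms model exactly 6 vertebrae (L1-L5, S)")
        if min(self.image_height, self.image_width, self.vertebra_height,
               self.vertebra_width) <= 0 or self.gap < 0:
            raise ValueError("pixel dimensions must be positive")
        if len(self.endplate_tilts) != 6:
            raise ValueError("need one endplate tilt per vertebra")
        if not 0.5 <= self.taper <= 1.0:
            raise ValueError("taper must be in [0.5, 1]")


@dataclass(frozen=True)
class PhantomCase:
    """A generated phantom and its complete ground truth."""

    label_image: LabelImage
    boxes: tuple[BoundingBox, ...]
    true_corners: dict[str, CornerSet]
    true_lla_deg: float
    true_lsa_deg: float
    true_grade: str
    spec: PhantomSpec


def _acute(delta_deg: float) -> float:
    """Fold an angle difference into the acute range [0, 90)."""
    d = abs(delta_deg) % 180.0
    return 180.0 - d if d > 90.0 else d


def _trapezoid(cx: float, cy: float, spec: PhantomSpec, tilt_deg: float
               ) -> dict[str, Point]:
    """Vertex positions (sl, sr, il, ir) of one tilted trapezoid."""
    t = math.radians(tilt_deg)
    ux, uy = math.cos(t), math.sin(t)          # long (endplate) axis
    vx, vy = -math.sin(t), math.cos(t)         # short axis, toward inferior
    hw_sup = spec.vertebra_width / 2.0
    hw_inf = hw_sup * spec.taper
    hh = spec.vertebra_height / 2.0
    return {
        "sl": Point(cx - hh * vx - hw_sup * ux, cy - hh * vy - hw_sup * uy),
        "sr": Point(cx - hh * vx + hw_sup * ux, cy - hh * vy + hw_sup * uy),
        "il": Point(cx + hh * vx - hw_inf * ux, cy + hh * vy - hw_inf * uy),
        "ir": Point(cx + hh * vx + hw_inf * ux, cy + hh * vy + hw_inf * uy),
    }


def _vertical_half_extent(spec: PhantomSpec, tilt_deg: float) -> float:
    t = math.radians(tilt_deg)
    return (spec.vertebra_width * abs(math.sin(t))
            + spec.vertebra_height * abs(math.cos(t))) / 2.0


def _rasterize(vertices: Sequence[dict[str, Point]], shape: tuple[int, int]
               ) -> np.ndarray:
    """Fill each trapezoid (interior + boundary) onto a label canvas;
    raises on overlap between vertebrae."""
    canvas = np.zeros(shape, dtype=np.int64)
    for idx, verts in enumerate(vertices, start=1):
        order = [verts["sl"], verts["sr"], verts["ir"], verts["il"]]
        mask = smio.fill_polygon(
            [p.x for p in order], [p.y for p in order], shape
        )
        if np.any(canvas[mask] != 0):
            raise PhantomGenerationError(f"vertebra {idx} overlaps a neighbor")
        canvas[mask] = idx
    return canvas


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; identical specs (incl. seed) produce
    bit-identical rasters.

    Raises
    ------
    PhantomGenerationError
        If a vertebra falls outside the canvas, or jittered vertebrae
        still overlap after a few re-draws.
    """
    n = spec.n_vertebrae
    extents = [_vertical_half_extent(spec, t) for t in spec.endplate_tilts]
    column = 2.0 * sum(extents) + spec.gap * (n - 1)
    if column > spec.image_height:
        raise PhantomGenerationError(
            f"column height {column:.0f} px exceeds image height {spec.image_height}"
        )
    top = (spec.image_height - column) / 2.0
    centers: list[tuple[float, float]] = []
    y = top
    for i, e in enumerate(extents):
        cy = y + e
        cx = spec.image_width / 2.0 + spec.curve_offset_amplitude * math.sin(
            math.pi * i / (n - 1)
        )
        centers.append((cx, cy))
        y = cy + e + spec.gap

    rng = np.random.default_rng(spec.seed)
    # random sub-pixel placement phase: real scans land on the pixel grid
    # at arbitrary fractional offsets, so the phantom should too
    phase = rng.uniform(0.0, 1.0, size=2)
    centers = [(cx + phase[0], cy + phase[1]) for cx, cy in centers]
    jitter = spec.noise.boundary_jitter_px
    last_err: PhantomGenerationError | None = None
    for _attempt in range(5):
        vertices = []
        for (cx, cy), tilt in zip(centers, spec.endplate_tilts):
            verts = _trapezoid(cx, cy, spec, tilt)
            if jitter > 0:
                verts = {
                    k: Point(p.x + rng.uniform(-jitter, jitter),
                             p.y + rng.uniform(-jitter, jitter))
                    for k, p in verts.items()
                }
            for p in verts.values():
                if not (0 <= p.x < spec.image_width and 0 <= p.y < spec.image_height):
                    raise PhantomGenerationError(
                        f"vertex {p} outside {spec.image_width}x{spec.image_height} canvas"
                    )
            vertices.append(verts)
        try:
            canvas = _rasterize(vertices, (spec.image_height, spec.image_width))
            break
        except PhantomGenerationError as err:
            last_err = err
    else:
        raise PhantomGenerationError(f"could not place vertebrae: {last_err}")

    label_image = LabelImage(canvas)
    # label values ascend 1..6, so boxes arrive in L1..S order already
    boxes = tuple(smio.boxes_from_label_image(label_image))
    true_corners = {
        name: CornerSet(v["sl"], v["sr"], v["il"], v["ir"])
        for name, v in zip(VERTEBRA_NAMES, vertices)
    }
    lla = _acute(spec.endplate_tilts[5] - spec.endplate_tilts[0])
    lsa = _acute(spec.endplate_tilts[5] - spec.endplate_tilts[4])
    return PhantomCase(
        label_image=label_image,
        boxes=boxes,
        true_corners=true_corners,
        true_lla_deg=lla,
        true_lsa_deg=lsa,
        true_grade=grade_lordosis(lla),
        spec=spec,
    )


def render_grayscale(case: PhantomCase) -> np.ndarray:
    """Companion grayscale render (uint8): bone bright on dark, with the
    spec's salt & pepper fraction applied.  The label raster is never
    noised."""
    img = np.where(case.label_image.pixels > 0, 200, 30).astype(np.uint8)
    frac = case.spec.noise.salt_pepper_fraction
    if frac > 0:
        rng = np.random.default_rng(case.spec.seed + 1)
        noisy = rng.random(img.shape) < frac
        salt = rng.random(img.shape) < 0.5
        img[noisy & salt] = 255
        img[noisy & ~salt] = 0
    return img


def write_phantom(case: PhantomCase, out_dir: str | Path, basename: str = "case"
                  ) -> dict[str, Path]:
    """Write one case: label PNG, YOLO ground-truth txt with the same
    basename, and a JSON sidecar with true corners, angles and grade."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = case.label_image.height, case.label_image.width
    png = smio.write_label_png(case.label_image, out_dir / f"{basename}.png")
    txt = smio.write_yolo(case.boxes, out_dir / f"{basename}.txt", h, w)
    sidecar = {
        "corners": {
            name: {k: [p.x, p.y] for k, p in cs.as_dict().items()}
            for name, cs in case.true_corners.items()
        },
        "lla_deg": case.true_lla_deg,
        "lsa_deg": case.true_lsa_deg,
        "grade": case.true_grade,
    }
    jpath = out_dir / f"{basename}.json"
    jpath.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return {"label_png": png, "yolo_txt": txt, "truth_json": jpath}


def checksum(case: PhantomCase) -> str:
    """MD5 of the label raster bytes — a cheap determinism fingerprint."""
    return hashlib.md5(case.label_image.pixels.astype(np.uint8).tobytes()).hexdigest()


def _allocate(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n cases to classes."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    n: int,
    grade_mix: Sequence[float],
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    thresholds: GradeThresholds = GradeThresholds(),
) -> list[PhantomCase]:
    """Generate a cohort whose true grades follow ``grade_mix``.

    ``grade_mix`` gives the (hypo, normal, hyper) proportions; counts
    use largest-remainder rounding so, e.g., 51 cases at proportions
    (6/51, 19/51, 26/51) yield exactly (6, 19, 26).  Per case, the
    S-vs-L1 tilt difference (which equals the LLA) is sampled uniformly
    within the target class's angle interval and the intermediate tilts
    follow the default tilt profile.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(grade_mix) != 3 or abs(sum(grade_mix) - 1.0) > 1e-9 or min(grade_mix) < 0:
        raise ValueError("grade_mix must be 3 non-negative proportions summing to 1")
    intervals = {
        "hypo": (GRADE_INTERVALS["hypo"][0], thresholds.low),
        "normal": (thresholds.low, thresholds.high),
        "hyper": (thresholds.high, GRADE_INTERVALS["hyper"][1]),
    }
    for g, (lo, hi) in intervals.items():
        if not lo < hi:
            raise ValueError(f"empty angle interval for class {g}")
    counts = _allocate(n, grade_mix)
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for grade, count in zip(("hypo", "normal", "hyper"), counts):
        lo, hi = intervals[grade]
        # keep clear of the class boundary so jitter cannot flip the truth
        pad = 0.02 * (hi - lo)
        for _ in range(count):
            delta = float(rng.uniform(lo + pad, hi - pad))
            tilts = tuple(delta * f for f in TILT_PROFILE)
            case_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(base_spec, endplate_tilts=tilts, seed=case_seed)
            cases.append(generate_phantom(spec))
    return cases
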