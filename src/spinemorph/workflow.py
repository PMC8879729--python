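"""Batch orchestration: cohort generation, measurement, evaluation.

These functions are the engine behind the command-line interface; they
operate on directories of cases (label PNG + YOLO txt + truth JSON per
case) and emit CSV/JSON reports.  A failing case is logged and flagged,
never aborts the batch.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as smio
from .angles import AngleReport, GradeThresholds, angle_report
from .corners import CornerParams, vertebra_corners
from .errors import SpinemorphError
from .evaluation import (
    MatchParams,
    confusion_and_accuracy,
    euclidean_distance,
    iou,
    map_over_thresholds,
    mean_error,
)
from .io import Point, VERTEBRA_NAMES
from .phantom import PhantomSpec, checksum, generate_cohort, write_phantom
from .region_area import (
    AreaThresholds,
    RegionAreaResult,
    calibrate_area_thresholds,
    region_area_result,
)

log = logging.getLogger("spinemorph")

#: Cohort grade proportions mirroring the 51-subject clinical test split
#: (6 hypolordotic, 19 normal, 26 hyperlordotic).
DEFAULT_GRADE_MIX: tuple[float, float, float] = (6 / 51, 19 / 51, 26 / 51)


def measure_case(
    label_image: smio.LabelImage,
    corner_params: CornerParams = CornerParams(),
    thresholds: GradeThresholds = GradeThresholds(),
    area_thresholds: AreaThresholds | None = None,
) -> tuple[AngleReport, RegionAreaResult]:
    """Full measurement of one segmented case: Harris corners of L1, L5
    and S → LLA/LSA/grade, plus the centroid-polygon region area."""
    cs_l1 = vertebra_corners(label_image, "L1", corner_params)
    cs_l5 = vertebra_corners(label_image, "L5", corner_params)
    cs_s = vertebra_corners(label_image, "S", corner_params)
    report = angle_report(cs_l1, cs_l5, cs_s, thresholds)
    boxes = smio.boxes_from_label_image(label_image)
    area = region_area_result(
        boxes, label_image.height, label_image.width, area_thresholds
    )
    return report, area


def run_phantom_cohort(
    out_dir: str | Path,
    n: int = 51,
    grade_mix: Sequence[float] = DEFAULT_GRADE_MIX,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate and write a phantom cohort plus a manifest CSV.

    The manifest records per-case ground truth and a raster checksum so
    reruns under the same seed can be verified byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = generate_cohort(n, grade_mix, base_spec, seed)
    rows = []
    for i, case in enumerate(cases):
        case_id = f"case_{i:03d}"
        write_phantom(case, out_dir, case_id)
        rows.append(
            {
                "case_id": case_id,
                "lla_deg": round(case.true_lla_deg, 6),
                "lsa_deg": round(case.true_lsa_deg, 6),
                "grade": case.true_grade,
                "checksum": checksum(case),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _discover_cases(in_dir: Path) -> list[str]:
    return sorted(p.stem for p in in_dir.glob("*.png"))


def run_measure(
    in_dir: str | Path,
    out_csv: str | Path | None = None,
    corner_params: CornerParams = CornerParams(),
    thresholds: GradeThresholds = GradeThresholds(),
    area_thresholds: AreaThresholds | None = None,
) -> pd.DataFrame:
    """Measure every case (label PNG) in a directory.

    Output columns: case_id, lla_deg, lsa_deg, grade, area_px,
    area_grade, status.  Per-case failures are logged with the case id
    and flagged in ``status``; the batch continues.
    """
    in_dir = Path(in_dir)
    case_ids = _discover_cases(in_dir)
    if not case_ids:
        raise SpinemorphError(f"no readable cases (label PNGs) in {in_dir}")
    rows = []
    for case_id in case_ids:
        try:
            img = smio.read_label_png(in_dir / f"{case_id}.png")
            report, area = measure_case(img, corner_params, thresholds, area_thresholds)
            rows.append(
                {
                    "case_id": case_id,
                    "lla_deg": round(report.lla_deg, 6),
                    "lsa_deg": round(report.lsa_deg, 6),
                    "grade": report.grade,
                    "area_px": area.area_px,
                    "area_grade": area.grade,
                    "status": "ok",
                }
            )
        except (SpinemorphError, KeyError, ValueError) as err:
            log.warning("case %s failed: %s", case_id, err)
            rows.append(
                {
                    "case_id": case_id,
                    "lla_deg": np.nan,
                    "lsa_deg": np.nan,
                    "grade": "failed",
                    "area_px": np.nan,
                    "area_grade": "failed",
                    "status": f"error: {err}",
                }
            )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_evaluate(
    gt_dir: str | Path,
    pred_dir: str | Path,
    image_height: int = 320,
    image_width: int = 320,
    match_params: MatchParams = MatchParams(),
    pixel_spacing_mm: float = 1.0,
    measured_csv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> dict:
    """Score predicted YOLO boxes (and optionally measured angles)
    against ground truth.

    ``gt_dir`` holds per-case ground-truth txt (+ truth JSON sidecars);
    ``pred_dir`` holds detection txt with confidences, same basenames.
    Per-vertebra EU/IOU use the six sorted, confidence-filtered
    predictions; mAP is computed over the pooled raw detections.  If
    ``measured_csv`` (from :func:`run_measure`) is given and truth
    sidecars exist, angle mean errors and grading confusion matrices are
    added.
    """
    gt_dir, pred_dir = Path(gt_dir), Path(pred_dir)
    case_ids = sorted(p.stem for p in gt_dir.glob("*.txt"))
    if not case_ids:
        raise SpinemorphError(f"no ground-truth txt files in {gt_dir}")
    missing = [c for c in case_ids if not (pred_dir / f"{c}.txt").exists()]
    if missing:
        raise SpinemorphError(f"predictions missing for cases: {missing[:5]}")

    gt_sets, pred_sets = [], []
    eu_by_label: dict[str, list[float]] = {n: [] for n in VERTEBRA_NAMES}
    iou_by_label: dict[str, list[float]] = {n: [] for n in VERTEBRA_NAMES}
    flagged = []
    for case_id in case_ids:
        gt = smio.read_yolo(gt_dir / f"{case_id}.txt", image_height, image_width)
        pred = smio.read_yolo(pred_dir / f"{case_id}.txt", image_height, image_width)
        gt_sets.append(gt)
        pred_sets.append(pred)
        confident = [p for p in pred if (p.confidence or 0.0) >= match_params.conf_threshold]
        try:
            gt_sorted = smio.sort_vertebrae(gt)
            pred_sorted = smio.sort_vertebrae(confident)
        except SpinemorphError as err:
            log.warning("case %s: %s", case_id, err)
            flagged.append(case_id)
            continue
        for g, p in zip(gt_sorted, pred_sorted):
            eu_by_label[g.label].append(
                euclidean_distance(smio.centroid(g), smio.centroid(p), pixel_spacing_mm)
            )
            iou_by_label[g.label].append(iou(g, p))

    maps = map_over_thresholds(gt_sets, pred_sets)
    report: dict = {
        "n_cases": len(case_ids),
        "flagged_cases": flagged,
        "per_vertebra": {
            name: {
                "eu_mean": float(np.mean(eu_by_label[name])) if eu_by_label[name] else None,
                "eu_std": float(np.std(eu_by_label[name])) if eu_by_label[name] else None,
                "iou_mean": float(np.mean(iou_by_label[name])) if iou_by_label[name] else None,
                "iou_std": float(np.std(iou_by_label[name])) if iou_by_label[name] else None,
            }
            for name in VERTEBRA_NAMES
        },
        "map50": maps["map50"],
        "map5095": maps["map5095"],
    }

    if measured_csv is not None:
        measured = pd.read_csv(measured_csv).set_index("case_id")
        truth_rows = []
        for case_id in case_ids:
            sidecar = gt_dir / f"{case_id}.json"
            if sidecar.exists() and case_id in measured.index:
                truth = json.loads(sidecar.read_text())
                truth_rows.append((case_id, truth))
        if truth_rows:
            ids = [c for c, _ in truth_rows]
            sub = measured.loc[ids]
            ok = sub["status"] == "ok"
            report["angle_me"] = {
                "lla": mean_error(
                    sub.loc[ok, "lla_deg"], [t["lla_deg"] for (c, t) in truth_rows if ok[c]]
                ),
                "lsa": mean_error(
                    sub.loc[ok, "lsa_deg"], [t["lsa_deg"] for (c, t) in truth_rows if ok[c]]
                ),
            }
            true_grades = [t["grade"] for (c, t) in truth_rows if ok[c]]
            counts, acc = confusion_and_accuracy(true_grades, list(sub.loc[ok, "grade"]))
            report["confusion"] = counts.tolist()
            report["accuracy"] = acc
            if "area_grade" in sub.columns and not (sub.loc[ok, "area_grade"] == "uncalibrated").any():
                a_counts, a_acc = confusion_and_accuracy(
                    true_grades, list(sub.loc[ok, "area_grade"])
                )
                report["area_confusion"] = a_counts.tolist()
                report["area_accuracy"] = a_acc

    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def calibrate_from_tables(
    measured_csv: str | Path, truth_csv: str | Path, out_json: str | Path | None = None
) -> AreaThresholds:
    """Calibrate area cut-points from a measured CSV (``area_px``) and a
    truth table (``case_id,...,grade``)."""
    measured = pd.read_csv(measured_csv).set_index("case_id")
    truth = pd.read_csv(truth_csv).set_index("case_id")
    joined = measured.join(truth["grade"].rename("true_grade"), how="inner")
    joined = joined[joined["status"] == "ok"] if "status" in joined else joined
    thresholds = calibrate_area_thresholds(
        list(joined["area_px"]), list(joined["true_grade"])
    )
    if out_json is not None:
        Path(out_json).write_text(
            json.dumps(
                {"low_cut": thresholds.low_cut, "high_cut": thresholds.high_cut}, indent=2
            )
            + "\n"
        )
    return thresholds
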