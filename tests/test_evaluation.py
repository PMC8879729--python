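"""Detection and grading metrics, with independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spinemorph.evaluation import (
    MatchParams,
    average_precision,
    confusion_and_accuracy,
    euclidean_distance,
    iou,
    map_over_thresholds,
    match_detections,
    mean_error,
    mean_eu,
    nms,
    precision_recall,
)
from spinemorph.io import BoundingBox, Point


def _box(x0, y0, x1, y1, conf=None):
    return BoundingBox(x0, y0, x1, y1, confidence=conf)


class TestEuclidean:
    def test_examples(self):
        assert euclidean_distance(Point(1, 1), Point(1, 1)) == 0.0
        assert euclidean_distance(Point(0, 0), Point(3, 4)) == 5.0
        assert euclidean_distance(Point(0, 0), Point(3, 4), 0.5) == 2.5

    def test_mean_eu_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        d = list(rng.random(1000) * 10)
        total = 0.0
        for v in d:
            total += v
        assert mean_eu(d) == pytest.approx(total / len(d), abs=1e-9)

    def test_mean_of_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_eu([])


class TestIou:
    def test_identical_and_disjoint(self):
        a = _box(0, 0, 2, 2)
        assert iou(a, a) == 1.0
        assert iou(a, _box(5, 5, 7, 7)) == 0.0

    def test_one_seventh_overlap_vs_pixel_grid_oracle(self):
        a, b = _box(0, 0, 2, 2), _box(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7, abs=1e-12)
        # fine-grid Monte-Carlo-free oracle: count subpixel cells
        n = 600  # grid over [0,3]^2, cell 0.005
        xs = (np.arange(n) + 0.5) * 3 / n
        gx, gy = np.meshgrid(xs, xs)
        in_a = (gx < 2) & (gy < 2)
        in_b = (gx > 1) & (gy > 1)
        grid_iou = (in_a & in_b).sum() / (in_a | in_b).sum()
        assert iou(a, b) == pytest.approx(grid_iou, abs=0.01)

    def test_degenerate_boxes_give_zero(self):
        assert iou(_box(2, 2, 2, 2), _box(2, 2, 2, 2)) == 0.0

    @given(
        x=st.floats(0, 50), y=st.floats(0, 50),
        dx=st.floats(0, 30), dy=st.floats(0, 30),
        shift=st.floats(0, 20),
    )
    def test_symmetric_bounded_translation_invariant(self, x, y, dx, dy, shift):
        a = _box(x, y, x + dx + 1, y + dy + 1)
        b = _box(x + shift, y, x + shift + dx + 1, y + dy + 1)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        assert iou(a.shifted(5, 7), b.shifted(5, 7)) == pytest.approx(v, abs=1e-12)


class TestMeanError:
    def test_examples(self):
        assert mean_error([40, 50], [40, 50]) == 0.0
        assert mean_error([40, 50], [39, 51]) == 1.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        p, o = rng.random(500) * 90, rng.random(500) * 90
        acc = 0.0
        for a, b in zip(p, o):
            acc += abs(a - b)
        assert mean_error(p, o) == pytest.approx(acc / 500, abs=1e-9)

    def test_zero_iff_equal(self):
        assert mean_error([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mean_error([1.0, 2.0], [1.0, 2.5]) > 0.0


class TestMatching:
    def _gt(self):
        return [_box(10 + 40 * i, 10, 40 + 40 * i, 40) for i in range(3)]

    def test_perfect_predictions_all_matched(self):
        gt = self._gt()
        pred = [_box(b.xmin, b.ymin, b.xmax, b.ymax, conf=1.0) for b in gt]
        m = match_detections(gt, pred)
        assert m.tp == 3 and m.fp == 0 and m.fn == 0
        assert precision_recall(m) == (1.0, 1.0)

    def test_low_confidence_all_dropped(self):
        gt = self._gt()
        pred = [_box(b.xmin, b.ymin, b.xmax, b.ymax, conf=0.5) for b in gt]
        m = match_detections(gt, pred)
        assert m.tp == 0 and m.fn == 3
        p, r = precision_recall(m)
        assert (p, r) == (1.0, 0.0)  # no predictions -> P=1 by convention

    def test_nms_suppresses_duplicate_on_one_gt(self):
        gt = [_box(10, 10, 40, 40)]
        dup1 = _box(10, 10, 40, 40, conf=0.9)
        dup2 = _box(12, 12, 42, 42, conf=0.8)  # IOU with dup1 > 0.3
        m = match_detections(gt, [dup1, dup2])
        assert m.tp == 1 and m.fp == 0
        assert m.pairs[0][1].confidence == 0.9

    def test_counts_give_expected_pr(self):
        gt = self._gt() + [_box(10, 100, 40, 130)]
        pred = [_box(b.xmin, b.ymin, b.xmax, b.ymax, conf=0.9) for b in self._gt()]
        pred.append(_box(200, 200, 230, 230, conf=0.9))  # false positive
        m = match_detections(gt, pred)
        assert (m.tp, m.fp, m.fn) == (3, 1, 1)
        assert precision_recall(m) == (0.75, 0.75)

    def test_missing_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            match_detections(self._gt(), [_box(0, 0, 1, 1)])

    def test_nms_keeps_separated_boxes(self):
        boxes = [_box(0, 0, 10, 10, conf=0.9), _box(50, 50, 60, 60, conf=0.8)]
        assert len(nms(boxes, 0.3)) == 2


def _staircase_ap_oracle(gt_sets, pred_sets, thr):
    """Exhaustive PR-staircase enumeration: walk detections in
    confidence order, record (recall, precision) after each, then
    integrate max-precision-at-recall>=r over every recall step."""
    from spinemorph.evaluation import iou as _iou

    n_gt = sum(len(g) for g in gt_sets)
    dets = []
    for i, preds in enumerate(pred_sets):
        for j, p in enumerate(preds):
            dets.append((-p.confidence, i, j, p))
    dets.sort(key=lambda t: t[:3])
    free = [list(g) for g in gt_sets]
    points = []
    tp = fp = 0
    for _, i, _, p in dets:
        ious = [(_iou(g, p), g) for g in free[i]]
        best = max(ious, key=lambda t: t[0]) if ious else (0.0, None)
        if best[0] >= thr:
            tp += 1
            free[i].remove(best[1])
        else:
            fp += 1
        points.append((tp / n_gt, tp / (tp + fp)))
    recalls = sorted({r for r, _ in points})
    ap = 0.0
    prev_r = 0.0
    for r in recalls:
        p_max = max((p for rr, p in points if rr >= r), default=0.0)
        ap += (r - prev_r) * p_max
        prev_r = r
    return ap


class TestAveragePrecision:
    def _toy(self):
        """3-image toy set: one duplicate detection and one missed box."""
        g = lambda x: _box(x, 10, x + 20, 30)
        gt_sets = [[g(10), g(50)], [g(10)], [g(10)]]
        pred_sets = [
            [_box(10, 10, 30, 30, conf=0.95), _box(11, 11, 31, 31, conf=0.6),
             _box(50, 10, 70, 30, conf=0.8)],
            [_box(10, 10, 30, 30, conf=0.9)],
            [],  # miss
        ]
        return gt_sets, pred_sets

    def test_perfect_detections_map_one(self):
        gt_sets = [[_box(10, 10, 40, 40), _box(60, 10, 90, 40)]]
        pred_sets = [[_box(10, 10, 40, 40, conf=0.9), _box(60, 10, 90, 40, conf=0.95)]]
        maps = map_over_thresholds(gt_sets, pred_sets)
        assert maps["map50"] == 1.0
        assert maps["map5095"] == 1.0

    def test_zero_detections_ap_zero(self):
        assert average_precision([[_box(0, 0, 5, 5)]], [[]]) == 0.0

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="no ground truth"):
            average_precision([[]], [[_box(0, 0, 5, 5, conf=0.9)]])

    def test_toy_set_matches_staircase_oracle(self):
        gt_sets, pred_sets = self._toy()
        for thr in (0.5, 0.75):
            assert average_precision(gt_sets, pred_sets, thr) == pytest.approx(
                _staircase_ap_oracle(gt_sets, pred_sets, thr), abs=1e-9
            )

    def test_ap_non_increasing_with_stricter_iou(self):
        gt_sets, pred_sets = self._toy()
        # slightly perturb predictions so IOUs are below 1
        pred_sets = [
            [_box(b.xmin + 2, b.ymin + 1, b.xmax + 2, b.ymax + 1, conf=b.confidence)
             for b in preds]
            for preds in pred_sets
        ]
        aps = [average_precision(gt_sets, pred_sets, t)
               for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    def test_ap_invariant_to_image_order(self):
        gt_sets, pred_sets = self._toy()
        perm = [2, 0, 1]
        a = average_precision(gt_sets, pred_sets)
        b = average_precision([gt_sets[i] for i in perm], [pred_sets[i] for i in perm])
        assert a == pytest.approx(b, abs=1e-12)


class TestConfusion:
    def test_perfect_diagonal_split(self):
        truth = ["hypo"] * 6 + ["normal"] * 19 + ["hyper"] * 26
        counts, acc = confusion_and_accuracy(truth, truth)
        assert counts.tolist() == [[6, 0, 0], [0, 19, 0], [0, 0, 26]]
        assert acc == 1.0

    def test_known_misclassification_pattern(self):
        truth = ["hypo"] * 6 + ["normal"] * 19 + ["hyper"] * 26
        pred = (
            ["hypo"] * 6
            + ["hypo"] * 6 + ["normal"] * 11 + ["hyper"] * 2
            + ["normal"] * 5 + ["hyper"] * 21
        )
        counts, acc = confusion_and_accuracy(truth, pred)
        assert counts.tolist() == [[6, 0, 0], [6, 11, 2], [0, 5, 21]]
        assert acc == pytest.approx(38 / 51)
        assert counts.sum() == 51

    def test_accuracy_equals_agreement_rate_oracle(self):
        rng = np.random.default_rng(7)
        grades = np.array(["hypo", "normal", "hyper"])
        t = list(grades[rng.integers(0, 3, 200)])
        p = list(grades[rng.integers(0, 3, 200)])
        _, acc = confusion_and_accuracy(t, p)
        assert acc == pytest.approx(np.mean([a == b for a, b in zip(t, p)]))

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError, match="unknown grade"):
            confusion_and_accuracy(["hypo"], ["severe"])
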