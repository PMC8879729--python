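"""Gaussian smoothing, Harris response and corner detection/labeling."""

import math

import numpy as np
import pytest

from spinemorph.corners import (
    CornerCandidate,
    CornerParams,
    assign_anatomical_corners,
    detect_corners,
    gaussian_smooth,
    harris_response,
    mask_orientation,
    vertebra_corners,
)
from spinemorph.errors import CornerAssignmentError
from spinemorph.io import LabelImage, Point, VERTEBRA_NAMES, fill_polygon


class TestGaussianSmooth:
    def test_constant_preserved(self):
        g = np.full((20, 20), 3.7)
        np.testing.assert_allclose(gaussian_smooth(g, 1.0), g, atol=1e-9)

    def test_mass_conserved_with_reflective_boundary(self):
        rng = np.random.default_rng(0)
        g = rng.random((30, 40))
        assert gaussian_smooth(g, 2.0).sum() == pytest.approx(g.sum(), abs=1e-6)

    def test_impulse_center_matches_discrete_kernel(self):
        """Direct summation oracle: value at the impulse equals the
        normalized sampled-Gaussian kernel weight at the origin."""
        sigma, radius = 1.0, int(4 * 1.0)
        g = np.zeros((41, 41))
        g[20, 20] = 1.0
        out = gaussian_smooth(g, sigma)
        k = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma**2))
        k /= k.sum()
        assert out[20, 20] == pytest.approx(k[radius] ** 2, abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((0, 0)), 1.0)


class TestHarrisResponse:
    def test_constant_image_zero_response(self):
        r = harris_response(np.full((16, 16), 5.0))
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_edges_score_nonpositive_corners_positive(self):
        params = CornerParams()
        step = np.zeros((64, 64))
        step[:, 32:] = 1.0
        r_step = harris_response(gaussian_smooth(step, 1.0), params)
        square = np.zeros((64, 64))
        square[22:42, 22:42] = 1.0
        r_sq = harris_response(gaussian_smooth(square, 1.0), params)
        # interior of the straight edge, away from image borders
        assert r_step[20:44, 28:36].max() <= 1e-12
        assert r_sq.max() > 1e-5

    def test_equivariant_under_90_degree_rotation(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        r = harris_response(img)
        r_rot = harris_response(np.rot90(img))
        np.testing.assert_allclose(np.rot90(r), r_rot, atol=1e-6)

    def test_matches_skimage_on_corner_locations(self):
        """Independent cross-check: the strongest peaks of our response
        coincide with skimage's Harris peaks on the same image."""
        from skimage.feature import corner_harris, corner_peaks

        img = np.zeros((64, 64))
        img[20:44, 16:48] = 1.0
        smoothed = gaussian_smooth(img, 1.0)
        ours = detect_corners(harris_response(smoothed))
        ref = corner_peaks(
            corner_harris(smoothed, k=0.05, sigma=1.2), min_distance=5, num_peaks=4
        )
        ours_rc = {(int(c.point.y - 0.5), int(c.point.x - 0.5)) for c in ours[:4]}
        for r, c in ref:
            assert min(abs(r - rr) + abs(c - cc) for rr, cc in ours_rc) <= 2


class TestDetectCorners:
    def test_zero_response_gives_empty(self):
        assert detect_corners(np.zeros((16, 16))) == []

    def test_square_yields_its_four_corners(self):
        img = np.zeros((64, 64))
        img[22:42, 22:42] = 1.0  # corner pixels centered at 22.5 / 41.5
        found = detect_corners(harris_response(gaussian_smooth(img, 1.0)))
        assert len(found) == 4
        truth = [(22.5, 22.5), (41.5, 22.5), (22.5, 41.5), (41.5, 41.5)]
        for tx, ty in truth:
            assert min(
                math.hypot(c.point.x - tx, c.point.y - ty) for c in found
            ) <= 2.0

    def test_rotated_square_corners_recovered(self):
        t = math.radians(30)
        cx = cy = 32.0
        half = 10.0
        pts = []
        for sx, sy in [(-1, -1), (1, -1), (1, 1), (-1, 1)]:
            x = cx + half * (sx * math.cos(t) - sy * math.sin(t))
            y = cy + half * (sx * math.sin(t) + sy * math.cos(t))
            pts.append((x, y))
        img = fill_polygon([p[0] for p in pts], [p[1] for p in pts], (64, 64)).astype(float)
        found = detect_corners(harris_response(gaussian_smooth(img, 1.0)))
        assert len(found) >= 4
        for tx, ty in pts:
            assert min(
                math.hypot(c.point.x - tx, c.point.y - ty) for c in found[:4]
            ) <= 2.0

    def test_sorted_by_response_descending(self):
        resp = np.zeros((40, 40))
        resp[10, 10], resp[10, 30], resp[30, 10], resp[30, 30] = 4.0, 3.0, 2.0, 1.0
        found = detect_corners(resp)
        assert [c.response for c in found] == [4.0, 3.0, 2.0, 1.0]


class TestAssignAnatomicalCorners:
    def _cands(self, pts, resp=None):
        resp = resp or [1.0] * len(pts)
        return [CornerCandidate(Point(*p), r) for p, r in zip(pts, resp)]

    def test_rectangle_corners_assigned(self):
        cs = assign_anatomical_corners(
            self._cands([(0, 0), (10, 0), (0, 20), (10, 20)]), Point(5, 10)
        )
        assert cs.superior_left == Point(0, 0)
        assert cs.superior_right == Point(10, 0)
        assert cs.inferior_left == Point(0, 20)
        assert cs.inferior_right == Point(10, 20)

    def test_spurious_low_response_points_ignored(self):
        cands = self._cands(
            [(0, 0), (10, 0), (0, 20), (10, 20), (5, 0.5), (5, 19.5)],
            [1, 1, 1, 1, 0.2, 0.2],
        )
        cs = assign_anatomical_corners(cands, Point(5, 10))
        assert cs.superior_left == Point(0, 0)
        assert cs.inferior_right == Point(10, 20)

    def test_three_candidates_raise(self):
        with pytest.raises(CornerAssignmentError, match="at least 4"):
            assign_anatomical_corners(self._cands([(0, 0), (1, 0), (0, 1)]), Point(0.5, 0.5))

    def test_empty_quadrant_named_in_error(self):
        cands = self._cands([(0, 0), (10, 0), (0, 20), (1, 19)])  # two in inferior-left
        with pytest.raises(CornerAssignmentError, match="inferior-right"):
            assign_anatomical_corners(cands, Point(5, 10))

    def test_tilted_frame_assignment(self):
        """At 60 degrees tilt, image-frame quadrants would mislabel; the
        axis-aware rule must still find all four."""
        t = math.radians(60)
        u = (math.cos(t), math.sin(t))
        v = (-math.sin(t), math.cos(t))
        c = (50.0, 50.0)
        pts = {
            "sl": (c[0] - 10 * v[0] - 25 * u[0], c[1] - 10 * v[1] - 25 * u[1]),
            "sr": (c[0] - 10 * v[0] + 25 * u[0], c[1] - 10 * v[1] + 25 * u[1]),
            "il": (c[0] + 10 * v[0] - 25 * u[0], c[1] + 10 * v[1] - 25 * u[1]),
            "ir": (c[0] + 10 * v[0] + 25 * u[0], c[1] + 10 * v[1] + 25 * u[1]),
        }
        cs = assign_anatomical_corners(
            self._cands(list(pts.values())), Point(*c), axis_deg=60.0
        )
        assert cs.superior_left == Point(*pts["sl"])
        assert cs.inferior_right == Point(*pts["ir"])


class TestMaskOrientation:
    @pytest.mark.parametrize("tilt", [0.0, 20.0, 48.0, 75.0, -30.0])
    def test_recovers_rectangle_tilt(self, tilt):
        t = math.radians(tilt)
        pts = []
        for sx, sy in [(-1, -1), (1, -1), (1, 1), (-1, 1)]:
            pts.append(
                (
                    64 + 27 * sx * math.cos(t) - 12 * sy * math.sin(t),
                    64 + 27 * sx * math.sin(t) + 12 * sy * math.cos(t),
                )
            )
        mask = fill_polygon([p[0] for p in pts], [p[1] for p in pts], (128, 128))
        assert mask_orientation(mask) == pytest.approx(tilt, abs=2.0)


class TestVertebraCorners:
    def test_phantom_l1_corners_within_2px(self, default_case):
        cs = vertebra_corners(default_case.label_image, "L1")
        truth = default_case.true_corners["L1"]
        for got, want in zip(cs.points(), truth.points()):
            assert math.hypot(got.x - want.x, got.y - want.y) <= 2.0

    def test_margin_change_is_stable(self, default_case):
        a = vertebra_corners(default_case.label_image, "S", margin_sigmas=4.0)
        b = vertebra_corners(default_case.label_image, "S", margin_sigmas=6.0)
        for p, q in zip(a.points(), b.points()):
            assert math.hypot(p.x - q.x, p.y - q.y) <= 0.5

    def test_mask_touching_border_still_works(self):
        px = np.zeros((40, 40), dtype=int)
        px[0:14, 0:30] = 1
        cs = vertebra_corners(LabelImage(px, {1: "L1"}), "L1")
        assert len(cs.points()) == 4

    def test_absent_vertebra_raises(self, default_case):
        with pytest.raises(KeyError):
            vertebra_corners(default_case.label_image, "T12")

    def test_translation_equivariance(self, default_case):
        px = default_case.label_image.pixels
        shifted = LabelImage(np.roll(px, (6, -4), axis=(0, 1)))
        a = vertebra_corners(default_case.label_image, "L3")
        b = vertebra_corners(shifted, "L3")
        for p, q in zip(a.points(), b.points()):
            assert q.x - p.x == pytest.approx(-4.0, abs=1e-9)
            assert q.y - p.y == pytest.approx(6.0, abs=1e-9)

    def test_cohort_recovery_mean_below_1_5px(self, small_cohort):
        errs = []
        for case in small_cohort:
            for name in VERTEBRA_NAMES:
                cs = vertebra_corners(case.label_image, name)
                truth = case.true_corners[name]
                for got, want in zip(cs.points(), truth.points()):
                    errs.append(math.hypot(got.x - want.x, got.y - want.y))
        assert float(np.mean(errs)) < 1.5
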