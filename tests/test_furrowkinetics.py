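"""Furrow detection, ingression timing, constriction kinetics."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Point
from shapely.ops import unary_union

from furrowquant import _geom
from furrowquant.cortexprofile import CellContour, annotate_poles, subtract_camera_background
from furrowquant.furrowkinetics import (
    cohort_average_curve,
    constriction_curve,
    detect_furrow,
    detect_ingression_onset,
    furrow_basal_distance,
    furrow_segment,
    furrow_width_um,
    percent_constriction,
)
from furrowquant.synthmovie import SimulationParams, simulate_division


def _closed_shape_contour(points: np.ndarray, n: int = 200) -> CellContour:
    return annotate_poles(_geom.resample_closed(points, n))


def _circle(r=30.0, c=(48.0, 48.0), n=200):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])


def _two_lobe_union(r1=28.0, r2=16.0, sep=36.0, n=200):
    """Union of two overlapping circles; returns (contour, analytic neck points)."""
    a = unary_union([Point(40.0, 48.0).buffer(r1, 256), Point(40.0 + sep, 48.0).buffer(r2, 256)])
    pts = np.asarray(a.exterior.coords)[:-1]
    # intersection points of the two circles (true neck)
    d = sep
    x = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    y = np.sqrt(r1 * r1 - x * x)
    neck = np.array([[40.0 + x, 48.0 - y], [40.0 + x, 48.0 + y]])
    return _closed_shape_contour(pts), neck


def _brute_force_most_concave(points: np.ndarray, k: int = 5) -> np.ndarray:
    """Independent curvature oracle: circumradius of (i-k, i, i+k) triples,
    signed by the local turn; returns signed curvature per vertex."""
    n = len(points)
    orient = 1.0 if _geom.signed_area(points) > 0 else -1.0
    kappa = np.zeros(n)
    for i in range(n):
        a, b, c = points[(i - k) % n], points[i], points[(i + k) % n]
        ab, bc, ca = b - a, c - b, a - c
        cross = ab[1] * bc[0] - ab[0] * bc[1]  # x=col, y=row
        denom = np.linalg.norm(ab) * np.linalg.norm(bc) * np.linalg.norm(ca)
        if denom == 0:
            continue
        # Menger curvature signed by the turn: concave (inward) negative
        kappa[i] = orient * 2.0 * cross / denom
    return kappa


class TestDetectFurrow:
    def test_circle_has_no_furrow(self):
        assert detect_furrow(_closed_shape_contour(_circle())) is None

    def test_ellipse_has_no_furrow(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ell = np.column_stack([48 + 34 * np.cos(th), 48 + 17 * np.sin(th)])
        assert detect_furrow(_closed_shape_contour(ell)) is None

    def test_degenerate_contour_rejected(self):
        tiny = _circle(n=8)
        with pytest.raises(ValueError):
            detect_furrow(
                CellContour(
                    points=tiny, apical_pole_index=0, basal_pole_index=4, long_axis=np.array([1.0, 0])
                )
            )

    def test_two_lobe_neck_matches_brute_force_oracle(self):
        contour, neck = _two_lobe_union()
        fp = detect_furrow(contour)
        assert fp is not None
        spacing = contour.perimeter_px() / contour.n_points
        # against the analytic neck
        for det in (fp.left, fp.right):
            d = np.linalg.norm(neck - det, axis=1).min()
            assert d <= 1.5 * spacing
        # against the independent curvature oracle, per side
        kappa = _brute_force_most_concave(contour.points)
        lat = contour.lateral_coordinate()
        for name, idx in (("left", fp.left_index), ("right", fp.right_index)):
            side = lat < 0 if name == "left" else lat > 0
            cand = np.flatnonzero(side)
            oracle = cand[np.argmin(kappa[cand])]
            sep = abs(idx - oracle)
            assert min(sep, contour.n_points - sep) <= 1

    def test_generator_truth_contours_neck_detection(self, clean_division):
        # on ground-truth polylines the detected furrow matches the known
        # neck points within one contour sample
        _, truth = clean_division
        for t in (8, 11, 13):
            contour = annotate_poles(truth.contours[t])
            fp = detect_furrow(contour)
            assert fp is not None
            spacing = contour.perimeter_px() / contour.n_points
            for det, true_pt in ((fp.left, truth.furrow_left[t]), (fp.right, truth.furrow_right[t])):
                d = min(
                    np.linalg.norm(det - truth.furrow_left[t]),
                    np.linalg.norm(det - truth.furrow_right[t]),
                )
                assert d <= 1.5 * spacing, f"frame {t}"


class TestIngressionOnset:
    def test_scheduled_onset_recovered(self, clean_contours, clean_params):
        onset = detect_ingression_onset(clean_contours)
        assert onset is not None
        assert abs(onset - clean_params.ingression_onset_frame) <= 1

    def test_all_convex_movie_reports_no_ingression(self):
        contours = [_closed_shape_contour(_circle()) for _ in range(3)]
        assert detect_ingression_onset(contours) is None

    def test_onset_at_first_frame(self):
        contour, _ = _two_lobe_union()
        assert detect_ingression_onset([contour, contour]) == 0

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            detect_ingression_onset([_closed_shape_contour(_circle())])


class TestPercentConstriction:
    @pytest.mark.parametrize(
        "d,d0,dmb,expected",
        [(10.0, 10.0, 0.5, 0.0), (0.5, 10.0, 0.5, 100.0), (5.25, 10.0, 0.5, 50.0)],
    )
    def test_anchors_and_linearity(self, d, d0, dmb, expected):
        assert percent_constriction(d, d0, dmb) == expected

    def test_unit_change_invariance(self):
        # px -> µm applied consistently leaves the percentage unchanged
        px = 0.16
        assert percent_constriction(30.0, 60.0, 4.0) == pytest.approx(
            percent_constriction(30.0 * px, 60.0 * px, 4.0 * px)
        )

    def test_affine_in_diameter(self):
        d = np.linspace(0.5, 10, 20)
        pct = np.array([percent_constriction(x, 10.0, 0.5) for x in d])
        resid = np.polyfit(d, pct, 1, full=True)[1]
        assert resid[0] < 1e-18

    def test_inverted_anchors_rejected(self):
        with pytest.raises(ValueError):
            percent_constriction(5.0, 0.5, 10.0)

    def test_diameter_outside_range_rejected(self):
        with pytest.raises(ValueError):
            percent_constriction(30.0, 10.0, 0.5)


class TestConstrictionCurve:
    def test_linear_schedule_recovered(self, clean_movie_bg, clean_division):
        _, truth = clean_division
        curve = constriction_curve(clean_movie_bg)
        true_pct = 100.0 * truth.constriction
        rms = np.sqrt(np.nanmean((curve["percent"].to_numpy() - true_pct) ** 2))
        assert rms < 3.0
        assert curve["percent"].iloc[0] == 0.0
        assert curve["percent"].iloc[-1] > 95.0
        assert bool(curve["complete"].iloc[0]) or curve["percent"].max() > 95.0

    def test_curve_is_monotone(self, clean_movie_bg):
        pct = constriction_curve(clean_movie_bg, smooth_k=0)["percent"].to_numpy()
        ok = ~np.isnan(pct)
        assert np.all(np.diff(pct[ok]) >= -1e-9)

    def test_ring_diameter_tracks_truth_within_one_px(self, clean_movie_bg, clean_division, clean_params):
        _, truth = clean_division
        curve = constriction_curve(clean_movie_bg)
        err = np.abs(curve["ring_diameter_um"].to_numpy() - truth.ring_diameter_um)
        after = np.arange(len(err)) >= truth.ingression_onset_frame
        assert np.nanmax(err[after]) <= clean_params.pixel_size

    def test_single_frame_movie_rejected(self):
        from furrowquant.cortexprofile import TimeLapseMovie

        with pytest.raises(ValueError):
            TimeLapseMovie(frames=np.zeros((1, 8, 8)), pixel_size=0.16)

    def test_two_identical_cells_average_to_either(self, clean_movie_bg):
        curve = constriction_curve(clean_movie_bg)
        avg = cohort_average_curve([curve.copy(), curve.copy()], smooth_k=0)
        merged = curve.dropna(subset=["percent"])
        np.testing.assert_allclose(
            avg.set_index("t_s").loc[merged["t_s"], "percent"].to_numpy(),
            merged["percent"].to_numpy(),
        )


class TestFurrowBasalDistance:
    def test_phantom_offset_recovered(self):
        # no bridge, so the basal distance is the bare generator offset
        p = SimulationParams(
            seed=9, initial_furrow_basal_distance=2.0, neck_elongation=0.0, shot_noise=False,
            read_noise_sd=0.0,
        )
        movie, truth = simulate_division(p)
        movie = subtract_camera_background(movie, p.camera_offset)
        contours = [None] * movie.n_frames
        t = truth.ingression_onset_frame + 1
        from furrowquant.cortexprofile import trace_contour

        contour = trace_contour(movie.frames[t])
        fp = detect_furrow(contour)
        assert fp is not None
        from furrowquant.furrowkinetics import measured_basal_distance

        dist = measured_basal_distance(movie.frames[t], contour, fp, p.pixel_size)
        assert dist == pytest.approx(truth.basal_distance_um[t], abs=0.2)

    def test_furrow_at_basal_pole_gives_zero(self):
        contour = annotate_poles(_circle())
        assert furrow_basal_distance(contour, contour.basal_pole, 0.16) == 0.0

    def test_distance_follows_the_pole_labels(self):
        # measured from whichever pole is labelled basal: flipping the image
        # vertically relabels the poles and changes the reading accordingly
        contour, _ = _two_lobe_union()
        fp = detect_furrow(contour)
        d1 = furrow_basal_distance(contour, fp.midpoint, 1.0)
        flipped = contour.points.copy()
        flipped[:, 0] = 96.0 - flipped[:, 0]
        cflip = annotate_poles(flipped)
        fp2 = detect_furrow(cflip)
        d2 = furrow_basal_distance(cflip, fp2.midpoint, 1.0)
        total = float(
            (contour.basal_pole - contour.apical_pole) @ contour.long_axis
        )
        assert d1 + d2 == pytest.approx(total, abs=2.0)


@pytest.fixture(scope="module")
def deep_neck():
    p = SimulationParams(seed=4, shot_noise=False, read_noise_sd=0.0, neck_elongation=2.0)
    movie, truth = simulate_division(p)
    contour = annotate_poles(truth.contours[13])
    fp = detect_furrow(contour)
    assert fp is not None
    return contour, fp


class TestFurrowSegment:

    def test_segment_covers_the_furrow(self, deep_neck):
        # a tube neck puts the maximal-curvature sample on the shoulder
        # corner, so containment is asserted up to one contour sample
        contour, fp = deep_neck
        lo, hi = furrow_segment(contour, fp.left_index)
        frac = fp.left_index / contour.n_points
        tol = 1.5 / contour.n_points
        assert (frac - lo + tol) % 1.0 <= (hi - lo) + 2 * tol
        assert hi > lo

    def test_tiny_threshold_gives_degenerate_segment(self, deep_neck):
        contour, fp = deep_neck
        lo, hi = furrow_segment(contour, fp.left_index, angle_threshold_deg=0.5)
        assert hi - lo <= 2.5 / contour.n_points

    def test_invalid_threshold_rejected(self, deep_neck):
        contour, fp = deep_neck
        for bad in (0.0, 95.0):
            with pytest.raises(ValueError):
                furrow_segment(contour, fp.left_index, angle_threshold_deg=bad)

    def test_elongated_neck_widens_the_furrow(self):
        # same ring diameter, longer bridge -> wider furrow segment, the
        # "widened furrow" phenotype read-out
        widths = []
        for tube in (0.8, 3.0):
            p = SimulationParams(seed=4, shot_noise=False, read_noise_sd=0.0, neck_elongation=tube)
            _, truth = simulate_division(p)
            contour = annotate_poles(truth.contours[13])
            fp = detect_furrow(contour)
            widths.append(furrow_width_um(contour, fp.left_index, p.pixel_size))
        assert widths[1] > widths[0]
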