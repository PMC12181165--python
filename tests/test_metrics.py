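"""The six metric formulas, their oracles and the unit-scaling law."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nematrack.errors import ParameterError, UndefinedCurvatureError
from nematrack.metrics import (
    AnalysisConfig,
    CurvatureSeries,
    StrokeEvent,
    crawl_speed,
    curvature_series,
    detect_strokes,
    dynamic_amplitude,
    menger_curvature,
    swim_speed,
    wave_initiation_rate,
    worm_area,
    worm_length,
)
from nematrack.skeleton import SkeletonObservation
from nematrack.tracking import WormTrack


def make_cfg(**kw):
    base = dict(min_size_px=0, ucf=1.0, min_pct=0, frame_rate=7.5)
    base.update(kw)
    return AnalysisConfig(**base)


class FakeContour:
    def __init__(self, area_px):
        self.area_px = area_px


def fake_obs(area_px=0, midline_len_px=None, midpoint=None, points=None):
    return SkeletonObservation(
        contour=FakeContour(area_px),
        midline=None,
        midline_len_px=midline_len_px,
        tracking_points=points,
        midpoint=midpoint,
        self_collision=False,
    )


def track_from_midpoints(midpoints: dict):
    t = WormTrack(worm_id=1)
    for f, m in midpoints.items():
        t.observations[f] = fake_obs(midpoint=m)
        t.first_frame = min(t.first_frame, f) if t.first_frame >= 0 else f
        t.last_frame = f
    return t


class TestAreaAndLength:
    def test_area_formula(self):
        assert worm_area(fake_obs(area_px=1000), make_cfg(ucf=2.5)) == 6250.0

    def test_ucf_one_is_numeric_identity(self):
        assert worm_area(fake_obs(area_px=321), make_cfg(ucf=1.0)) == 321.0
        assert worm_length(fake_obs(midline_len_px=57.0), make_cfg(ucf=1.0)) == 57.0

    def test_rectangle_area(self):
        assert worm_area(fake_obs(area_px=200), make_cfg(ucf=3.0)) == 1800.0

    def test_length_formula(self):
        assert worm_length(fake_obs(midline_len_px=150), make_cfg(ucf=3.0)) == 450.0


class TestCrawlSpeed:
    def test_displacement_times_ucf_times_fps(self):
        track = track_from_midpoints({0: (10, 10), 1: (13, 14)})
        df = crawl_speed(track, make_cfg(ucf=1.0, frame_rate=7.5))
        assert df["value"].tolist() == [pytest.approx(37.5)]

    def test_stationary_midpoint_zero(self):
        track = track_from_midpoints({0: (5, 5), 1: (5, 5), 2: (5, 5)})
        assert crawl_speed(track, make_cfg()).value.tolist() == [0.0, 0.0]

    def test_no_value_across_gaps(self):
        track = track_from_midpoints({0: (0, 0), 1: (1, 0), 5: (9, 0), 6: (10, 0)})
        df = crawl_speed(track, make_cfg(frame_rate=1.0))
        assert df["frame_index"].tolist() == [1, 6]


class TestMengerCurvature:
    def test_collinear_is_zero(self):
        assert menger_curvature((0, 0), (1, 0), (2, 0)) == 0.0

    def test_known_circle(self):
        c = menger_curvature((2, 0), (0, 2), (-2, 0))
        assert abs(c) == pytest.approx(0.5)

    def test_sign_flips_with_turn_direction(self):
        left = menger_curvature((0, 0), (1, 0), (2, 1))
        right = menger_curvature((0, 0), (1, 0), (2, -1))
        assert left == -right != 0

    def test_coincident_points_rejected(self):
        with pytest.raises(UndefinedCurvatureError):
            menger_curvature((1, 1), (1, 1), (2, 2))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_magnitude_matches_circumcircle_oracle(self, seed):
        """|c| equals 1/R from an independent perpendicular-bisector
        circumcenter solve."""
        rng = np.random.default_rng(seed)
        x, y, z = rng.uniform(0, 10, (3, 2))
        A = 2 * np.array([[y[0] - x[0], y[1] - x[1]], [z[0] - y[0], z[1] - y[1]]])
        b = np.array([y @ y - x @ x, z @ z - y @ y])
        if abs(np.linalg.det(A)) < 1e-12:
            return
        center = np.linalg.solve(A, b)
        assert abs(menger_curvature(x, y, z)) == pytest.approx(
            1.0 / np.linalg.norm(x - center), abs=1e-9
        )


class TestStrokesAndWaves:
    def series(self, values, point=1):
        s = CurvatureSeries(worm_id=1, frame_rate=1.0)
        for f, v in enumerate(values):
            arr = np.full(5, np.nan)
            arr[point - 1] = v
            s.values[f] = arr
        return s

    def test_alternating_signs_count_each_crossing(self):
        strokes = detect_strokes(self.series([+1, -1, +1, -1, +1]))
        assert len(strokes) == 4
        assert [e.direction for e in strokes] == ["+to-", "-to+", "+to-", "-to+"]

    def test_constant_sign_no_strokes(self):
        assert detect_strokes(self.series([0.3, 0.7, 0.2, 0.9])) == []

    def test_exact_zero_passed_through(self):
        strokes = detect_strokes(self.series([+1, 0, -1]))
        assert len(strokes) == 1

    def test_strokes_never_span_censored_gaps(self):
        s = self.series([+1, -1])
        arr = np.full(5, np.nan)
        arr[0] = +1
        s.values[10] = arr  # opposite-sign sample after a long gap
        arr2 = np.full(5, np.nan)
        arr2[0] = -1
        s.values[11] = arr2
        strokes = detect_strokes(s)
        assert [e.frame_index for e in strokes] == [1, 11]

    def test_wave_rate_arithmetic(self):
        strokes = [StrokeEvent(i, "+to-") for i in range(4)]
        assert wave_initiation_rate(strokes, 30.0) == 4.0

    def test_partial_stroke_rounds_down(self):
        strokes = [StrokeEvent(i, "+to-") for i in range(3)]
        assert wave_initiation_rate(strokes, 60.0) == 1.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ParameterError):
            wave_initiation_rate([], 0.0)


class TestSwimSpeed:
    def test_two_stroke_interval_arithmetic(self):
        # boundaries at strokes 0 and 2 -> frames 0 and 4, 2 s apart at 2 fps
        track = track_from_midpoints({f: (7.0 * f, 0.0) for f in range(5)})
        strokes = [StrokeEvent(f, "+to-") for f in (0, 2, 4)]
        df = swim_speed(track, strokes, make_cfg(ucf=1.0, frame_rate=2.0))
        # 28 px over 2 s
        assert df["value"].tolist() == [pytest.approx(14.0)]

    def test_fewer_than_two_boundaries_empty(self):
        track = track_from_midpoints({0: (0, 0), 1: (1, 1)})
        assert swim_speed(track, [StrokeEvent(0, "+to-")], make_cfg()).empty

    def test_intervals_with_censored_frames_dropped(self):
        mids = {f: (float(f), 0.0) for f in range(9) if f != 2}
        track = track_from_midpoints(mids)
        strokes = [StrokeEvent(f, "+to-") for f in (0, 1, 4, 6, 8)]
        df = swim_speed(track, strokes, make_cfg(frame_rate=1.0))
        # first interval [0, 4] contains censored frame 2 -> dropped
        assert df["frame_index"].tolist() == [8]


class TestDynamicAmplitude:
    def series_with(self, frame_vals):
        s = CurvatureSeries(worm_id=1, frame_rate=1.0)
        for f, vals in frame_vals.items():
            arr = np.full(5, np.nan)
            arr[: len(vals)] = vals
            s.values[f] = arr
        return s

    def strokes(self, frames):
        return [StrokeEvent(f, "+to-") for f in frames]

    def test_printed_formula(self):
        s = self.series_with({0: [0.4], 1: [-0.3], 2: [0.1]})
        df = dynamic_amplitude(s, self.strokes([0, 1, 2]))
        assert df["value"].tolist() == [pytest.approx(0.1)]

    def test_symmetric_undulation_zero(self):
        s = self.series_with({0: [0.4], 1: [-0.4], 2: [0.0]})
        df = dynamic_amplitude(s, self.strokes([0, 1, 2]))
        assert df["value"].tolist() == [pytest.approx(0.0)]

    def test_one_sided_bending(self):
        s = self.series_with({0: [0.5], 1: [0.2], 2: [0.3]})
        df = dynamic_amplitude(s, self.strokes([0, 1, 2]))
        assert df["value"].tolist() == [pytest.approx(0.3)]

    def test_extrema_pool_across_tracking_points(self):
        s = self.series_with({0: [0.1, 0.6], 1: [-0.2, 0.0], 2: [0.0, 0.0]})
        df = dynamic_amplitude(s, self.strokes([0, 1, 2]))
        assert df["value"].tolist() == [pytest.approx(0.6 - 0.2)]

    def test_range_mode_uses_max_minus_min(self):
        s = self.series_with({0: [0.4], 1: [-0.3], 2: [0.1]})
        df = dynamic_amplitude(s, self.strokes([0, 1, 2]), mode="range")
        assert df["value"].tolist() == [pytest.approx(0.7)]


class TestCurvatureSeries:
    def test_straight_worm_curvature_near_zero(self, translating_rendered):
        """A non-undulating worm reads |c| far below the undulation scale."""
        from nematrack.pipeline import analyze_sequence

        seq, truth = translating_rendered
        cfg = AnalysisConfig(min_size_px=100, ucf=5.0, min_pct=30, frame_rate=7.5)
        result = analyze_sequence(seq, cfg)
        series = curvature_series(result.tracks[0], cfg)
        vals = np.concatenate([series.values[f] for f in series.frames()])
        undulation_scale = 0.008  # generator peak-curvature scale, 1/um
        assert np.nanmax(np.abs(vals)) < 0.1 * undulation_scale

    def test_peak_curvature_recovers_serpenoid_amplitude(self, swim_analysis):
        """Peak |c| at each interior point within 15% of the analytic peak."""
        result, truth, cfg = swim_analysis
        k0 = truth.scene.worms[0].kappa0_per_um
        series = curvature_series(result.tracks[0], cfg)
        for p in range(1, 6):
            _, vals = series.point_series(p)
            assert max(abs(v) for v in vals) == pytest.approx(k0, rel=0.15)

    def test_single_frame_series_is_defined(self):
        pts = np.column_stack([np.linspace(0, 60, 7), np.zeros(7)])
        track = WormTrack(worm_id=1)
        track.observations[0] = fake_obs(points=pts, midpoint=(30.0, 0.0))
        track.first_frame = track.last_frame = 0
        series = curvature_series(track, make_cfg())
        assert series.frames() == [0]


class TestUnitScaling:
    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50).map(lambda s: round(s, 3)))
    def test_scaling_law_exact(self, s):
        """ucf -> s * ucf scales area by s^2, speeds and length by s,
        curvature by 1/s."""
        cfg1 = make_cfg(ucf=2.0, frame_rate=7.5)
        cfg2 = make_cfg(ucf=2.0 * s, frame_rate=7.5)
        obs = fake_obs(area_px=1234, midline_len_px=78.5)
        assert worm_area(obs, cfg2) == pytest.approx(worm_area(obs, cfg1) * s**2)
        assert worm_length(obs, cfg2) == pytest.approx(worm_length(obs, cfg1) * s)
        track = track_from_midpoints({0: (1.0, 2.0), 1: (4.0, 6.0)})
        assert crawl_speed(track, cfg2)["value"][0] == pytest.approx(
            crawl_speed(track, cfg1)["value"][0] * s
        )
        pts = np.array([[0, 0], [1, 0.3], [2, 0]], dtype=float)
        c1 = menger_curvature(*(pts * 2.0))
        c2 = menger_curvature(*(pts * 2.0 * s))
        assert c2 == pytest.approx(c1 / s)
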