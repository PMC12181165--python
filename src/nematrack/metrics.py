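"""The six locomotion metrics.

All geometry is converted from pixels to micrometers through the unit
conversion factor (UCF, um/px) before physical quantities are formed:

* worm area  = body pixel count * UCF^2                          [um^2]
* worm length = midline path length * UCF                        [um]
* crawl speed = midpoint displacement per frame * UCF * fps      [um/s]
* curvature  = signed Menger curvature (1/circumradius) at the
  five interior tracking points                                  [1/um]
* wave initiation rate = floor(strokes / 2) waves per observed
  minute, a stroke being a zero crossing of the signed curvature
  at the near-end tracking point                                 [waves/min]
* swim speed = midpoint displacement between every second stroke
  divided by the interval duration (cancels lateral jitter)      [um/s]
* dynamic amplitude = |max curvature| - |min curvature| over a
  two-stroke interval, across all tracking points                [1/um]

Menger curvature of three points x, y, z is 4 * area(xyz) / (|xy||yz||zx|),
the inverse radius of their circumscribed circle.  It is signed here by the
turn direction (z-component of the cross product) so that zero crossings of
the time series are well defined; skeleton orientation is kept temporally
consistent by matching ends to the previous frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedCurvatureError
from .skeleton import SkeletonObservation
from .tracking import WormTrack

__all__ = [
    "AnalysisConfig",
    "CurvatureSeries",
    "StrokeEvent",
    "MetricsTable",
    "worm_area",
    "worm_length",
    "crawl_speed",
    "menger_curvature",
    "curvature_series",
    "detect_strokes",
    "wave_initiation_rate",
    "swim_speed",
    "dynamic_amplitude",
    "summarize",
]

METRIC_UNITS = {
    "worm_area": "um^2",
    "worm_length": "um",
    "crawl_speed": "um/s",
    "swim_speed": "um/s",
    "dynamic_amplitude": "1/um",
    "wave_initiation_rate": "waves/min",
}


@dataclass
class AnalysisConfig:
    """User parameters of a run.

    min_size_px: minimum worm size, in pixels (inclusive gate).
    ucf: unit conversion factor, micrometers per pixel.
    min_pct: minimum percentage of frames a worm must appear in.
    frame_rate: capture rate, frames per second.
    stroke_point: tracking point whose curvature defines strokes; default 1,
        the end-most point at which curvature is defined.
    amplitude_mode: "printed" applies |max| - |min| literally; "range"
        applies max - min.
    """

    min_size_px: float
    ucf: float
    min_pct: float
    frame_rate: float
    stroke_point: int = 1
    amplitude_mode: str = "printed"

    def __post_init__(self) -> None:
        if not self.ucf > 0:
            raise ParameterError(f"ucf must be positive, got {self.ucf}")
        if not self.frame_rate > 0:
            raise ParameterError(f"frame_rate must be positive, got {self.frame_rate}")
        if not 0 <= self.min_pct <= 100:
            raise ParameterError(f"min_pct must be in [0, 100], got {self.min_pct}")
        if self.stroke_point not in (1, 2, 3, 4, 5):
            raise ParameterError("stroke_point must be an interior point index 1..5")
        if self.amplitude_mode not in ("printed", "range"):
            raise ParameterError("amplitude_mode must be 'printed' or 'range'")


def worm_area(obs: SkeletonObservation, cfg: AnalysisConfig) -> float:
    """Body pixel count scaled to um^2."""
    return obs.contour.area_px * cfg.ucf**2


def worm_length(obs: SkeletonObservation, cfg: AnalysisConfig) -> float:
    """Midline path length scaled to um."""
    if obs.midline_len_px is None:
        raise ParameterError("cannot measure length of a censored observation")
    return obs.midline_len_px * cfg.ucf


def crawl_speed(track: WormTrack, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-frame midpoint speed over consecutive observed frame pairs.

    No value is emitted across gaps (missing or censored frames); each row
    is indexed by the later frame of its pair.
    """
    frames = track.observed_frames()
    rows = []
    for f0, f1 in zip(frames, frames[1:]):
        if f1 - f0 != 1:
            continue
        p0 = np.asarray(track.observations[f0].midpoint)
        p1 = np.asarray(track.observations[f1].midpoint)
        disp_px = float(np.linalg.norm(p1 - p0))
        rows.append(
            {
                "frame_index": f1,
                "time_s": f1 / cfg.frame_rate,
                "value": disp_px * cfg.ucf * cfg.frame_rate,
            }
        )
    return pd.DataFrame(rows, columns=["frame_index", "time_s", "value"])


def menger_curvature(x, y, z) -> float:
    """Signed Menger curvature of three planar points, in 1/(input units).

    Magnitude is 4*area/(|xy|*|yz|*|zx|) = 1/circumradius; the sign is the
    z-component sign of (y - x) x (z - y).  Collinear points return 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    a = np.linalg.norm(y - x)
    b = np.linalg.norm(z - y)
    c = np.linalg.norm(z - x)
    if a == 0 or b == 0 or c == 0:
        raise UndefinedCurvatureError("coincident points have no curvature")
    cross = (y[0] - x[0]) * (z[1] - y[1]) - (y[1] - x[1]) * (z[0] - y[0])
    if cross == 0:
        return 0.0
    return float(4.0 * (abs(cross) / 2.0) / (a * b * c) * math.copysign(1.0, cross))


@dataclass
class CurvatureSeries:
    """Signed curvature at interior tracking points 1..5 over a track.

    ``values[frame]`` is a length-5 array (NaN where undefined); curvature is
    in 1/um, positions having been scaled by the UCF before computation.
    """

    worm_id: int
    frame_rate: float
    values: dict[int, np.ndarray] = field(default_factory=dict)

    def frames(self) -> list[int]:
        return sorted(self.values)

    def point_series(self, point_index: int) -> tuple[list[int], list[float]]:
        """(frames, curvature) at one tracking point, NaN samples dropped."""
        if point_index not in (1, 2, 3, 4, 5):
            raise ParameterError("curvature is defined at points 1..5 only")
        frames, vals = [], []
        for f in self.frames():
            v = self.values[f][point_index - 1]
            if not np.isnan(v):
                frames.append(f)
                vals.append(float(v))
        return frames, vals


def _orient(points: np.ndarray, prev: np.ndarray | None) -> np.ndarray:
    """Flip the tracking-point order if that better matches the last frame."""
    if prev is None:
        return points
    keep = np.linalg.norm(points[0] - prev[0]) + np.linalg.norm(points[-1] - prev[-1])
    flip = np.linalg.norm(points[0] - prev[-1]) + np.linalg.norm(points[-1] - prev[0])
    return points[::-1] if flip < keep else points


def curvature_series(track: WormTrack, cfg: AnalysisConfig) -> CurvatureSeries:
    """Per-frame signed curvature at the five interior tracking points."""
    series = CurvatureSeries(worm_id=track.worm_id, frame_rate=cfg.frame_rate)
    prev: np.ndarray | None = None
    for f in track.observed_frames():
        pts = track.observations[f].tracking_points
        pts = _orient(np.asarray(pts, dtype=float), prev)
        prev = pts
        pts_um = pts * cfg.ucf
        vals = np.full(5, np.nan)
        for i in range(1, 6):
            try:
                vals[i - 1] = menger_curvature(pts_um[i - 1], pts_um[i], pts_um[i + 1])
            except UndefinedCurvatureError:
                pass
        series.values[f] = vals
    return series


@dataclass(frozen=True)
class StrokeEvent:
    """A zero crossing of the signed curvature at the stroke point."""

    frame_index: int
    direction: str  # "+to-" or "-to+"


def detect_strokes(series: CurvatureSeries, point_index: int = 1) -> list[StrokeEvent]:
    """Zero crossings of the curvature series at one tracking point.

    The new nonzero sign is compared with the last nonzero sign, so exact
    zeros are passed through rather than counted twice.  A gap in observed
    frames (censoring or a missed detection) resets the comparison: strokes
    never span a censored interval.
    """
    frames, vals = series.point_series(point_index)
    events: list[StrokeEvent] = []
    last_sign = 0
    last_frame: int | None = None
    for f, v in zip(frames, vals):
        if last_frame is not None and f - last_frame > 1:
            last_sign = 0  # censored / missing gap: restart
        last_frame = f
        s = (v > 0) - (v < 0)
        if s == 0:
            continue
        if last_sign != 0 and s != last_sign:
            events.append(StrokeEvent(f, "+to-" if s < 0 else "-to+"))
        last_sign = s
    return events


def wave_initiation_rate(strokes: list[StrokeEvent], observed_duration: float) -> float:
    """Waves per minute: floor(strokes / 2) over the un-censored tracked time.

    Partial strokes round down to the last complete wave.
    """
    if not observed_duration > 0:
        raise ParameterError("observed duration must be positive")
    waves = len(strokes) // 2
    return waves / observed_duration * 60.0


def swim_speed(
    track: WormTrack, strokes: list[StrokeEvent], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Midpoint speed sampled once per two-stroke interval.

    Taking positions only at every second stroke cancels the lateral jitter
    of the stroke cycle, leaving net translation.  Intervals containing any
    censored or missing frame are dropped.
    """
    boundaries = [ev.frame_index for ev in strokes[::2]]
    observed = set(track.observed_frames())
    rows = []
    for f0, f1 in zip(boundaries, boundaries[1:]):
        if any(f not in observed for f in range(f0, f1 + 1)):
            continue
        p0 = np.asarray(track.observations[f0].midpoint)
        p1 = np.asarray(track.observations[f1].midpoint)
        dt = (f1 - f0) / cfg.frame_rate
        rows.append(
            {
                "frame_index": f1,
                "time_s": f1 / cfg.frame_rate,
                "value": float(np.linalg.norm(p1 - p0)) * cfg.ucf / dt,
            }
        )
    return pd.DataFrame(rows, columns=["frame_index", "time_s", "value"])


def dynamic_amplitude(
    series: CurvatureSeries,
    strokes: list[StrokeEvent],
    mode: str = "printed",
) -> pd.DataFrame:
    """|max| - |min| of signed curvature over each two-stroke interval.

    The extrema are taken over all defined tracking points and frames in the
    interval and need not come from the same point.  ``mode="range"``
    computes max - min instead.
    """
    boundaries = [ev.frame_index for ev in strokes[::2]]
    rows = []
    for f0, f1 in zip(boundaries, boundaries[1:]):
        window = [
            series.values[f]
            for f in series.frames()
            if f0 <= f <= f1 and not np.all(np.isnan(series.values[f]))
        ]
        if not window:
            continue
        stack = np.concatenate(window)
        stack = stack[~np.isnan(stack)]
        if stack.size == 0:
            continue
        hi, lo = float(stack.max()), float(stack.min())
        value = (abs(hi) - abs(lo)) if mode == "printed" else (hi - lo)
        rows.append({"frame_index": f1, "time_s": f1 / series.frame_rate, "value": value})
    return pd.DataFrame(rows, columns=["frame_index", "time_s", "value"])


@dataclass
class MetricsTable:
    """Per-frame (or per-interval) rows and per-worm summary means."""

    per_frame: pd.DataFrame  # metric, worm_id, frame_index, time_s, value, units
    summary: pd.DataFrame  # metric, worm_id, mean_value, n_samples, units

    PER_FRAME_COLUMNS = ["metric", "worm_id", "frame_index", "time_s", "value", "units"]
    SUMMARY_COLUMNS = ["metric", "worm_id", "mean_value", "n_samples", "units"]


def summarize(tracks: list[WormTrack], cfg: AnalysisConfig) -> MetricsTable:
    """Compute all six metrics for every track.

    Area, length and crawl speed produce per-frame rows; swim speed and
    dynamic amplitude per two-stroke-interval rows; the wave initiation rate
    is a single per-worm value.  The summary holds the arithmetic mean of
    each worm's rows; worms with no defined samples for a metric are omitted
    from that metric's summary.
    """
    frames_rows: list[dict] = []
    summary_rows: list[dict] = []

    def emit(metric: str, worm_id: int, df: pd.DataFrame) -> None:
        for _, r in df.iterrows():
            frames_rows.append(
                {
                    "metric": metric,
                    "worm_id": worm_id,
                    "frame_index": int(r["frame_index"]),
                    "time_s": float(r["time_s"]),
                    "value": float(r["value"]),
                    "units": METRIC_UNITS[metric],
                }
            )
        if len(df):
            summary_rows.append(
                {
                    "metric": metric,
                    "worm_id": worm_id,
                    "mean_value": float(df["value"].mean()),
                    "n_samples": int(len(df)),
                    "units": METRIC_UNITS[metric],
                }
            )

    for track in tracks:
        frames = track.observed_frames()
        area_df = pd.DataFrame(
            [
                {
                    "frame_index": f,
                    "time_s": f / cfg.frame_rate,
                    "value": worm_area(track.observations[f], cfg),
                }
                for f in frames
            ],
            columns=["frame_index", "time_s", "value"],
        )
        length_df = pd.DataFrame(
            [
                {
                    "frame_index": f,
                    "time_s": f / cfg.frame_rate,
                    "value": worm_length(track.observations[f], cfg),
                }
                for f in frames
            ],
            columns=["frame_index", "time_s", "value"],
        )
        emit("worm_area", track.worm_id, area_df)
        emit("worm_length", track.worm_id, length_df)
        emit("crawl_speed", track.worm_id, crawl_speed(track, cfg))

        if frames:
            series = curvature_series(track, cfg)
            strokes = detect_strokes(series, cfg.stroke_point)
            emit("swim_speed", track.worm_id, swim_speed(track, strokes, cfg))
            emit(
                "dynamic_amplitude",
                track.worm_id,
                dynamic_amplitude(series, strokes, cfg.amplitude_mode),
            )
            duration = track.n_observed_uncensored_duration(cfg.frame_rate)
            if duration > 0:
                rate = wave_initiation_rate(strokes, duration)
                summary_rows.append(
                    {
                        "metric": "wave_initiation_rate",
                        "worm_id": track.worm_id,
                        "mean_value": rate,
                        "n_samples": len(strokes) // 2,
                        "units": METRIC_UNITS["wave_initiation_rate"],
                    }
                )

    per_frame = pd.DataFrame(frames_rows, columns=MetricsTable.PER_FRAME_COLUMNS)
    summary = pd.DataFrame(summary_rows, columns=MetricsTable.SUMMARY_COLUMNS)
    return MetricsTable(per_frame=per_frame, summary=summary)
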