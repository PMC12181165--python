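"""Persistent worm identities across frames, with collision censoring.

Association is greedy: mask overlap with a track's last contour is primary
evidence, nearest centroid within one median body length is the fallback
gate.  An observation that overlaps two or more live tracks is a worm-worm
collision: the participating IDs are terminated, the merged blob is carried
(and rendered) but never measured, and when it resolves into two or more
separate size-gated contours each survivor receives a fresh ID.  IDs are
never reused.

Self-collisions (curls) keep their ID: the worm never merged with another
animal, so the track merely pauses metric collection for those frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .segmentation import ContourObservation
from .skeleton import SkeletonObservation

__all__ = [
    "WormTrack",
    "CollisionEvent",
    "Tracker",
    "match_frame",
    "censor_self_collisions",
    "filter_frame_percentage",
    "track_video",
]

# A track unseen for more than this many consecutive frames (without a
# collision) is closed; a later unmatched contour gets a new ID.
MISSING_PATIENCE = 5


@dataclass
class WormTrack:
    """Time-indexed observations for one worm ID.

    ``observations`` holds frames with valid (measurable) skeletons;
    ``censored`` holds frames where the worm was detected but self-colliding,
    which count as observed for the frame-percentage filter yet contribute no
    metric samples.
    """

    worm_id: int
    observations: dict[int, SkeletonObservation] = field(default_factory=dict)
    censored: dict[int, SkeletonObservation] = field(default_factory=dict)
    first_frame: int = -1
    last_frame: int = -1
    missing_streak: int = 0

    @property
    def n_observed(self) -> int:
        return len(self.observations) + len(self.censored)

    def add(self, frame_index: int, sk: SkeletonObservation) -> None:
        if self.first_frame < 0:
            self.first_frame = frame_index
        self.last_frame = frame_index
        self.missing_streak = 0
        if sk.self_collision:
            self.censored[frame_index] = sk
        else:
            self.observations[frame_index] = sk

    def last_contour(self) -> ContourObservation | None:
        if self.last_frame < 0:
            return None
        sk = self.observations.get(self.last_frame) or self.censored.get(self.last_frame)
        return sk.contour if sk is not None else None

    def observed_frames(self) -> list[int]:
        return sorted(self.observations)

    def n_observed_uncensored_duration(self, frame_rate: float) -> float:
        """Seconds of measurable (un-censored) tracked time."""
        return len(self.observations) / frame_rate


@dataclass
class CollisionEvent:
    """A worm-worm merge interval, half-open ``[start_frame, end_frame)``.

    ``end_frame`` is -1 while unresolved.  ``blob_observations`` keeps the
    merged contour per frame for rendering; it is never measured.
    """

    start_frame: int
    participant_ids: tuple[int, ...]
    kind: str = "worm-worm"
    end_frame: int = -1
    successor_ids: tuple[int, ...] = ()
    blob_observations: dict[int, ContourObservation] = field(default_factory=dict)
    missing_streak: int = 0


class Tracker:
    """Frame-by-frame ID assignment state machine.

    Frames must be fed strictly in order, which makes tracking output
    independent of how segmentation was chunked.
    """

    def __init__(self) -> None:
        self.next_id = 1
        self.active: list[WormTrack] = []
        self.closed: list[WormTrack] = []
        self.open_events: list[CollisionEvent] = []
        self.events: list[CollisionEvent] = []

    def _new_track(self, frame_index: int, sk: SkeletonObservation) -> WormTrack:
        track = WormTrack(worm_id=self.next_id)
        self.next_id += 1
        track.add(frame_index, sk)
        self.active.append(track)
        return track

    def _body_length_gate(self) -> float:
        lengths = [
            sk.midline_len_px
            for t in self.active
            for sk in [t.observations.get(t.last_frame)]
            if sk is not None and sk.midline_len_px
        ]
        return float(np.median(lengths)) if lengths else np.inf

    def step(self, obs: list[SkeletonObservation], frame_index: int) -> None:
        remaining = list(obs)

        # 1. carry open collision blobs: consumed by overlap with the blob
        for ev in list(self.open_events):
            overlapping = [
                sk
                for sk in remaining
                if sk.contour.overlap_px(ev.blob_observations[max(ev.blob_observations)]) > 0
            ]
            if len(overlapping) >= 2:
                # separation complete: close event, issue fresh IDs
                ev.end_frame = frame_index
                successors = []
                for sk in overlapping:
                    remaining.remove(sk)
                    successors.append(self._new_track(frame_index, sk).worm_id)
                ev.successor_ids = tuple(successors)
                self.open_events.remove(ev)
                self.events.append(ev)
            elif len(overlapping) == 1:
                sk = overlapping[0]
                remaining.remove(sk)
                ev.blob_observations[frame_index] = sk.contour
                ev.missing_streak = 0
            else:
                ev.missing_streak += 1
                if ev.missing_streak > MISSING_PATIENCE:
                    ev.end_frame = frame_index
                    self.open_events.remove(ev)
                    self.events.append(ev)

        # 2. overlap matrix between live tracks and remaining observations
        overlaps: dict[int, list[tuple[int, WormTrack]]] = {}
        for track in self.active:
            last = track.last_contour()
            if last is None:
                continue
            for j, sk in enumerate(remaining):
                ov = sk.contour.overlap_px(last)
                if ov > 0:
                    overlaps.setdefault(j, []).append((ov, track))

        # 3. collision starts: one observation overlapping >= 2 tracks
        consumed: set[int] = set()
        collided_tracks: set[int] = set()
        for j, hits in overlaps.items():
            live_hits = [(ov, t) for ov, t in hits if t.worm_id not in collided_tracks]
            if len(live_hits) >= 2:
                participants = tuple(t.worm_id for _, t in live_hits)
                ev = CollisionEvent(start_frame=frame_index, participant_ids=participants)
                ev.blob_observations[frame_index] = remaining[j].contour
                self.open_events.append(ev)
                consumed.add(j)
                for _, t in live_hits:
                    collided_tracks.add(t.worm_id)
                    self.active.remove(t)
                    self.closed.append(t)

        # 4. greedy one-to-one assignment by overlap, largest first
        assigned_tracks: set[int] = set()
        pairs = sorted(
            (
                (ov, j, t)
                for j, hits in overlaps.items()
                if j not in consumed
                for ov, t in hits
                if t.worm_id not in collided_tracks
            ),
            key=lambda p: -p[0],
        )
        for ov, j, track in pairs:
            if j in consumed or track.worm_id in assigned_tracks:
                continue
            track.add(frame_index, remaining[j])
            consumed.add(j)
            assigned_tracks.add(track.worm_id)

        # 5. centroid fallback within one body length for leftover pairs
        gate = self._body_length_gate()
        free_tracks = [
            t
            for t in self.active
            if t.worm_id not in assigned_tracks and t.worm_id not in collided_tracks
        ]
        free_obs = [j for j in range(len(remaining)) if j not in consumed]
        dist_pairs = []
        for t in free_tracks:
            last = t.last_contour()
            if last is None:
                continue
            for j in free_obs:
                d = float(
                    np.hypot(
                        remaining[j].contour.centroid[0] - last.centroid[0],
                        remaining[j].contour.centroid[1] - last.centroid[1],
                    )
                )
                if d <= gate:
                    dist_pairs.append((d, j, t))
        for d, j, t in sorted(dist_pairs, key=lambda p: p[0]):
            if j in consumed or t.worm_id in assigned_tracks:
                continue
            t.add(frame_index, remaining[j])
            consumed.add(j)
            assigned_tracks.add(t.worm_id)

        # 6. unmatched observations found a new worm
        for j in range(len(remaining)):
            if j not in consumed:
                self._new_track(frame_index, remaining[j])

        # 7. unmatched tracks are carried as missing, with finite patience
        for track in list(self.active):
            if track.worm_id in assigned_tracks or track.last_frame == frame_index:
                continue
            track.missing_streak += 1
            if track.missing_streak > MISSING_PATIENCE:
                self.active.remove(track)
                self.closed.append(track)

    def finish(self) -> tuple[list[WormTrack], list[CollisionEvent]]:
        tracks = sorted(self.closed + self.active, key=lambda t: t.worm_id)
        events = self.events + self.open_events
        return tracks, events


def match_frame(
    tracker: Tracker, obs: list[SkeletonObservation], frame_index: int
) -> tuple[list[WormTrack], list[CollisionEvent]]:
    """Advance the tracker by one frame; returns its live tracks and events."""
    tracker.step(obs, frame_index)
    return tracker.active, tracker.events + tracker.open_events


def censor_self_collisions(track: WormTrack) -> WormTrack:
    """Move self-colliding frames out of the measurable observation map.

    ``Tracker`` already routes self-collision skeletons into ``censored``;
    this pass makes the operation idempotent for externally built tracks.
    """
    for frame in [f for f, sk in track.observations.items() if sk.self_collision]:
        track.censored[frame] = track.observations.pop(frame)
    return track


def filter_frame_percentage(
    tracks: list[WormTrack], total_frames: int, min_pct: float
) -> list[WormTrack]:
    """Drop tracks observed in fewer than ``min_pct`` percent of all frames.

    The threshold is inclusive and applied once, globally, against the full
    video length.
    """
    if not 0 <= min_pct <= 100:
        raise ParameterError(f"min_pct must be in [0, 100], got {min_pct}")
    if total_frames < 1:
        raise ParameterError(f"total_frames must be >= 1, got {total_frames}")
    return [t for t in tracks if 100.0 * t.n_observed / total_frames >= min_pct]


def track_video(
    per_frame_obs: list[list[SkeletonObservation]],
) -> tuple[list[WormTrack], list[CollisionEvent]]:
    """Run the tracker over per-frame skeleton observations in frame order."""
    tracker = Tracker()
    for frame_index, obs in enumerate(per_frame_obs):
        tracker.step(obs, frame_index)
    tracks, events = tracker.finish()
    for t in tracks:
        censor_self_collisions(t)
    return tracks, events
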