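"""Midline extraction from worm contours.

Each contour mask is thinned to a 1-pixel-wide skeleton; the midline is the
longest endpoint-to-endpoint geodesic through the skeleton pixel graph, with
short spurs pruned and each end extended along its local tangent to the mask
boundary (worm tips taper, so thinning stops short of them).  Seven tracking
points are placed at equal arclength fractions 0, 1/6, ..., 1; tracking
point 3 is the worm midpoint used for speed measures.

Self-collisions (a worm curling into a closed loop or overlapping its own
body) are flagged rather than measured: an interior hole in the mask, a
skeleton cycle, or a residual branch after spur pruning all raise the flag.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _thin

from .errors import DegenerateShapeError
from .segmentation import ContourObservation

__all__ = [
    "SkeletonObservation",
    "skeletonize",
    "sample_tracking_points",
    "detect_self_collision",
    "path_length",
]

log = logging.getLogger(__name__)

# Spurs shorter than this fraction of the main path are pruning artifacts;
# longer side branches mean the body overlaps itself.
SPUR_FRACTION = 0.10
# and spurs shorter than this many pixels are always artifacts
MIN_SPUR_PX = 4
# interior holes below this pixel count are threshold speckle, not a closed
# loop of the body, and are filled before thinning
MIN_HOLE_PX = 16

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonObservation:
    """Ordered midline and tracking points for one worm in one frame.

    When ``self_collision`` is true the geometry fields are ``None`` and the
    observation contributes no metric samples.
    """

    contour: ContourObservation
    midline: np.ndarray | None  # (m, 2) float (x, y), ordered end to end
    midline_len_px: float | None  # polyline arclength in pixel units
    tracking_points: np.ndarray | None  # (7, 2) float (x, y)
    midpoint: tuple[float, float] | None  # tracking point 3
    self_collision: bool

    @property
    def frame_index(self) -> int:
        return self.contour.frame_index


def path_length(path: np.ndarray) -> float:
    """Arclength of an ordered polyline in pixel units."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def _pixel_graph(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pix = set(zip(*np.nonzero(skel)))
    return {
        p: [q for d in _N8 if (q := (p[0] + d[0], p[1] + d[1])) in pix] for p in pix
    }


def _bfs(
    graph: dict, start: tuple[int, int]
) -> tuple[dict[tuple[int, int], int], dict[tuple[int, int], tuple[int, int]]]:
    dist = {start: 0}
    parent: dict = {}
    queue = deque([start])
    while queue:
        p = queue.popleft()
        for q in graph[p]:
            if q not in dist:
                dist[q] = dist[p] + 1
                parent[q] = p
                queue.append(q)
    return dist, parent


def _longest_endpoint_path(graph: dict) -> list[tuple[int, int]] | None:
    """Geodesic between the farthest-apart pair of skeleton endpoints."""
    endpoints = [p for p, nb in graph.items() if len(nb) <= 1]
    if len(endpoints) < 2:
        return None
    best = None
    best_len = -1
    for a in endpoints:
        dist, parent = _bfs(graph, a)
        reach = [e for e in endpoints if e in dist and e != a]
        if not reach:
            continue
        b = max(reach, key=dist.get)
        if dist[b] > best_len:
            best_len = dist[b]
            path = [b]
            while path[-1] != a:
                path.append(parent[path[-1]])
            best = path[::-1]
    return best


def _holes(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask) & ~mask


def _has_real_hole(mask: np.ndarray) -> bool:
    holes = _holes(mask)
    if not holes.any():
        return False
    labels, n = ndimage.label(holes)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return bool(np.any(sizes >= MIN_HOLE_PX))


def _fill_speckle_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes below the speckle threshold before thinning."""
    holes = _holes(mask)
    if not holes.any():
        return mask
    labels, n = ndimage.label(holes)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    small = np.flatnonzero(sizes < MIN_HOLE_PX) + 1
    return mask | np.isin(labels, small)


def detect_self_collision(contour: ContourObservation, raw_skeleton: np.ndarray) -> bool:
    """True iff the mask has an interior hole or the pruned skeleton branches.

    A curled worm closes a loop (hole); an overlapping body leaves a branch
    point or a third endpoint that survives spur pruning.  Holes smaller
    than :data:`MIN_HOLE_PX` are thresholding speckle and ignored.
    """
    mask = contour.mask
    if _has_real_hole(mask):
        return True
    graph = _pixel_graph(raw_skeleton)
    if not graph:
        return False
    main = _longest_endpoint_path(graph)
    if main is None:  # pure cycle, no endpoints
        return True
    on_path = set(main)
    off = {p for p in graph if p not in on_path}
    if not off:
        return False
    # longest off-path branch, measured as geodesic depth away from the main path
    limit = max(SPUR_FRACTION * len(main), MIN_SPUR_PX)
    depth = {p: 0 for p in on_path}
    queue = deque(on_path)
    seen = set(on_path)
    max_depth = 0
    while queue:
        p = queue.popleft()
        for q in graph[p]:
            if q not in seen:
                seen.add(q)
                depth[q] = depth[p] + 1
                max_depth = max(max_depth, depth[q])
                queue.append(q)
    if len(off - seen) > 0:  # disconnected skeleton piece: overlapping body
        return True
    return max_depth > limit


def _extend_end(
    end: np.ndarray, inward: np.ndarray, mask: np.ndarray, origin: tuple[int, int]
) -> list[np.ndarray]:
    """March from a path end along the outward tangent until leaving the mask.

    Returns extra (x, y) vertices (possibly empty) in marching order.
    """
    direction = end - inward
    norm = np.linalg.norm(direction)
    if norm == 0:
        return []
    direction = direction / norm
    x0, y0 = origin
    h, w = mask.shape
    extra = []
    step = 0.5
    pos = end.astype(float)
    for _ in range(int(2 * max(h, w))):
        nxt = pos + direction * step
        col = int(round(nxt[0])) - x0
        row = int(round(nxt[1])) - y0
        if not (0 <= row < h and 0 <= col < w) or not mask[row, col]:
            break
        pos = nxt
        extra.append(pos.copy())
    return extra


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average along the path, end points held fixed.

    Removes pixel-staircase jitter while leaving body-scale bends (many
    times the window) essentially untouched.
    """
    if len(path) <= window:
        return path
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(path, ((pad, pad), (0, 0)), mode="edge")
    smooth = np.column_stack(
        [np.convolve(padded[:, i], kernel, mode="valid") for i in (0, 1)]
    )
    smooth[0] = path[0]
    smooth[-1] = path[-1]
    return smooth


def skeletonize(contour: ContourObservation) -> SkeletonObservation:
    """Thin a contour mask to its ordered midline and tracking points."""
    mask = _fill_speckle_holes(contour.mask)
    skel = _thin(mask)
    if skel.sum() <= 1:
        raise DegenerateShapeError(
            f"contour at frame {contour.frame_index} thins to a single pixel"
        )
    if detect_self_collision(contour, skel):
        log.debug("self-collision at frame %d", contour.frame_index)
        return SkeletonObservation(contour, None, None, None, None, True)

    graph = _pixel_graph(skel)
    main = _longest_endpoint_path(graph)
    if main is None or len(main) < 2:
        raise DegenerateShapeError(
            f"contour at frame {contour.frame_index} has no two-endpoint midline"
        )
    x0, y0, _, _ = contour.bbox
    # (row, col) pixels -> global (x, y)
    path = np.array([[c + x0, r + y0] for r, c in main], dtype=float)

    k = min(4, len(path) - 1)
    head_ext = _extend_end(path[0], path[k], mask, (x0, y0))
    tail_ext = _extend_end(path[-1], path[-1 - k], mask, (x0, y0))
    midline = np.vstack(
        [arr for arr in (head_ext[::-1], path, tail_ext) if len(arr)]
    )
    # The raw pixel path is a staircase; unsmoothed, its chain length
    # overestimates oblique midlines by up to ~8% and the jagged vertices
    # leak into the curvature of the tracking points.
    midline = _smooth_path(midline)
    length = path_length(midline)
    if length < 2 or len(midline) < 7:
        raise DegenerateShapeError(
            f"contour at frame {contour.frame_index} midline too short ({length:.1f} px)"
        )
    points = sample_tracking_points(midline)
    return SkeletonObservation(
        contour=contour,
        midline=midline,
        midline_len_px=length,
        tracking_points=points,
        midpoint=(float(points[3, 0]), float(points[3, 1])),
        self_collision=False,
    )


def sample_tracking_points(midline: np.ndarray) -> np.ndarray:
    """Seven on-path points at arclength fractions 0, 1/6, ..., 1.

    Positions are interpolated along the polyline at the exact target
    arclengths, so consecutive spacings are equal by construction and the
    end points coincide with the midline ends.
    """
    midline = np.asarray(midline, dtype=float)
    if len(midline) < 7:
        raise DegenerateShapeError(f"midline has {len(midline)} < 7 vertices")
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], 7)
    xs = np.interp(targets, cum, midline[:, 0])
    ys = np.interp(targets, cum, midline[:, 1])
    return np.column_stack([xs, ys])
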