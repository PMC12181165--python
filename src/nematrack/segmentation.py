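"""Per-frame worm segmentation.

The preprocessing chain is temporal-median background subtraction, Otsu
thresholding of the absolute difference image, and a 3x3 morphological
opening to drop isolated speckle.  Candidate worms are 8-connected
foreground components, gated by a minimum pixel count (inclusive) and by
removal of components that touch the frame border.

Masks use image convention: row = y (down), column = x (right), 0-based.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import reconstruction

from .errors import ParameterError
from .video_io import FrameSequence, chunk_frames

__all__ = [
    "ContourObservation",
    "BackgroundModel",
    "build_background",
    "preprocess_frame",
    "find_contours",
    "filter_min_size",
    "filter_edge_touching",
    "segment_frame",
    "segment_video",
]

_EIGHT = np.ones((3, 3), dtype=bool)

# Below this peak |frame - reference| difference a frame is considered
# foreground-free; Otsu on a near-constant image is meaningless.
MIN_CONTRAST = 10


@dataclass
class ContourObservation:
    """One segmented worm candidate in one frame.

    ``mask`` is cropped to ``bbox`` = (x0, y0, x1, y1), half-open, to keep
    memory proportional to worm size rather than frame size.
    """

    frame_index: int
    mask: np.ndarray  # bool, shape (y1 - y0, x1 - x0)
    bbox: tuple[int, int, int, int]
    boundary: np.ndarray  # ordered (k, 2) float array of (x, y) polygon points
    area_px: int
    centroid: tuple[float, float]  # (x, y)

    def mask_pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Global (rows, cols) of the mask pixels."""
        rr, cc = np.nonzero(self.mask)
        x0, y0, _, _ = self.bbox
        return rr + y0, cc + x0

    def overlap_px(self, other: "ContourObservation") -> int:
        """Pixel count of the mask intersection with another observation."""
        ax0, ay0, ax1, ay1 = self.bbox
        bx0, by0, bx1, by1 = other.bbox
        x0, y0 = max(ax0, bx0), max(ay0, by0)
        x1, y1 = min(ax1, bx1), min(ay1, by1)
        if x0 >= x1 or y0 >= y1:
            return 0
        a = self.mask[y0 - ay0 : y1 - ay0, x0 - ax0 : x1 - ax0]
        b = other.mask[y0 - by0 : y1 - by0, x0 - bx0 : x1 - bx0]
        return int(np.count_nonzero(a & b))


@dataclass
class BackgroundModel:
    """Per-pixel temporal-median reference frame.

    ``polarity`` records whether worms are dark on a light substrate
    (the common transmitted-light case) or the reverse; segmentation uses
    the absolute difference so both work identically.
    """

    reference: np.ndarray  # uint8, (h, w)
    polarity: str = "dark-on-light"


def build_background(seq: FrameSequence, sample_stride: int = 1) -> BackgroundModel:
    """Median of every ``sample_stride``-th frame.

    Any pixel a moving worm occupies in fewer than half of the sampled
    frames converges to the substrate intensity, so static debris stays in
    the reference and is subtracted away.
    """
    if sample_stride < 1:
        raise ParameterError(f"sample_stride must be >= 1, got {sample_stride}")
    sampled = seq.frames[::sample_stride]
    reference = np.median(sampled, axis=0).astype(np.uint8)
    return BackgroundModel(reference=reference)


def preprocess_frame(frame: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """Binary foreground mask for one frame.

    Worm pixels are separated from the substrate by an automatic (Otsu)
    intensity threshold oriented by the polarity flag.  The temporal-median
    reference then removes static artifacts at the component level: a
    candidate that does not differ from the reference over its own pixels
    (debris, smudges) is discarded, while a live worm - even one undulating
    in place whose body core never uncovers - stays intact.
    """
    frame = np.asarray(frame)
    if frame.shape != bg.reference.shape:
        raise ParameterError(
            f"frame shape {frame.shape} does not match background {bg.reference.shape}"
        )
    diff = np.abs(frame.astype(np.int16) - bg.reference.astype(np.int16))
    if diff.max() < MIN_CONTRAST:
        return np.zeros(frame.shape, dtype=bool)
    thresh = threshold_otsu(frame)
    # inclusive: on a noiseless two-level image Otsu returns the foreground
    # level itself
    fg = frame <= thresh if bg.polarity == "dark-on-light" else frame >= thresh
    # opening by reconstruction: drops speckle that a 3x3 erosion destroys
    # while restoring surviving components exactly (worm tips taper to a
    # single pixel and must not be shaved off)
    eroded = ndimage.binary_erosion(fg, structure=_EIGHT)
    fg = reconstruction(eroded, fg, method="dilation", footprint=_EIGHT).astype(bool)
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n:
        # mean |frame - reference| per component; static components score ~0
        mean_diff = ndimage.mean(diff, labels=labels, index=np.arange(1, n + 1))
        static = np.flatnonzero(mean_diff < MIN_CONTRAST) + 1
        if static.size:
            fg &= ~np.isin(labels, static)
    return fg


def find_contours(mask: np.ndarray, frame_index: int) -> list[ContourObservation]:
    """One observation per 8-connected foreground component."""
    labels, n = ndimage.label(mask, structure=_EIGHT)
    observations: list[ContourObservation] = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == i
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        area = int(comp.sum())
        rr, cc = np.nonzero(comp)
        centroid = (float(cc.mean() + x0), float(rr.mean() + y0))
        boundary = _outer_boundary(comp, x0, y0)
        observations.append(
            ContourObservation(
                frame_index=frame_index,
                mask=comp,
                bbox=(x0, y0, x1, y1),
                boundary=boundary,
                area_px=area,
                centroid=centroid,
            )
        )
    return observations


def _outer_boundary(comp: np.ndarray, x0: int, y0: int) -> np.ndarray:
    """Longest iso-contour of the padded component, in global (x, y)."""
    padded = np.pad(comp.astype(np.uint8), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:  # single-pixel component
        rr, cc = np.nonzero(comp)
        return np.array([[cc[0] + x0, rr[0] + y0]], dtype=float)
    outer = max(contours, key=len)
    # find_contours returns (row, col); convert to (x, y) and undo padding
    return np.column_stack([outer[:, 1] - 1 + x0, outer[:, 0] - 1 + y0])


def filter_min_size(
    obs: list[ContourObservation], min_size_px: float
) -> list[ContourObservation]:
    """Keep observations with ``area_px >= min_size_px`` (inclusive)."""
    if min_size_px < 0:
        raise ParameterError(f"min_size_px must be >= 0, got {min_size_px}")
    return [o for o in obs if o.area_px >= min_size_px]


def filter_edge_touching(
    obs: list[ContourObservation], width: int, height: int
) -> list[ContourObservation]:
    """Drop observations whose mask touches the frame border.

    Bounding boxes are tight, so touching reduces to a bbox test.
    """
    return [
        o
        for o in obs
        if o.bbox[0] > 0 and o.bbox[1] > 0 and o.bbox[2] < width and o.bbox[3] < height
    ]


def segment_frame(
    frame: np.ndarray,
    bg: BackgroundModel,
    frame_index: int,
    min_size_px: float,
) -> list[ContourObservation]:
    """Full per-frame chain: preprocess, components, size gate, edge filter."""
    mask = preprocess_frame(frame, bg)
    obs = find_contours(mask, frame_index)
    obs = filter_min_size(obs, min_size_px)
    h, w = frame.shape
    return filter_edge_touching(obs, w, h)


def segment_video(
    seq: FrameSequence,
    bg: BackgroundModel,
    min_size_px: float,
    chunk_size: int | None = None,
    workers: int = 1,
) -> list[list[ContourObservation]]:
    """Segment every frame, chunk-parallel, merged strictly in frame order.

    Each frame depends only on (frame, background), so any chunking yields
    an identical per-frame contour list; worker threads only change wall
    time, never output.
    """
    if chunk_size is None:
        chunk_size = max(1, seq.n_frames // max(1, workers))
    chunks = chunk_frames(seq, chunk_size)

    def run(chunk):
        return [
            segment_frame(frame, bg, chunk.start_index + j, min_size_px)
            for j, frame in enumerate(chunk.frames)
        ]

    if workers <= 1:
        results = [run(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run, chunks))
    merged: list[list[ContourObservation]] = []
    for r in results:
        merged.extend(r)
    return merged
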