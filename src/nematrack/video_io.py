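"""Video decoding, frame chunking and annotated-video encoding.

Frames are held as a single ``(n_frames, height, width)`` uint8 array in
grayscale.  The native containers are multi-page TIFF (frame rate stored as
JSON in the image description tag) and GIF (frame rate from frame duration);
AVI/MP4 are decoded through imageio when an ffmpeg-capable plugin is
importable in the running environment.

Frame indices are 0-based and intervals half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

from .errors import ConfigurationError, DecodeError, ParameterError

__all__ = [
    "FrameSequence",
    "FrameChunk",
    "load_video",
    "write_video",
    "chunk_frames",
    "write_annotated_video",
]

# ITU-R BT.601 luma weights for color -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames plus the capture frame rate."""

    frames: np.ndarray  # (n, h, w) uint8
    frame_rate: float  # frames / second

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError(
                f"frames must be a (n, h, w) stack, got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise ParameterError("a frame sequence needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ParameterError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def times(self) -> np.ndarray:
        """Seconds from frame 0 for each frame index."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class FrameChunk:
    """A half-open slice ``[start_index, end_index)`` of a FrameSequence."""

    start_index: int
    end_index: int
    frames: np.ndarray

    def __len__(self) -> int:
        return self.end_index - self.start_index


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Collapse an (n, h, w[, 3|4]) stack to 8-bit grayscale."""
    frames = np.asarray(frames)
    if frames.ndim == 4:
        frames = frames[..., :3] @ _LUMA
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return frames


def load_video(path: str | Path, frame_rate_override: float | None = None) -> FrameSequence:
    """Decode a video file into a grayscale :class:`FrameSequence`.

    The frame rate comes from container metadata unless overridden.  TIFF
    stacks written by :func:`write_video` carry it in the image description;
    GIF carries it as per-frame duration.
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"video file does not exist: {path}")
    if path.stat().st_size == 0:
        raise DecodeError(f"video file is empty: {path}")

    suffix = path.suffix.lower()
    fps: float | None = None
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tif:
                frames = tif.asarray()
                desc = tif.pages[0].description
            if desc:
                try:
                    fps = float(json.loads(desc).get("frame_rate"))
                except (ValueError, TypeError, json.JSONDecodeError):
                    fps = None
        elif suffix == ".gif":
            frames, fps = _read_gif(path)
        else:
            frames, fps = _read_via_imageio(path)
    except DecodeError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise DecodeError(f"could not decode video {path}: {exc}") from exc

    frames = to_grayscale(np.atleast_3d(frames))
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise DecodeError(f"video {path} decodes to fewer than 2 frames")

    if frame_rate_override is not None:
        fps = float(frame_rate_override)
    if fps is None or not fps > 0:
        raise ConfigurationError(
            f"no frame-rate metadata in {path}; pass frame_rate_override"
        )
    return FrameSequence(frames=frames, frame_rate=fps)


def _read_gif(path: Path) -> tuple[np.ndarray, float | None]:
    frames = []
    duration_ms = None
    with Image.open(path) as im:
        try:
            while True:
                duration_ms = im.info.get("duration", duration_ms)
                frames.append(np.asarray(im.convert("L")))
                im.seek(im.tell() + 1)
        except EOFError:
            pass
    fps = 1000.0 / duration_ms if duration_ms else None
    return np.stack(frames), fps


def _read_via_imageio(path: Path) -> tuple[np.ndarray, float | None]:
    try:
        import imageio.v2 as iio

        reader = iio.get_reader(path)
    except Exception as exc:  # noqa: BLE001
        raise DecodeError(
            f"no decoder available for {path.suffix} container ({exc}); "
            "use a TIFF/GIF container or install an ffmpeg imageio plugin"
        ) from exc
    meta = reader.get_meta_data()
    frames = np.stack([np.asarray(f) for f in reader])
    reader.close()
    fps = meta.get("fps")
    return frames, float(fps) if fps else None


def write_video(seq: FrameSequence, path: str | Path, frames: np.ndarray | None = None) -> None:
    """Encode a frame stack (grayscale or RGB) with frame-rate metadata.

    ``frames`` overrides ``seq.frames`` so annotated RGB stacks can reuse the
    sequence's metadata.
    """
    path = Path(path)
    data = seq.frames if frames is None else np.asarray(frames)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            tifffile.imwrite(
                path,
                data,
                description=json.dumps({"frame_rate": seq.frame_rate}),
                photometric="rgb" if data.ndim == 4 else "minisblack",
            )
        elif suffix == ".gif":
            mode = "RGB" if data.ndim == 4 else "L"
            ims = [Image.fromarray(f, mode=mode) for f in data]
            ims[0].save(
                path,
                save_all=True,
                append_images=ims[1:],
                duration=int(round(1000.0 / seq.frame_rate)),
                loop=0,
            )
        else:
            import imageio.v2 as iio

            iio.mimwrite(path, list(data), fps=seq.frame_rate)
    except OSError as exc:
        raise OSError(f"cannot write video to {path}: {exc}") from exc


def chunk_frames(seq: FrameSequence, chunk_size: int) -> list[FrameChunk]:
    """Partition the sequence into half-open chunks that tile it exactly."""
    if chunk_size < 1:
        raise ParameterError(f"chunk_size must be >= 1, got {chunk_size}")
    chunks = []
    for start in range(0, seq.n_frames, chunk_size):
        end = min(start + chunk_size, seq.n_frames)
        chunks.append(FrameChunk(start, end, seq.frames[start:end]))
    return chunks


# Overlay palette: tracked worms vs censored (collision / curl) frames.
TRACKED_COLOR = (60, 120, 255)  # blue
COLLISION_COLOR = (255, 210, 40)  # yellow


def write_annotated_video(
    seq: FrameSequence,
    tracks: Sequence,
    path: str | Path,
    events: Sequence | None = None,
) -> None:
    """Render tracking overlays onto the video and encode it.

    Tracked observations are drawn in blue with the worm ID at the midpoint;
    censored frames (self-collisions and worm-worm collision blobs) are drawn
    in yellow so collision intervals are visually distinct.
    """
    out = np.repeat(seq.frames[..., None], 3, axis=3).copy()
    for i in range(seq.n_frames):
        im = Image.fromarray(out[i], mode="RGB")
        draw = ImageDraw.Draw(im)
        for track in tracks:
            sk = track.observations.get(i)
            if sk is not None:
                _draw_observation(draw, sk, TRACKED_COLOR, track.worm_id)
            censored = getattr(track, "censored", {}).get(i)
            if censored is not None:
                _draw_observation(draw, censored, COLLISION_COLOR, track.worm_id)
        for ev in events or ():
            blob = ev.blob_observations.get(i)
            if blob is not None:
                _draw_contour(draw, blob, COLLISION_COLOR)
        out[i] = np.asarray(im)
    write_video(seq, path, frames=out)


def _draw_contour(draw: ImageDraw.ImageDraw, contour, color) -> None:
    poly = [(float(x), float(y)) for x, y in contour.boundary]
    if len(poly) >= 2:
        draw.line(poly, fill=color, width=1)


def _draw_observation(draw: ImageDraw.ImageDraw, sk, color, worm_id: int) -> None:
    contour = getattr(sk, "contour", sk)
    _draw_contour(draw, contour, color)
    midline = getattr(sk, "midline", None)
    if midline is not None:
        draw.line([(float(x), float(y)) for x, y in midline], fill=(255, 255, 0))
    cx, cy = contour.centroid
    draw.text((cx + 3, cy + 3), str(worm_id), fill=color)
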