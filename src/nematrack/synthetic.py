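"""Synthetic multi-worm videos with exact ground truth.

Worm bodies follow a serpenoid model: signed centerline curvature

    kappa(s, t) = kappa0 * sin(2*pi*s/lambda - 2*pi*f*t + phase)

for arclength s along a body of fixed length, undulation frequency f and
body wavelength lambda.  The heading integral of kappa is available in
closed form, so the rendered curve has exact, known arclength and per-point
curvature - the oracle every detection and metric test compares against.
The body is a tube whose half-width tapers to a point at head and tail, as
real worms do.

Scenes raster worms dark-on-light, add Gaussian pixel noise, and record a
ground-truth sidecar: per frame and worm, the rendered pixel count, midpoint
position, analytic curvature at the seven tracking fractions, and flags for
curls (scripted closed-loop postures), border contact and worm-worm overlap.

Coordinates use image convention (x right, y down); a fixed seed makes the
rendered byte stream fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from skimage.draw import disk, polygon

from .errors import SpecificationError
from .video_io import FrameSequence

__all__ = [
    "WormSpec",
    "SceneSpec",
    "GroundTruth",
    "centerline",
    "render_scene",
    "crawl_scene",
    "swim_scene",
    "collision_scene",
    "curl_scene",
]

# half-width profile tapers over this leading/trailing fraction of the body
TAPER_FRACTION = 0.15
# closed-loop posture: constant curvature of 1.2 full turns over the body
CURL_TURNS = 1.2


@dataclass
class WormSpec:
    """Kinematics of one simulated worm.

    Defaults approximate a day-1 adult: ~1 mm body, ~70 um width, body wave
    of moderate amplitude.  ``curl_frames`` lists frame indices where the
    worm is posed as a closed loop (self-collision).
    """

    length_um: float = 1000.0
    width_um: float = 70.0
    drift_um_s: tuple[float, float] = (0.0, 0.0)
    freq_hz: float = 1.0
    kappa0_per_um: float = 0.006
    wavelength_um: float = 900.0
    init_pos_um: tuple[float, float] = (0.0, 0.0)
    heading_rad: float = 0.0
    phase: float = 0.0
    curl_frames: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.length_um > self.width_um > 0:
            raise SpecificationError("need length_um > width_um > 0")
        if self.freq_hz < 0:
            raise SpecificationError("undulation frequency must be >= 0")


@dataclass
class SceneSpec:
    """One rendered video: worms, optics and noise."""

    worms: list[WormSpec]
    width_px: int = 320
    height_px: int = 320
    ucf: float = 5.0  # um per pixel
    frame_rate: float = 7.5
    n_frames: int = 60
    bg_intensity: int = 200
    worm_intensity: int = 60
    noise_sigma: float = 3.0
    seed: int = 0


@dataclass
class CenterlineSample:
    """Analytic centerline at one time point."""

    points_um: np.ndarray  # (n, 2)
    s_um: np.ndarray  # (n,) arclengths, 0..length
    curvature_per_um: np.ndarray  # (n,) signed kappa at each sample
    length_um: float

    def curvature_at_fraction(self, fractions: np.ndarray) -> np.ndarray:
        return np.interp(fractions * self.length_um, self.s_um, self.curvature_per_um)

    def point_at_fraction(self, fraction: float) -> np.ndarray:
        s = fraction * self.length_um
        return np.array(
            [
                np.interp(s, self.s_um, self.points_um[:, 0]),
                np.interp(s, self.s_um, self.points_um[:, 1]),
            ]
        )


def centerline(
    spec: WormSpec, t: float, n: int = 600, curl: bool = False
) -> CenterlineSample:
    """Exact serpenoid centerline at time ``t``.

    The curve is arclength-parameterized, so its length is ``length_um`` by
    construction; the worm midpoint (s = L/2) sits at
    ``init_pos_um + drift * t``.  With ``curl=True`` the body is a constant
    curvature loop of :data:`CURL_TURNS` turns instead.
    """
    L = spec.length_um
    s = np.linspace(0.0, L, n)
    if curl:
        kappa = np.full(n, CURL_TURNS * 2.0 * math.pi / L)
        theta = spec.heading_rad + kappa * s
    else:
        two_pi = 2.0 * math.pi
        c = spec.phase - two_pi * spec.freq_hz * t
        kappa = spec.kappa0_per_um * np.sin(two_pi * s / spec.wavelength_um + c)
        alpha = spec.kappa0_per_um * spec.wavelength_um / two_pi
        theta = spec.heading_rad + alpha * (
            math.cos(c) - np.cos(two_pi * s / spec.wavelength_um + c)
        )
    x = cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    y = cumulative_trapezoid(np.sin(theta), s, initial=0.0)
    pts = np.column_stack([x, y])
    mid = np.array(
        [np.interp(L / 2, s, x), np.interp(L / 2, s, y)]
    )
    target = np.asarray(spec.init_pos_um) + np.asarray(spec.drift_um_s) * t
    pts += target - mid
    return CenterlineSample(points_um=pts, s_um=s, curvature_per_um=kappa, length_um=L)


def _half_width_profile(spec: WormSpec, s_um: np.ndarray) -> np.ndarray:
    """Tapered half-width: full in the trunk, elliptical fall-off to the tips."""
    u = s_um / spec.length_um
    edge = np.minimum(u, 1.0 - u) / TAPER_FRACTION
    return 0.5 * spec.width_um * np.sqrt(np.clip(edge, 0.0, 1.0))


def _rasterize_worm(
    sample: CenterlineSample, spec: WormSpec, scene: SceneSpec, curl: bool
) -> np.ndarray:
    """Boolean body mask for one worm on the scene canvas."""
    shape = (scene.height_px, scene.width_px)
    mask = np.zeros(shape, dtype=bool)
    pts_px = sample.points_um / scene.ucf
    radius_px = _half_width_profile(spec, sample.s_um) / scene.ucf
    if curl:
        # self-overlapping outline: stamp discs (polygon fill would cancel
        # the overlap under even-odd rules)
        for (px, py), r in zip(pts_px, radius_px):
            if r < 0.5:
                continue
            rr, cc = disk((py, px), r, shape=shape)
            mask[rr, cc] = True
        return mask
    tangent = np.gradient(pts_px, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    norms[norms == 0] = 1.0
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]]) / norms[:, None]
    left = pts_px + normal * radius_px[:, None]
    right = pts_px - normal * radius_px[:, None]
    outline = np.vstack([left, right[::-1]])
    rr, cc = polygon(outline[:, 1], outline[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


@dataclass
class GroundTruth:
    """Per-frame, per-worm truth for a rendered scene.

    ``table`` columns: frame, worm, pixels, mid_x_px, mid_y_px, arclength_um,
    curl, border, collision, and k0..k6 — the signed analytic curvature
    (1/um) at the seven tracking fractions.
    """

    scene: SceneSpec
    table: pd.DataFrame
    masks: dict[tuple[int, int], np.ndarray] | None = None

    def worm_rows(self, worm: int) -> pd.DataFrame:
        return self.table[self.table["worm"] == worm]

    def flags(self, worm: int, column: str) -> list[int]:
        rows = self.worm_rows(worm)
        return sorted(rows.loc[rows[column], "frame"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def render_scene(
    scene: SceneSpec, store_masks: bool = False
) -> tuple[FrameSequence, GroundTruth]:
    """Raster the scene and assemble its ground-truth sidecar."""
    diag_um = math.hypot(scene.width_px, scene.height_px) * scene.ucf
    for spec in scene.worms:
        if spec.length_um > diag_um:
            raise SpecificationError(
                f"worm of length {spec.length_um} um exceeds frame diagonal {diag_um:.0f} um"
            )
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((scene.n_frames, scene.height_px, scene.width_px), dtype=np.uint8)
    rows: list[dict] = []
    masks: dict[tuple[int, int], np.ndarray] = {}
    fractions = np.arange(7) / 6.0

    for i in range(scene.n_frames):
        t = i / scene.frame_rate
        worm_masks = []
        samples = []
        for w, spec in enumerate(scene.worms):
            curl = i in spec.curl_frames
            sample = centerline(spec, t, curl=curl)
            m = _rasterize_worm(sample, spec, scene, curl)
            worm_masks.append(m)
            samples.append((sample, curl))
        union = np.zeros_like(worm_masks[0]) if worm_masks else None
        counts = np.zeros((scene.height_px, scene.width_px), dtype=np.int16)
        for m in worm_masks:
            union |= m
            counts += m
        for w, (m, (sample, curl)) in enumerate(zip(worm_masks, samples)):
            overlap = bool(np.any(m & (counts >= 2))) if len(worm_masks) > 1 else False
            border = bool(
                m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()
            )
            mid = sample.point_at_fraction(0.5) / scene.ucf
            kappas = sample.curvature_at_fraction(fractions)
            row = {
                "frame": i,
                "worm": w,
                "pixels": int(m.sum()),
                "mid_x_px": float(mid[0]),
                "mid_y_px": float(mid[1]),
                "arclength_um": sample.length_um,
                "curl": curl,
                "border": border,
                "collision": overlap,
            }
            row.update({f"k{j}": float(kappas[j]) for j in range(7)})
            rows.append(row)
            if store_masks:
                masks[(w, i)] = m
        frame = np.full(
            (scene.height_px, scene.width_px), float(scene.bg_intensity)
        )
        if union is not None:
            frame[union] = scene.worm_intensity
        if scene.noise_sigma > 0:
            frame += rng.normal(0.0, scene.noise_sigma, size=frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames, frame_rate=scene.frame_rate)
    truth = GroundTruth(
        scene=scene,
        table=pd.DataFrame(rows),
        masks=masks if store_masks else None,
    )
    return seq, truth


# --------------------------------------------------------------------------
# Named fixture scenes.  Defaults mirror the two assay protocols (crawling:
# 7.5 fps on plates; thrashing/swimming: 14 fps in liquid) at CI scale -
# a few worms on a small field rather than 20-50 on a full plate.
# --------------------------------------------------------------------------


def _spread_positions(n: int, scene_um: float, rng: np.random.Generator) -> list:
    cells = math.ceil(math.sqrt(n))
    pitch = scene_um / (cells + 1)
    pos = []
    for k in range(n):
        gx, gy = k % cells, k // cells
        jitter = rng.uniform(-0.15, 0.15, 2) * pitch
        pos.append((pitch * (gx + 1) + jitter[0], pitch * (gy + 1) + jitter[1]))
    return pos


def crawl_scene(
    n_worms: int = 3,
    n_frames: int = 150,
    seed: int = 0,
    drift_um_s: float = 120.0,
    width_px: int = 320,
    height_px: int = 320,
) -> SceneSpec:
    """Plate-crawling fixture: 7.5 fps, slow body wave, directed drift.

    Worms circle slowly (small heading spread) so they stay in frame for the
    clip durations used in tests.
    """
    rng = np.random.default_rng(seed)
    scene_um = width_px * 5.0
    positions = _spread_positions(n_worms, scene_um, rng)
    worms = []
    for k in range(n_worms):
        heading = rng.uniform(0, 2 * math.pi)
        worms.append(
            WormSpec(
                length_um=700.0,
                width_um=56.0,
                drift_um_s=(
                    drift_um_s * math.cos(heading),
                    drift_um_s * math.sin(heading),
                ),
                freq_hz=0.35,
                kappa0_per_um=0.007,
                wavelength_um=460.0,
                init_pos_um=positions[k],
                heading_rad=heading,
                phase=rng.uniform(0, 2 * math.pi),
            )
        )
    return SceneSpec(
        worms=worms,
        width_px=width_px,
        height_px=height_px,
        frame_rate=7.5,
        n_frames=n_frames,
        seed=seed,
    )


def swim_scene(
    freq_hz: float = 1.0,
    n_frames: int = 420,
    seed: int = 0,
    drift_um_s: tuple[float, float] = (0.0, 0.0),
    n_worms: int = 1,
    width_px: int = 256,
    height_px: int = 256,
) -> SceneSpec:
    """Liquid-thrashing fixture: 14 fps, vigorous symmetric undulation."""
    rng = np.random.default_rng(seed)
    scene_um = width_px * 5.0
    positions = _spread_positions(n_worms, scene_um, rng)
    worms = [
        WormSpec(
            length_um=700.0,
            width_um=56.0,
            drift_um_s=drift_um_s,
            freq_hz=freq_hz,
            kappa0_per_um=0.008,
            wavelength_um=630.0,
            init_pos_um=positions[k],
            heading_rad=rng.uniform(0, 2 * math.pi),
            phase=rng.uniform(0, 2 * math.pi),
        )
        for k in range(n_worms)
    ]
    return SceneSpec(
        worms=worms,
        width_px=width_px,
        height_px=height_px,
        frame_rate=14.0,
        n_frames=n_frames,
        seed=seed,
    )


def collision_scene(n_frames: int = 60, seed: int = 0) -> SceneSpec:
    """Two straight-ish worms crossing head-on mid-video.

    Their paths intersect at the field center, producing a contiguous block
    of overlap frames bracketed by clean tracking on both sides; the
    ground-truth ``collision`` flags mark the exact interval.
    """
    fps = 7.5
    mid_t = 0.5 * n_frames / fps
    speed = 150.0
    cy = 800.0
    worms = [
        WormSpec(
            length_um=600.0,
            width_um=56.0,
            drift_um_s=(speed, 0.0),
            freq_hz=0.0,
            kappa0_per_um=0.0,
            init_pos_um=(800.0 - speed * mid_t, cy),
            heading_rad=0.0,
        ),
        WormSpec(
            length_um=600.0,
            width_um=56.0,
            drift_um_s=(-speed, 0.0),
            freq_hz=0.0,
            kappa0_per_um=0.0,
            init_pos_um=(800.0 + speed * mid_t, cy + 40.0),
            heading_rad=math.pi,
        ),
    ]
    return SceneSpec(
        worms=worms,
        width_px=320,
        height_px=320,
        frame_rate=fps,
        n_frames=n_frames,
        seed=seed,
    )


def curl_scene(
    curl_start: int = 20, curl_end: int = 30, n_frames: int = 60, seed: int = 0
) -> SceneSpec:
    """One undulating worm scripted to curl into a closed loop mid-video."""
    worms = [
        WormSpec(
            length_um=700.0,
            width_um=56.0,
            drift_um_s=(0.0, 0.0),
            freq_hz=0.5,
            kappa0_per_um=0.007,
            wavelength_um=630.0,
            init_pos_um=(800.0, 800.0),
            heading_rad=0.3,
            curl_frames=frozenset(range(curl_start, curl_end)),
        )
    ]
    return SceneSpec(
        worms=worms,
        width_px=320,
        height_px=320,
        frame_rate=7.5,
        n_frames=n_frames,
        seed=seed,
    )
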