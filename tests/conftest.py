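"""Shared synthetic scenes, rendered once per session.

Every fixture is generated programmatically from the serpenoid generator;
no data files are stored.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nematrack.metrics import AnalysisConfig
from nematrack.pipeline import analyze_sequence
from nematrack.synthetic import (
    SceneSpec,
    WormSpec,
    collision_scene,
    curl_scene,
    render_scene,
    swim_scene,
)

DEFAULT_CFG = dict(min_size_px=100, ucf=5.0, min_pct=50, frame_rate=7.5)


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig(**DEFAULT_CFG)


def two_worm_scene(n_frames: int = 40, seed: int = 7) -> SceneSpec:
    """Two well-separated worms that stay interior for the whole clip."""
    worms = [
        WormSpec(
            length_um=600,
            width_um=50,
            drift_um_s=(40, 10),
            freq_hz=0.4,
            kappa0_per_um=0.007,
            wavelength_um=420,
            init_pos_um=(400, 400),
            heading_rad=0.2,
        ),
        WormSpec(
            length_um=600,
            width_um=50,
            drift_um_s=(-30, 20),
            freq_hz=0.4,
            kappa0_per_um=0.007,
            wavelength_um=420,
            init_pos_um=(1100, 1100),
            heading_rad=2.5,
            phase=1.0,
        ),
    ]
    return SceneSpec(
        worms=worms, width_px=320, height_px=320, frame_rate=7.5, n_frames=n_frames, seed=seed
    )


@pytest.fixture(scope="session")
def two_worm_rendered():
    return render_scene(two_worm_scene(), store_masks=True)


@pytest.fixture(scope="session")
def two_worm_analysis(two_worm_rendered, cfg):
    seq, truth = two_worm_rendered
    return analyze_sequence(seq, cfg), truth


@pytest.fixture(scope="session")
def swim_rendered():
    """One worm thrashing at 1 Hz in place, 30 s at 14 fps."""
    return render_scene(swim_scene(freq_hz=1.0, n_frames=420, seed=2))


@pytest.fixture(scope="session")
def swim_analysis(swim_rendered):
    seq, truth = swim_rendered
    cfg = AnalysisConfig(min_size_px=100, ucf=5.0, min_pct=50, frame_rate=14.0)
    return analyze_sequence(seq, cfg), truth, cfg


@pytest.fixture(scope="session")
def collision_rendered():
    return render_scene(collision_scene(n_frames=60))


@pytest.fixture(scope="session")
def collision_analysis(collision_rendered, cfg):
    seq, truth = collision_rendered
    return analyze_sequence(seq, cfg), truth


@pytest.fixture(scope="session")
def curl_rendered():
    return render_scene(curl_scene(curl_start=20, curl_end=30, n_frames=50))


@pytest.fixture(scope="session")
def curl_analysis(curl_rendered):
    seq, truth = curl_rendered
    cfg = AnalysisConfig(min_size_px=100, ucf=5.0, min_pct=40, frame_rate=7.5)
    return analyze_sequence(seq, cfg), truth


@pytest.fixture(scope="session")
def translating_rendered():
    """A straight worm translating at 120 um/s without undulation."""
    heading = 0.5
    spec = WormSpec(
        length_um=700,
        width_um=56,
        drift_um_s=(120 * math.cos(heading), 120 * math.sin(heading)),
        freq_hz=0.0,
        kappa0_per_um=0.0,
        init_pos_um=(300, 300),
        heading_rad=heading,
    )
    scene = SceneSpec(
        worms=[spec], width_px=400, height_px=400, frame_rate=7.5, n_frames=100, seed=3
    )
    return render_scene(scene)


def rect_mask(h: int = 20, w: int = 80, top: int = 8, left: int = 10, rh: int = 5, rw: int = 60):
    mask = np.zeros((h, w), dtype=bool)
    mask[top : top + rh, left : left + rw] = True
    return mask
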