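"""End-to-end analysis runs, tabular export and plots.

``analyze_sequence`` is the in-memory engine (used directly by tests);
``run_analysis`` wraps it with file I/O: per-metric CSVs, a combined XLSX
workbook, metric-vs-time plots, the annotated tracking video and a run
manifest.  Fixed input and configuration give byte-identical tables
regardless of worker count or chunking.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .errors import DegenerateShapeError
from .metrics import AnalysisConfig, MetricsTable, METRIC_UNITS, summarize
from .segmentation import build_background, segment_video
from .skeleton import skeletonize
from .tracking import CollisionEvent, WormTrack, filter_frame_percentage, track_video
from .video_io import FrameSequence, load_video, write_annotated_video

__all__ = ["RunManifest", "AnalysisResult", "analyze_sequence", "run_analysis", "export_tables"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """What a run saw and produced; written for every analysis."""

    input_path: str
    config: dict
    version: str
    n_frames: int
    n_contours: int
    n_tracks_total: int
    n_tracks_kept: int
    n_tracks_filtered: int
    n_collision_events: int
    timings_s: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class AnalysisResult:
    table: MetricsTable
    tracks: list[WormTrack]
    all_tracks: list[WormTrack]
    events: list[CollisionEvent]
    manifest: RunManifest


def analyze_sequence(
    seq: FrameSequence,
    cfg: AnalysisConfig,
    chunk_size: int | None = None,
    workers: int = 1,
    input_path: str = "<in-memory>",
) -> AnalysisResult:
    """Segment, skeletonize, track, censor, filter and summarize."""
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    bg = build_background(seq)
    per_frame_contours = segment_video(
        seq, bg, cfg.min_size_px, chunk_size=chunk_size, workers=workers
    )
    timings["segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    per_frame_skeletons = []
    n_contours = 0
    for frame_obs in per_frame_contours:
        n_contours += len(frame_obs)
        sks = []
        for obs in frame_obs:
            try:
                sks.append(skeletonize(obs))
            except DegenerateShapeError as exc:
                log.info("dropped degenerate contour: %s", exc)
        per_frame_skeletons.append(sks)
    timings["skeletonization"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tracks, events = track_video(per_frame_skeletons)
    kept = filter_frame_percentage(tracks, seq.n_frames, cfg.min_pct)
    timings["tracking"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = summarize(kept, cfg)
    timings["metrics"] = time.perf_counter() - t0

    if not kept:
        log.warning(
            "no track passed the %.0f%% frame-percentage filter (%d candidates)",
            cfg.min_pct,
            len(tracks),
        )
    manifest = RunManifest(
        input_path=str(input_path),
        config=asdict(cfg),
        version=__version__,
        n_frames=seq.n_frames,
        n_contours=n_contours,
        n_tracks_total=len(tracks),
        n_tracks_kept=len(kept),
        n_tracks_filtered=len(tracks) - len(kept),
        n_collision_events=len(events),
        timings_s={k: round(v, 3) for k, v in timings.items()},
    )
    return AnalysisResult(
        table=table, tracks=kept, all_tracks=tracks, events=events, manifest=manifest
    )


def export_tables(table: MetricsTable, out_dir: str | Path) -> list[Path]:
    """One combined workbook (sheet per metric + summary) plus per-metric CSVs.

    Units are stated in the value-column header of every sheet.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    xlsx = out_dir / "metrics.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        for metric, units in METRIC_UNITS.items():
            sub = table.per_frame[table.per_frame["metric"] == metric].drop(
                columns=["metric", "units"]
            )
            sub = sub.rename(columns={"value": f"value ({units})"})
            sub.to_excel(writer, sheet_name=metric[:31], index=False)
            csv = out_dir / f"{metric}.csv"
            sub.to_csv(csv, index=False)
            written.append(csv)
        summary = table.summary.copy()
        summary.to_excel(writer, sheet_name="summary", index=False)
    summary_csv = out_dir / "summary.csv"
    table.summary.to_csv(summary_csv, index=False)
    written.extend([summary_csv, xlsx])
    return written


def plot_metrics(table: MetricsTable, out_dir: str | Path) -> list[Path]:
    """Metric-vs-time line plots, one figure per metric, one line per worm."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for metric, units in METRIC_UNITS.items():
        sub = table.per_frame[table.per_frame["metric"] == metric]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 3.2))
        for worm_id, grp in sub.groupby("worm_id"):
            ax.plot(grp["time_s"], grp["value"], label=f"worm {worm_id}", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"{metric.replace('_', ' ')} ({units})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_analysis(
    video: str | Path,
    cfg: AnalysisConfig,
    out_dir: str | Path,
    chunk_size: int | None = None,
    workers: int = 1,
    frame_rate_override: float | None = None,
    write_video_out: bool = True,
) -> AnalysisResult:
    """Full file-to-files run: tables, plots, annotated video, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq = load_video(video, frame_rate_override=frame_rate_override)
    if abs(seq.frame_rate - cfg.frame_rate) > 1e-9:
        log.info(
            "using container frame rate %.3f fps (config said %.3f)",
            seq.frame_rate,
            cfg.frame_rate,
        )
        cfg = AnalysisConfig(
            min_size_px=cfg.min_size_px,
            ucf=cfg.ucf,
            min_pct=cfg.min_pct,
            frame_rate=seq.frame_rate,
            stroke_point=cfg.stroke_point,
            amplitude_mode=cfg.amplitude_mode,
        )
    result = analyze_sequence(
        seq, cfg, chunk_size=chunk_size, workers=workers, input_path=str(video)
    )
    export_tables(result.table, out_dir)
    plot_metrics(result.table, out_dir / "plots")
    if write_video_out:
        write_annotated_video(
            seq, result.tracks, out_dir / "annotated.tif", events=result.events
        )
    result.manifest.write(out_dir / "manifest.json")
    return result
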