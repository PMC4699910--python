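"""End-to-end pipeline driver: frames (or a path CSV) in, report bundle out.

Stages: segment every frame -> reconstruct the global mm path from the
camera log -> movement features -> cell occupancy and locality -> step
lengths -> power-law tail fit and walk classification.  Users entering
mid-pipeline with an already-reconstructed centroid path skip the imaging
stages; downstream outputs are identical either way.

Each stage writes a plain CSV; the fit is written both as JSON and as a
one-row summary table, and a machine-readable run log records versions,
the configuration and its hash, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .imaging import Frame, SegmentationConfig, segment_frame
from .io import centroids_from_table, segmentation_table
from .metrics import cell_occupancy, locality
from .path import CentroidPath, movement_features, reconstruct_global
from .powerlaw import (
    DivergentFitError,
    InsufficientDataError,
    PowerLawFit,
    fit_steps,
)
from .steps import extract_steps, mean_step_length_series
from .tracker import CameraLog, TrackerConfig, track_stream

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "run_pipeline_on_path",
    "run_virtual_recording",
]


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    path: CentroidPath
    features: object
    occupancy: object
    locality: object
    steps: object
    fit: PowerLawFit | None
    fit_error: str | None
    summary: pd.DataFrame


def _segmentation_config(cfg: PipelineConfig) -> SegmentationConfig:
    return SegmentationConfig(
        sigma=cfg.sigma,
        threshold_ratio=cfg.threshold_ratio,
        window=cfg.window,
        disk_width=cfg.disk_width,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        reject_border=cfg.reject_border,
    )


def run_pipeline(
    frames: list[Frame],
    camera_log: CameraLog,
    config: PipelineConfig | None = None,
    out_dir=None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full pipeline from a frame stack plus camera log."""
    cfg = config or PipelineConfig()
    seg_cfg = _segmentation_config(cfg)
    results = []
    timestamps = []
    for f in frames:
        try:
            _, c = segment_frame(f, seg_cfg)
        except ValueError as exc:
            raise ValueError(f"segmentation failed at frame {f.index}: {exc}") from exc
        results.append((c, 0))
        timestamps.append(f.timestamp)
    seg_table = segmentation_table(results)
    centroids = centroids_from_table(seg_table)
    path = reconstruct_global(
        centroids, camera_log, cfg.calibration, timestamps=timestamps
    )
    res = run_pipeline_on_path(path, cfg, out_dir=None, seed=seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seg_table.to_csv(out / "segmentation.csv", index=False)
        camera_log.to_csv(out / "camera_log.csv")
        _write_bundle(res, cfg, out, seed)
    return res


def run_pipeline_on_path(
    path: CentroidPath,
    config: PipelineConfig | None = None,
    out_dir=None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the analysis stages on an already-reconstructed centroid path."""
    cfg = config or PipelineConfig()
    feats = movement_features(path, delta=cfg.delta)
    occ = cell_occupancy(path, cell_size=cfg.cell_size, interval=cfg.tau)
    loc = locality(feats, occ)
    steps = extract_steps(
        path, dt=cfg.dt, theta=cfg.theta, reference=cfg.heading_reference
    )
    fit: PowerLawFit | None = None
    fit_error: str | None = None
    try:
        fit = fit_steps(
            steps, tail_floor=cfg.tail_floor, window_minutes=cfg.window_minutes
        )
    except (InsufficientDataError, DivergentFitError) as exc:
        fit_error = f"{type(exc).__name__}: {exc}"

    length_min = float(path.t[-1] - path.t[0]) / 60.0 if len(path) else 0.0
    if fit is not None:
        summary = fit.summary_row(length_min=length_min)
    else:
        summary = pd.DataFrame(
            [{"length_min": length_min, "n_step": len(steps), "fit_error": fit_error}]
        )
    res = PipelineResult(path, feats, occ, loc, steps, fit, fit_error, summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_bundle(res, cfg, out, seed)
    return res


def run_virtual_recording(
    renderer,
    tracker_cfg: TrackerConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    seg_interval_s: float = 1.0,
    calibration: float | None = None,
) -> tuple[CentroidPath, CameraLog]:
    """Closed-loop recording of a synthetic world: track, segment, reconstruct.

    Runs the difference-image tracker over the renderer's frame stream
    (camera initially centred on the worm), then segments frames at
    ``seg_interval_s`` spacing under the recorded camera offsets and
    reconstructs the global mm path.  This is the offline analogue of a
    real recording session and feeds the same downstream analysis.
    """
    from .imaging import Centroid

    tracker_cfg = tracker_cfg or TrackerConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    cal = calibration or renderer.world.calibration
    log, _ = track_stream(renderer, tracker_cfg, start_cam=renderer.initial_camera())
    n = renderer.n_frames()
    t = np.array([renderer.timestamp(i) for i in range(n)])
    stride = max(int(round(seg_interval_s / (t[1] - t[0]))), 1) if n > 1 else 1
    chosen = np.arange(0, n, stride)
    centroids: list[Centroid] = []
    for i in chosen:
        frame = renderer.frame(int(i), log.cam_x[i], log.cam_y[i])
        _, c = segment_frame(Frame(frame, index=int(i)), seg_cfg)
        centroids.append(c)
    sub_log = CameraLog(log.frame[chosen], log.cam_x[chosen], log.cam_y[chosen])
    path = reconstruct_global(centroids, sub_log, cal, timestamps=t[chosen])
    return path, log


def _write_bundle(res: PipelineResult, cfg: PipelineConfig, out: Path, seed) -> None:
    res.path.to_csv(out / "path.csv")
    res.features.to_csv(out / "features.csv")
    res.occupancy.to_frame().to_csv(out / "occupancy.csv", index=False)
    res.locality.to_csv(out / "locality.csv")
    res.steps.to_csv(out / "steps.csv")
    mean_step_length_series(res.steps, window=cfg.tau).to_csv(
        out / "mean_step_length.csv", index=False
    )
    if res.fit is not None:
        res.fit.to_json(out / "fit.json")
    res.summary.to_csv(out / "summary.csv", index=False)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    runlog = {
        "wormpath_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
    }
    (out / "runlog.json").write_text(json.dumps(runlog, indent=2))
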