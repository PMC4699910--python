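"""Canonical simulated study conditions for validation experiments.

These fix, in one place, the virtual recording set-up used to validate
the whole pipeline against generators with known ground truth: a
100 x 75 mm arena imaged at 10 px/mm through a 160 x 120 px tracked
camera window, a worm crawling at 0.3 mm/s (a typical off-food speed)
for 20 minutes, small immobile dark artifacts on the plate, tracking at
4 Hz and segmentation at the 1 s step-analysis sampling interval.
"""

from __future__ import annotations

import numpy as np

from .imaging import SegmentationConfig
from .path import CentroidPath
from .pipeline import run_virtual_recording
from .powerlaw import PowerLawFit, fit_steps
from .steps import extract_steps
from .synthetic import TrajectorySpec, WorldRenderer, WorldSpec, simulate_trajectory
from .tracker import TrackerConfig

__all__ = [
    "study_trajectory_spec",
    "study_world",
    "study_tracker_config",
    "study_segmentation_config",
    "record_and_analyze",
    "recover_walk_class",
]

ARENA_MM = (100.0, 75.0)
CALIBRATION = 10.0  # px per mm
FRAME_SHAPE = (120, 160)  # rows, cols
SPEED_MM_S = 0.3
DURATION_S = 1200.0
SIM_DT = 0.25
ARTIFACTS = [(48.0, 36.0, 0.12, 40.0), (52.0, 39.0, 0.10, 35.0), (45.0, 40.0, 0.10, 45.0)]


def study_trajectory_spec(model: str, seed: int, duration_s: float = DURATION_S) -> TrajectorySpec:
    """Trajectory spec under the study conditions (plate-bounded walk)."""
    return TrajectorySpec(
        model=model,
        duration_s=duration_s,
        dt=SIM_DT,
        speed_mm_s=SPEED_MM_S,
        seed=seed,
        start_xy=(50.0, 37.5),
        alpha=2.0,
        xmin_mm=0.3,
        turn_sigma=60.0,
        bounds=(2.0, 2.0, 98.0, 73.0),
    )


def study_world(seed: int, artifacts: list | None = None) -> WorldSpec:
    return WorldSpec(
        arena_mm=ARENA_MM,
        calibration=CALIBRATION,
        seed=seed,
        artifacts=ARTIFACTS if artifacts is None else artifacts,
    )


def study_tracker_config() -> TrackerConfig:
    return TrackerConfig(rate_hz=4.0, sigma=1.5, crop_size=48)


def study_segmentation_config() -> SegmentationConfig:
    # worm is ~10 x 2.5 px at 10 px/mm, so a 15 px window and small area
    # bounds replace the high-magnification defaults
    return SegmentationConfig(sigma=1.0, window=15, min_area=10, max_area=300)


def record_and_analyze(
    model: str, seed: int, duration_s: float = DURATION_S
) -> tuple[CentroidPath, PowerLawFit]:
    """Simulate, render, track, segment, reconstruct, and fit one recording."""
    path, _ = simulate_trajectory(study_trajectory_spec(model, seed, duration_s))
    renderer = WorldRenderer(study_world(seed), path, frame_shape=FRAME_SHAPE)
    rec, _ = run_virtual_recording(
        renderer,
        study_tracker_config(),
        study_segmentation_config(),
        seg_interval_s=1.0,
    )
    steps = extract_steps(rec, dt=1.0, theta=40.0)
    fit = fit_steps(steps, window_minutes=20.0)
    return rec, fit


def recover_walk_class(model: str, seed: int) -> str:
    """Walk class recovered by the full pipeline for one seeded recording."""
    _, fit = record_and_analyze(model, seed)
    return fit.walk_class
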