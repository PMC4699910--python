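"""Global centroid-path reconstruction and movement features.

Per-frame centroids live in camera coordinates; adding the camera offset
recorded for that frame and dividing by the optical calibration
(pixels/mm) gives a position relative to the initial camera position, in
millimetres.  From the calibrated path, windowed finite differences give
the four movement features: speed s_t, acceleration a_t, heading angle
phi_t, and angular speed omega_t:

    s_t   = sqrt((x_t - x_{t-d})^2 + (y_t - y_{t-d})^2) / d
    a_t   = (s_t - s_{t-d}) / d
    phi_t = atan2(y_t - y_{t-d}, x_t - x_{t-d})          (degrees)
    omega_t = wrap(phi_t - phi_{t-d}) / d

where d (``delta``) is the sample interval of the windowed difference.
The heading uses the quadrant-aware two-argument arctangent so that
leftward and rightward motion are distinguishable, and angular
differences are wrapped to (-180, 180] degrees before dividing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import Centroid
from .tracker import CameraLog

__all__ = [
    "CentroidPath",
    "MovementFeatures",
    "wrap_angle",
    "reconstruct_global",
    "movement_features",
]

#: pixels per mm implied by a 1280x960 sensor imaging a ~10 x 7.5 mm field
DEFAULT_CALIBRATION = 128.0


def wrap_angle(deg):
    """Wrap angle differences (degrees) into (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float), 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # keep +180 rather than -180
    return np.where(wrapped == -180.0, 180.0, wrapped)


@dataclass
class CentroidPath:
    """Time-ordered global worm positions in mm.

    ``valid`` marks samples whose segmentation was accepted; invalid
    samples are gaps (their coordinates are NaN) and are never
    interpolated across.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    calibration: float = DEFAULT_CALIBRATION

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("path columns must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x_mm": self.x, "y_mm": self.y, "valid": self.valid.astype(int)}
        )

    def to_csv(self, path) -> None:
        # %.17g guarantees doubles survive the CSV round trip bit-exactly,
        # so entering the pipeline from a path file reproduces in-memory runs
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, calibration: float = DEFAULT_CALIBRATION) -> "CentroidPath":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"t", "x_mm", "y_mm", "valid"} - set(df.columns)
        if missing:
            raise ValueError(f"path CSV missing columns: {sorted(missing)}")
        return cls(
            df["t"].to_numpy(),
            df["x_mm"].to_numpy(),
            df["y_mm"].to_numpy(),
            df["valid"].to_numpy().astype(bool),
            calibration=calibration,
        )


@dataclass
class MovementFeatures:
    """Windowed-difference movement features; NaN where undefined.

    ``angle`` is NaN for zero displacement (heading undefined on a zero
    vector); every feature is defined only where both samples entering its
    difference are valid.
    """

    t: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    angle: np.ndarray
    ang_speed: np.ndarray
    delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "speed": self.speed,
                "accel": self.accel,
                "angle": self.angle,
                "ang_speed": self.ang_speed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def reconstruct_global(
    centroids: Sequence[Centroid],
    log: CameraLog,
    calibration: float = DEFAULT_CALIBRATION,
    timestamps: Sequence[float] | None = None,
    fps: float | None = None,
) -> CentroidPath:
    """Combine per-frame centroids with the camera log into a global mm path.

    ``global = (centroid + camera offset) / calibration``.  Invalid
    centroids become gaps.  Timestamps come either from ``timestamps``
    (one per centroid) or a constant ``fps``.

    Raises ``ValueError`` listing the missing frames when the log lacks an
    entry for some centroid frame.
    """
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    frames = np.array([c.frame_index for c in centroids], dtype=int)
    offsets = {int(f): (cx, cy) for f, cx, cy in zip(log.frame, log.cam_x, log.cam_y)}
    missing = [int(f) for f in frames if int(f) not in offsets]
    if missing:
        raise ValueError(f"camera log missing entries for frames: {missing[:10]}")
    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
    elif fps is not None:
        t = frames / float(fps)
    else:
        t = frames.astype(float)
    x = np.full(len(centroids), np.nan)
    y = np.full(len(centroids), np.nan)
    valid = np.zeros(len(centroids), dtype=bool)
    for i, c in enumerate(centroids):
        if c.valid:
            cx, cy = offsets[int(c.frame_index)]
            x[i] = (c.x + cx) / calibration
            y[i] = (c.y + cy) / calibration
            valid[i] = True
    return CentroidPath(t, x, y, valid, calibration=calibration)


def movement_features(path: CentroidPath, delta: float = 1.0) -> MovementFeatures:
    """Speed, acceleration, heading, and angular speed at window ``delta`` s.

    ``delta`` must be a positive multiple of the path's sampling period.
    Paths shorter than two windows yield empty features.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    n = len(path)
    if n < 2:
        return MovementFeatures(
            np.array([]), np.array([]), np.array([]), np.array([]), np.array([]), delta
        )
    dt = np.diff(path.t)
    period = float(np.median(dt))
    if not np.allclose(dt, period, rtol=1e-6, atol=1e-9):
        raise ValueError("movement features require uniform sampling")
    k = delta / period
    if abs(k - round(k)) > 1e-6:
        raise ValueError(
            f"delta {delta} is not a multiple of the sampling period {period}"
        )
    k = int(round(k))
    if k == 0 or n <= k:
        return MovementFeatures(
            np.array([]), np.array([]), np.array([]), np.array([]), np.array([]), delta
        )

    speed = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    pair_ok = np.zeros(n, dtype=bool)
    dx = path.x[k:] - path.x[:-k]
    dy = path.y[k:] - path.y[:-k]
    ok = path.valid[k:] & path.valid[:-k]
    disp = np.hypot(dx, dy)
    speed[k:] = np.where(ok, disp / delta, np.nan)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(dy, dx))
    ang = np.where(disp > 0, ang, np.nan)
    angle[k:] = np.where(ok, ang, np.nan)
    pair_ok[k:] = ok

    accel = np.full(n, np.nan)
    ang_speed = np.full(n, np.nan)
    both = pair_ok[k:] & pair_ok[:-k]
    accel[k:] = np.where(both, (speed[k:] - speed[:-k]) / delta, np.nan)
    dphi = wrap_angle(angle[k:] - angle[:-k])
    ang_speed[k:] = np.where(both, dphi / delta, np.nan)

    keep = slice(k, n)
    return MovementFeatures(
        path.t[keep], speed[keep], accel[keep], angle[keep], ang_speed[keep], delta
    )
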