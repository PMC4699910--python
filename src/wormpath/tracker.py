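"""Offline difference-image worm localization and virtual re-centering.

The live tracker keeps a moving worm in the camera's field of view: it
subtracts a reference frame (grabbed after the last camera move) from the
current frame so that immobile dark artifacts on the agar (salt
precipitates, air bubbles) cancel to zero, smooths the difference, and
takes the brightest pixel as the worm location.  When that location drifts
too far from the frame centre it moves the camera and records the move in
a per-frame log, from which the global path is later reconstructed.

This module re-implements that loop offline: camera moves are virtual and
instantaneous, applied to a :class:`FrameSource` that can render the view
at any camera offset (e.g. the synthetic world renderer), or ignored for
pre-recorded fixed-camera stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imaging import Frame

__all__ = [
    "CameraLog",
    "TrackerConfig",
    "TrackerState",
    "FrameSource",
    "ArrayFrameSource",
    "difference_locate",
    "track_stream",
]


@dataclass
class CameraLog:
    """Per-frame camera offsets in pixels (one entry per frame, increasing index)."""

    frame: np.ndarray
    cam_x: np.ndarray
    cam_y: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.cam_x = np.asarray(self.cam_x, dtype=float)
        self.cam_y = np.asarray(self.cam_y, dtype=float)
        if not (len(self.frame) == len(self.cam_x) == len(self.cam_y)):
            raise ValueError("camera log columns must have equal length")
        if len(self.frame) and np.any(np.diff(self.frame) <= 0):
            raise ValueError("camera log frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame, "cam_x": self.cam_x, "cam_y": self.cam_y}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CameraLog":
        df = pd.read_csv(path)
        missing = {"frame", "cam_x", "cam_y"} - set(df.columns)
        if missing:
            raise ValueError(f"camera log missing columns: {sorted(missing)}")
        bad = df[["frame", "cam_x", "cam_y"]].isna().any(axis=1)
        if bad.any():
            # +2: 1 for the header line, 1 for 1-based line numbers
            raise ValueError(
                f"camera log has malformed values at line {int(bad.idxmax()) + 2}"
            )
        return cls(df["frame"].to_numpy(), df["cam_x"].to_numpy(), df["cam_y"].to_numpy())


@dataclass
class TrackerConfig:
    """Parameters of the tracking loop.

    rate_hz
        Localization rate; the stream is subsampled so consecutive
        processed frames are at least ``1/rate_hz`` apart, giving the worm
        time to move between compared frames.
    sigma
        Gaussian smoothing of the difference image before the argmax.
    crop_size
        Side of the square search window centred on the previous location;
        active only after the warm-up condition is met.
    recenter_frac
        Re-centre the (virtual) camera when the worm is farther than this
        fraction of the frame width/height from the centre.
    warmup_frames
        Cropping engages only after this many processed frames *and* the
        first camera move.
    polarity
        ``"dark"`` (default): difference is ``max(reference - current, 0)``,
        so only where the scene got *darker* — the worm's new position —
        lights up, and the worm's ghost at its reference-time position is
        clipped away.  ``"abs"``: absolute difference (both light up).
    """

    rate_hz: float = 10.0
    sigma: float = 2.0
    crop_size: int = 128
    recenter_frac: float = 0.25
    warmup_frames: int = 20
    allow_moves: bool = True
    polarity: str = "dark"


@dataclass
class TrackerState:
    """Mutable state of the tracking loop."""

    reference_frame: np.ndarray | None = None
    last_location: tuple[float, float] | None = None
    frames_seen: int = 0
    moved_once: bool = False
    warmup_frames: int = 20

    @property
    def crop_enabled(self) -> bool:
        return self.frames_seen >= self.warmup_frames and self.moved_once


@runtime_checkable
class FrameSource(Protocol):
    """A stream that can render its frames at a given camera offset."""

    def n_frames(self) -> int: ...

    def timestamp(self, index: int) -> float: ...

    def frame(self, index: int, cam_x: float, cam_y: float) -> np.ndarray: ...


class ArrayFrameSource:
    """Wrap a pre-recorded list of frames as a fixed-camera source.

    Camera offsets are ignored (the footage cannot be re-rendered), so use
    ``TrackerConfig(allow_moves=False)`` with this source.
    """

    def __init__(self, frames: list[Frame]):
        if not frames:
            raise ValueError("empty frame stream")
        self._frames = frames

    def n_frames(self) -> int:
        return len(self._frames)

    def timestamp(self, index: int) -> float:
        return self._frames[index].timestamp

    def frame(self, index: int, cam_x: float, cam_y: float) -> np.ndarray:
        return self._frames[index].pixels


def difference_locate(
    current: np.ndarray,
    reference: np.ndarray,
    state: TrackerState,
    sigma: float = 2.0,
    crop_size: int = 128,
    polarity: str = "dark",
) -> tuple[float, float]:
    """Locate the worm as the argmax of the smoothed difference image.

    Immobile artifacts are identical in both frames and cancel exactly;
    only the moving worm survives.  With the default ``"dark"`` polarity
    the difference is ``max(reference - current, 0)``: a dark worm entering
    a region makes it brighter in the difference, while the ghost it leaves
    behind (region getting lighter) is clipped to zero.  When cropping is
    enabled the search is restricted to a ``crop_size`` window centred on
    the last known location.  A difference with no evidence at all
    (identically zero) returns the previous location unchanged.
    """
    cur = np.asarray(current, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if cur.shape != ref.shape:
        raise ValueError(f"frame shape {cur.shape} != reference shape {ref.shape}")
    if polarity == "dark":
        diff = np.maximum(ref - cur, 0.0)
    elif polarity == "abs":
        diff = np.abs(cur - ref)
    else:
        raise ValueError("polarity must be 'dark' or 'abs'")
    h, w = diff.shape
    x0 = y0 = 0
    if state.crop_enabled and state.last_location is not None:
        lx, ly = state.last_location
        half = crop_size // 2
        x0 = int(np.clip(round(lx) - half, 0, max(w - crop_size, 0)))
        y0 = int(np.clip(round(ly) - half, 0, max(h - crop_size, 0)))
        diff = diff[y0 : y0 + crop_size, x0 : x0 + crop_size]
    if not diff.any():
        if state.last_location is not None:
            return state.last_location
        return ((w - 1) / 2.0, (h - 1) / 2.0)
    smooth = ndi.gaussian_filter(diff, sigma=sigma, mode="nearest")
    iy, ix = np.unravel_index(int(np.argmax(smooth)), smooth.shape)
    return (float(ix + x0), float(iy + y0))


def track_stream(
    source: FrameSource | list[Frame],
    cfg: TrackerConfig | None = None,
    start_cam: tuple[float, float] = (0.0, 0.0),
) -> tuple[CameraLog, pd.DataFrame]:
    """Run the tracking loop over a frame stream.

    Subsamples the stream at ``cfg.rate_hz``, localizes the worm by frame
    differencing, and emits a virtual camera move whenever the worm
    estimate drifts beyond ``recenter_frac`` of the frame size from the
    centre; the reference frame is refreshed immediately after each move.

    Returns the camera log (one entry per *stream* frame) and a table of
    per-processed-frame worm locations with columns
    ``frame, t, x, y, global_x, global_y``.
    """
    cfg = cfg or TrackerConfig()
    if isinstance(source, list):
        source = ArrayFrameSource(source)
    n = source.n_frames()
    if n == 0:
        raise ValueError("empty frame stream")

    cam = np.array(start_cam, dtype=float)
    state = TrackerState(warmup_frames=cfg.warmup_frames)
    min_dt = 1.0 / cfg.rate_hz if cfg.rate_hz > 0 else 0.0
    last_t: float | None = None

    log_x = np.empty(n)
    log_y = np.empty(n)
    rows: list[tuple] = []

    for i in range(n):
        t = source.timestamp(i)
        process = last_t is None or (t - last_t) >= min_dt - 1e-9
        if process:
            px = source.frame(i, cam[0], cam[1])
            if state.reference_frame is None:
                state.reference_frame = px
                state.last_location = None
            else:
                loc = difference_locate(
                    px,
                    state.reference_frame,
                    state,
                    cfg.sigma,
                    cfg.crop_size,
                    cfg.polarity,
                )
                h, w = px.shape
                cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
                gx, gy = loc[0] + cam[0], loc[1] + cam[1]
                rows.append((i, t, loc[0], loc[1], gx, gy))
                off_x, off_y = loc[0] - cx, loc[1] - cy
                if cfg.allow_moves and (
                    abs(off_x) > cfg.recenter_frac * w
                    or abs(off_y) > cfg.recenter_frac * h
                ):
                    dx, dy = round(off_x), round(off_y)
                    cam += (dx, dy)
                    state.moved_once = True
                    # fresh reference at the new offset; worm is now centred
                    state.reference_frame = source.frame(i, cam[0], cam[1])
                    state.last_location = (loc[0] - dx, loc[1] - dy)
                else:
                    state.last_location = loc
            state.frames_seen += 1
            last_t = t
        log_x[i], log_y[i] = cam
    log = CameraLog(np.arange(n), log_x, log_y)
    locations = pd.DataFrame(
        rows, columns=["frame", "t", "x", "y", "global_x", "global_y"]
    )
    return log, locations
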