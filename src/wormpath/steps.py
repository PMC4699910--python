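"""Turning-event detection and step-length extraction from a centroid path.

The path is first resampled at a regular interval (Delta t = 1 s by
default).  Walking the sampled path, a *turning event* is declared at a
fix where the heading of the incoming inter-sample segment deviates from
the reference heading established at the previous turning event by more
than a threshold angle Theta (40 degrees by default, chosen because the
head of a straight-crawling worm swings roughly +/-30 degrees).  A *step*
is the straight chord between two consecutive turning events,

    S_j = sqrt((Cx_j - Cx_{j-1})^2 + (Cy_j - Cy_{j-1})^2),

plus a terminal step from the last event to the final sampled point so
the path is fully partitioned.  Curvy crawling produces many short steps;
straight runs produce few long ones — the step-length distribution is the
input to the power-law walk classification.

Gaps in the path (rejected frames) break the sampled path into segments;
turning events and steps never span a break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .path import CentroidPath, wrap_angle

__all__ = [
    "SampledPath",
    "TurningEvent",
    "StepSeries",
    "resample",
    "find_turning_events",
    "step_lengths",
    "extract_steps",
    "mean_step_length_series",
]


@dataclass
class SampledPath:
    """Path resampled on a regular grid; ``segment`` ids separate gap-split runs."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    segment: np.ndarray
    dt: float

    def __len__(self) -> int:
        return len(self.t)

    def segments(self):
        """Yield (t, x, y) arrays for each contiguous gap-free run."""
        for sid in np.unique(self.segment):
            m = self.segment == sid
            yield self.t[m], self.x[m], self.y[m]


@dataclass(frozen=True)
class TurningEvent:
    """A directional-change fix on the sampled path.

    ``heading_prev`` is the reference heading the deviation was measured
    against; ``heading_curr`` the heading of the segment arriving at the
    event.  Both are NaN for the initial event of a segment.
    """

    index: int
    t: float
    x: float
    y: float
    heading_prev: float
    heading_curr: float


@dataclass
class StepSeries:
    """Chord lengths between consecutive turning events."""

    t_start: np.ndarray
    t_end: np.ndarray
    x0: np.ndarray
    y0: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    lengths: np.ndarray
    theta: float = 40.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def n_steps(self) -> int:
        return len(self.lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "j": np.arange(len(self.lengths)),
                "t_start": self.t_start,
                "t_end": self.t_end,
                "x0": self.x0,
                "y0": self.y0,
                "x1": self.x1,
                "y1": self.y1,
                "length_mm": self.lengths,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, theta: float = 40.0, dt: float = 1.0) -> "StepSeries":
        df = pd.read_csv(path)
        missing = {"t_start", "t_end", "x0", "y0", "x1", "y1", "length_mm"} - set(
            df.columns
        )
        if missing:
            raise ValueError(f"steps CSV missing columns: {sorted(missing)}")
        return cls(
            df["t_start"].to_numpy(), df["t_end"].to_numpy(),
            df["x0"].to_numpy(), df["y0"].to_numpy(),
            df["x1"].to_numpy(), df["y1"].to_numpy(),
            df["length_mm"].to_numpy(), theta=theta, dt=dt,
        )


def resample(path: CentroidPath, dt: float = 1.0) -> SampledPath:
    """Resample a path on the grid t_i = t0 + i*dt by nearest valid sample.

    Each grid time takes the valid sample minimizing |t - grid|; a grid
    point with no valid sample within dt/2 is a hole, and holes split the
    output into separate segments (steps never span them).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = path.valid
    if not v.any():
        raise ValueError("path has no valid samples")
    tv, xv, yv = path.t[v], path.x[v], path.y[v]
    t0, t_end = float(path.t[0]), float(path.t[-1])
    if t_end - t0 < 2 * dt:
        raise ValueError("path duration must be at least 2*dt")
    grid = t0 + dt * np.arange(int(np.floor((t_end - t0) / dt)) + 1)
    # nearest valid sample for every grid time
    pos = np.searchsorted(tv, grid)
    pos_lo = np.clip(pos - 1, 0, len(tv) - 1)
    pos_hi = np.clip(pos, 0, len(tv) - 1)
    lo_err = np.abs(grid - tv[pos_lo])
    hi_err = np.abs(tv[pos_hi] - grid)
    pick = np.where(lo_err <= hi_err, pos_lo, pos_hi)
    err = np.minimum(lo_err, hi_err)
    ok = err <= dt / 2 + 1e-9

    seg = np.cumsum(~ok)[ok]  # holes advance the segment id
    return SampledPath(grid[ok], xv[pick[ok]], yv[pick[ok]], seg, dt)


def _heading(dx: float, dy: float) -> float:
    return float(np.degrees(np.arctan2(dy, dx)))


def find_turning_events(
    sampled: SampledPath | tuple,
    theta: float = 40.0,
    reference: str = "outbound",
) -> list[TurningEvent]:
    """Walk one contiguous sampled segment and return its turning events.

    The first fix is always the initial event TE_0.  At each subsequent
    fix i (>= 2) the heading of the segment (i-1 -> i) is compared with
    the reference heading phi_p; when the wrapped difference exceeds
    ``theta`` an event is declared at the vertex fix i-1.  With
    ``reference="outbound"`` (default) phi_p is the heading of the first
    inter-sample segment *after* the previous event, i.e. the direction
    the current step set out in; ``"inbound"`` uses the heading of the
    segment that arrived at the previous event.  Zero-displacement
    segments carry the previous heading forward.

    Multi-segment :class:`SampledPath` inputs must be split first (see
    :func:`extract_steps`); pass a ``(t, x, y)`` tuple for a bare segment.
    """
    if not (0.0 < theta < 180.0):
        raise ValueError("theta must be in (0, 180) degrees")
    if reference not in ("outbound", "inbound"):
        raise ValueError("reference must be 'outbound' or 'inbound'")
    if isinstance(sampled, SampledPath):
        if len(np.unique(sampled.segment)) > 1:
            raise ValueError(
                "sampled path has gap-split segments; use extract_steps "
                "or iterate .segments()"
            )
        t, x, y = sampled.t, sampled.x, sampled.y
    else:
        t, x, y = (np.asarray(a, dtype=float) for a in sampled)

    n = len(t)
    events: list[TurningEvent] = []
    if n == 0:
        return events
    events.append(TurningEvent(0, float(t[0]), float(x[0]), float(y[0]), np.nan, np.nan))
    if n < 3:
        return events

    phi_p = np.nan  # reference heading for the current step
    phi_c = np.nan  # heading of the most recent inter-sample segment
    for i in range(1, n):
        dx, dy = x[i] - x[i - 1], y[i] - y[i - 1]
        prev_c = phi_c
        if dx != 0.0 or dy != 0.0:
            phi_c = _heading(dx, dy)
        if np.isnan(phi_c):
            continue  # still no motion since the segment start
        if np.isnan(phi_p):
            phi_p = phi_c  # first moving segment after the last event
            continue
        if abs(float(wrap_angle(phi_c - phi_p))) > theta:
            j = i - 1  # the vertex where direction changed
            events.append(
                TurningEvent(j, float(t[j]), float(x[j]), float(y[j]), phi_p, phi_c)
            )
            if reference == "outbound":
                phi_p = phi_c  # the deviating segment leads the new step out
            else:
                phi_p = prev_c if not np.isnan(prev_c) else phi_c
    return events


def step_lengths(
    events: list[TurningEvent],
    terminal_point: tuple[float, float] | None = None,
    terminal_time: float | None = None,
    theta: float = 40.0,
    dt: float = 1.0,
) -> StepSeries:
    """Chord lengths between consecutive events, plus the terminal step.

    The terminal step runs from the last event to ``terminal_point`` (the
    final sampled fix) so long final relocations are not dropped; it is
    omitted when the terminal point coincides with the last event and no
    other steps exist, or when no terminal point is given.
    """
    if not events:
        raise ValueError("need at least the initial turning event")
    pts = [(e.x, e.y, e.t) for e in events]
    if terminal_point is not None:
        tx, ty = terminal_point
        tt = terminal_time if terminal_time is not None else events[-1].t
        pts.append((float(tx), float(ty), float(tt)))
    arr = np.array(pts, dtype=float)
    x, y, t = arr[:, 0], arr[:, 1], arr[:, 2]
    lengths = np.hypot(np.diff(x), np.diff(y))
    return StepSeries(
        t[:-1], t[1:], x[:-1], y[:-1], x[1:], y[1:], lengths, theta=theta, dt=dt
    )


def extract_steps(
    path: CentroidPath,
    dt: float = 1.0,
    theta: float = 40.0,
    reference: str = "outbound",
) -> StepSeries:
    """Resample, find turning events, and collect step lengths.

    Gap-split segments are processed independently and concatenated; no
    step spans a gap.
    """
    sampled = resample(path, dt)
    parts: list[StepSeries] = []
    for t, x, y in sampled.segments():
        if len(t) < 2:
            continue
        events = find_turning_events((t, x, y), theta=theta, reference=reference)
        last = events[-1]
        if last.x == x[-1] and last.y == y[-1] and len(events) == 1:
            continue  # single stationary fix: nothing to measure
        terminal = None if (last.x == x[-1] and last.y == y[-1]) else (x[-1], y[-1])
        if terminal is None:
            ss = step_lengths(events, theta=theta, dt=dt)
        else:
            ss = step_lengths(events, terminal, t[-1], theta=theta, dt=dt)
        if len(ss):
            parts.append(ss)
    if not parts:
        return StepSeries(*(np.array([]) for _ in range(7)), theta=theta, dt=dt)
    return StepSeries(
        np.concatenate([p.t_start for p in parts]),
        np.concatenate([p.t_end for p in parts]),
        np.concatenate([p.x0 for p in parts]),
        np.concatenate([p.y0 for p in parts]),
        np.concatenate([p.x1 for p in parts]),
        np.concatenate([p.y1 for p in parts]),
        np.concatenate([p.lengths for p in parts]),
        theta=theta,
        dt=dt,
    )


def mean_step_length_series(
    steps: StepSeries, window: float = 60.0
) -> pd.DataFrame:
    """Mean step length per time window (NaN for windows with no steps).

    A step belongs to the window containing its terminating event time.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(steps) == 0:
        return pd.DataFrame({"t_start": [], "mean_step": [], "n_steps": []})
    t0 = float(steps.t_start.min())
    which = np.floor((steps.t_end - t0) / window).astype(int)
    n_win = int(which.max()) + 1
    mean = np.full(n_win, np.nan)
    count = np.zeros(n_win, dtype=int)
    for k in range(n_win):
        sel = which == k
        count[k] = int(sel.sum())
        if count[k]:
            mean[k] = float(steps.lengths[sel].mean())
    return pd.DataFrame(
        {"t_start": t0 + window * np.arange(n_win), "mean_step": mean, "n_steps": count}
    )
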