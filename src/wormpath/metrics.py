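"""Grid-based search-efficiency metrics: cell occupancy and locality.

The arena is divided into a grid of square cells (1 mm^2 by default,
roughly one adult worm length on a side).  Cell occupancy O_k counts the
unique cells the worm's centroid visits during each time interval tau_k
(1 minute by default); a low count at sustained speed means the worm is
re-searching the same ground.  Locality condenses this into a single
ratio per interval,

    L(tau_k) = E[v_k] / O_k,

the mean instantaneous speed over the interval divided by the cells
visited: high while the animal moves fast but stays in few cells (local,
area-restricted search), low during dispersal (global search).

Visitation is sample-based: a cell crossed between two consecutive
samples without a sample landing in it is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .path import CentroidPath, MovementFeatures

__all__ = ["OccupancySeries", "LocalitySeries", "cell_occupancy", "locality"]


@dataclass
class OccupancySeries:
    """Unique-cell visit counts per interval and cumulatively.

    ``cells`` keeps the per-interval sets of (col, row) cell indices so
    that downstream consumers (and tests) can recover exactly which cells
    were counted.
    """

    interval: np.ndarray          # interval index k
    t_start: np.ndarray           # interval start time, s
    counts: np.ndarray            # O_k
    cumulative_unique: np.ndarray
    cell_size: float
    tau: float
    origin: tuple[float, float]
    cells: list[set] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": self.interval,
                "t_start": self.t_start,
                "O_k": self.counts,
                "cumulative_unique": self.cumulative_unique,
            }
        )


@dataclass
class LocalitySeries:
    """Per-interval locality L_k = E[v_k] / O_k (NaN where undefined)."""

    interval: np.ndarray
    t_start: np.ndarray
    mean_speed: np.ndarray
    counts: np.ndarray
    locality: np.ndarray
    tau: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": self.interval,
                "t_start": self.t_start,
                "O_k": self.counts,
                "mean_speed": self.mean_speed,
                "locality": self.locality,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cell_occupancy(
    path: CentroidPath,
    cell_size: float = 1.0,
    interval: float = 60.0,
    origin: tuple[float, float] | None = None,
) -> OccupancySeries:
    """Count unique grid cells visited per interval and cumulatively.

    The grid is anchored at the floor of the path's minimum valid x, y
    unless an explicit ``origin`` (in mm) is given.  A cell counts as
    visited in interval k iff at least one valid sample falls inside it
    during that interval; intervals are [k*tau, (k+1)*tau) from the first
    sample time.
    """
    if cell_size <= 0 or interval <= 0:
        raise ValueError("cell_size and interval must be positive")
    v = path.valid
    if len(path) == 0 or not v.any():
        return OccupancySeries(
            np.array([], dtype=int), np.array([]), np.array([], dtype=int),
            np.array([], dtype=int), cell_size, interval, (0.0, 0.0), []
        )
    if origin is None:
        origin = (
            float(np.floor(path.x[v].min())),
            float(np.floor(path.y[v].min())),
        )
    t0 = float(path.t[0])
    n_int = int(np.floor((path.t[-1] - t0) / interval)) + 1
    col = np.floor((path.x - origin[0]) / cell_size)
    row = np.floor((path.y - origin[1]) / cell_size)
    which = np.floor((path.t - t0) / interval).astype(int)

    per_interval: list[set] = [set() for _ in range(n_int)]
    for i in np.nonzero(v)[0]:
        per_interval[which[i]].add((int(col[i]), int(row[i])))

    counts = np.array([len(s) for s in per_interval], dtype=int)
    seen: set = set()
    cumulative = np.empty(n_int, dtype=int)
    for k, s in enumerate(per_interval):
        seen |= s
        cumulative[k] = len(seen)
    ks = np.arange(n_int)
    return OccupancySeries(
        ks, t0 + ks * interval, counts, cumulative, cell_size, interval, origin,
        per_interval,
    )


def locality(features: MovementFeatures, occupancy: OccupancySeries) -> LocalitySeries:
    """Locality L_k = mean instantaneous speed over interval k / O_k.

    Speeds are the per-sample instantaneous speeds from
    :func:`wormpath.path.movement_features`; the mean ignores gap (NaN)
    samples.  Intervals with no valid speed samples or O_k = 0 are NaN.
    """
    edges = occupancy.t_start
    tau = occupancy.tau
    mean_speed = np.full(len(edges), np.nan)
    for k, start in enumerate(edges):
        sel = (features.t >= start) & (features.t < start + tau)
        vals = features.speed[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            mean_speed[k] = vals.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        loc = np.where(occupancy.counts > 0, mean_speed / occupancy.counts, np.nan)
    return LocalitySeries(
        occupancy.interval.copy(), edges.copy(), mean_speed,
        occupancy.counts.copy(), loc, tau,
    )
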