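"""Synthetic fixtures: trajectory simulators and a worm-frame renderer.

Every stage of the pipeline is testable without real recordings:

* :func:`simulate_trajectory` produces centroid paths with a known,
  controllable step-length structure — ballistic runs, correlated random
  walks (Brownian-like), Levy walks whose relocation lengths are Pareto
  distributed (clusters of small moves interspersed with rare long
  relocations), and a two-phase local-then-global switch.  The generator
  returns its true relocation segments, so recovered turning events and
  fitted exponents can be checked against ground truth.

* :class:`WorldRenderer` draws the worm as a dark, sinusoid-perturbed
  elongated blob on a noisy lighter background with immobile dark
  artifacts (salt-precipitate/air-bubble stand-ins), either as a fixed
  full-arena view or as a moving camera window over a larger world for
  exercising the tracker.  Per-frame ground-truth blob centroids are
  available in world coordinates.

All randomness is driven by explicit seeds; identical specs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import Frame
from .path import CentroidPath
from .tracker import CameraLog

__all__ = [
    "TrajectorySpec",
    "WorldSpec",
    "SegmentTruth",
    "simulate_trajectory",
    "WorldRenderer",
    "render_frames",
]

MODELS = ("ballistic", "brownian", "levy", "two_phase")


@dataclass
class TrajectorySpec:
    """Parameters of a simulated centroid trajectory.

    model
        ``ballistic`` — constant heading; ``brownian`` — correlated random
        walk with per-step wrapped-normal turns of scale ``turn_sigma``
        deg/sqrt(s); ``levy`` — straight relocation segments with Pareto
        (``alpha``, ``xmin_mm``) lengths and uniform fresh headings;
        ``two_phase`` — local (high-turn) walk until ``switch_time`` s,
        then global (low-turn) walk.
    speed_mm_s
        Crawl speed; 0.3 mm/s is a typical off-food young-adult speed.
    duration_s, dt
        Total simulated time and the output sampling interval.
    bounds
        Optional reflecting box (x0, y0, x1, y1) in mm emulating the
        plate edge; None leaves the walk unbounded.
    """

    model: str = "brownian"
    duration_s: float = 1200.0
    dt: float = 1.0
    speed_mm_s: float = 0.3
    seed: int = 0
    # brownian / two_phase
    turn_sigma: float = 60.0          # deg per sqrt(second)
    local_turn_sigma: float = 150.0   # two_phase, first phase
    global_turn_sigma: float = 12.0   # two_phase, second phase
    switch_time: float = 600.0
    # levy
    alpha: float = 2.0
    xmin_mm: float = 0.3
    levy_jitter: float = 0.0          # within-segment heading jitter, deg/sqrt(s)
    start_xy: tuple[float, float] = (0.0, 0.0)
    bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown trajectory model {self.model!r}; use {MODELS}")
        if self.duration_s <= 0 or self.dt <= 0 or self.speed_mm_s <= 0:
            raise ValueError("duration, dt, and speed must be positive")
        if self.model == "levy" and not (1.0 < self.alpha <= 3.0):
            raise ValueError("levy alpha must be in (1, 3]")
        if self.xmin_mm <= 0:
            raise ValueError("xmin_mm must be positive")


@dataclass(frozen=True)
class SegmentTruth:
    """One true relocation segment of a simulated Levy walk."""

    t_start: float
    length_mm: float
    heading_deg: float
    x0: float
    y0: float


def _reflect(x: float, y: float, heading: float, bounds) -> tuple[float, float, float]:
    """Mirror a position (and heading, degrees) back inside a reflecting box."""
    x0, y0, x1, y1 = bounds
    for _ in range(8):  # a dt-step can cross at most a few walls
        if x < x0:
            x, heading = 2 * x0 - x, 180.0 - heading
        elif x > x1:
            x, heading = 2 * x1 - x, 180.0 - heading
        elif y < y0:
            y, heading = 2 * y0 - y, -heading
        elif y > y1:
            y, heading = 2 * y1 - y, -heading
        else:
            break
    return x, y, heading


def _pareto(rng: np.random.Generator, alpha: float, xmin: float, size=None):
    """Draw from the continuous power law p(x) ~ x^-alpha, x >= xmin."""
    u = rng.random(size)
    return xmin * u ** (-1.0 / (alpha - 1.0))


def simulate_trajectory(
    spec: TrajectorySpec,
) -> tuple[CentroidPath, list[SegmentTruth]]:
    """Integrate the specified movement model at interval ``dt``.

    Returns the sampled path (all samples valid) and, for the ``levy``
    model, the list of true relocation segments; other models return an
    empty truth list.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s / spec.dt)) + 1
    t = spec.dt * np.arange(n)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = spec.start_xy
    step = spec.speed_mm_s * spec.dt
    truth: list[SegmentTruth] = []

    if spec.bounds is not None:
        bx0, by0, bx1, by1 = spec.bounds
        if not (bx0 < bx1 and by0 < by1):
            raise ValueError("bounds must satisfy x0 < x1 and y0 < y1")
        if not (bx0 <= x[0] <= bx1 and by0 <= y[0] <= by1):
            raise ValueError("start_xy must lie inside bounds")

    if spec.model == "ballistic":
        heading = rng.uniform(0.0, 360.0)
        for i in range(1, n):
            x[i] = x[i - 1] + step * np.cos(np.radians(heading))
            y[i] = y[i - 1] + step * np.sin(np.radians(heading))
            if spec.bounds is not None:
                x[i], y[i], heading = _reflect(x[i], y[i], heading, spec.bounds)
    elif spec.model in ("brownian", "two_phase"):
        heading = rng.uniform(0.0, 360.0)
        for i in range(1, n):
            if spec.model == "brownian":
                sigma = spec.turn_sigma
            else:
                sigma = (
                    spec.local_turn_sigma
                    if t[i] <= spec.switch_time
                    else spec.global_turn_sigma
                )
            heading += rng.normal(0.0, sigma * np.sqrt(spec.dt))
            x[i] = x[i - 1] + step * np.cos(np.radians(heading))
            y[i] = y[i - 1] + step * np.sin(np.radians(heading))
            if spec.bounds is not None:
                x[i], y[i], heading = _reflect(x[i], y[i], heading, spec.bounds)
    else:  # levy
        remaining = 0.0
        heading = 0.0
        for i in range(1, n):
            if remaining <= 0.0:
                heading = rng.uniform(0.0, 360.0)
                remaining = float(_pareto(rng, spec.alpha, spec.xmin_mm))
                truth.append(
                    SegmentTruth(t[i - 1], remaining, heading, x[i - 1], y[i - 1])
                )
            if spec.levy_jitter > 0:
                heading += rng.normal(0.0, spec.levy_jitter * np.sqrt(spec.dt))
            advance = min(step, remaining)
            x[i] = x[i - 1] + advance * np.cos(np.radians(heading))
            y[i] = y[i - 1] + advance * np.sin(np.radians(heading))
            if spec.bounds is not None:
                x[i], y[i], heading = _reflect(x[i], y[i], heading, spec.bounds)
            remaining -= step
    path = CentroidPath(t, x, y, np.ones(n, dtype=bool))
    return path, truth


@dataclass
class WorldSpec:
    """Geometry and photometry of the rendered virtual plate.

    Intensities are 8-bit: background ~ N(bg_mean, noise_sigma), the worm
    darker (``worm_intensity``), immobile artifacts darker still.
    ``artifacts`` entries are (x_mm, y_mm, radius_mm, intensity).
    """

    arena_mm: tuple[float, float] = (40.0, 30.0)
    calibration: float = 10.0          # px per mm
    worm_length_mm: float = 1.0
    worm_width_mm: float = 0.25
    wiggle_amp_mm: float = 0.08
    wiggle_freq_hz: float = 0.5
    bg_mean: float = 170.0
    noise_sigma: float = 6.0
    worm_intensity: float = 60.0
    artifacts: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")
        if self.worm_length_mm > min(self.arena_mm):
            raise ValueError("worm must fit inside the arena")

    @property
    def arena_px(self) -> tuple[int, int]:
        w, h = self.arena_mm
        return (int(round(w * self.calibration)), int(round(h * self.calibration)))


class WorldRenderer:
    """Render frames of a worm following ``path`` through the world.

    Implements the tracker's ``FrameSource`` protocol: ``frame(i, cam_x,
    cam_y)`` returns the ``frame_shape`` window whose top-left corner sits
    at world-pixel ``(cam_x, cam_y)``.  Sensor noise is regenerated per
    frame index (deterministically from the world seed), artifacts are
    immobile, and the worm is drawn as a chain of disks along a
    sinusoid-perturbed centreline oriented with the instantaneous heading.
    """

    def __init__(
        self,
        world: WorldSpec,
        path: CentroidPath,
        frame_shape: tuple[int, int] | None = None,
    ):
        self.world = world
        self.path = path
        wpx, hpx = world.arena_px
        self.frame_shape = frame_shape or (hpx, wpx)  # (rows, cols)
        self._headings = self._instantaneous_headings()
        self._check_in_arena()

    # -- geometry ---------------------------------------------------------

    def _instantaneous_headings(self) -> np.ndarray:
        x, y = self.path.x, self.path.y
        h = np.zeros(len(x))
        last = 0.0
        for i in range(len(x)):
            j = min(i + 1, len(x) - 1)
            k = max(i - 1, 0)
            dx, dy = x[j] - x[k], y[j] - y[k]
            if dx != 0 or dy != 0:
                last = np.degrees(np.arctan2(dy, dx))
            h[i] = last
        return h

    def _check_in_arena(self) -> None:
        w, hgt = self.world.arena_mm
        half = self.world.worm_length_mm / 2 + self.world.worm_width_mm
        bad = (
            (self.path.x < half)
            | (self.path.x > w - half)
            | (self.path.y < half)
            | (self.path.y > hgt - half)
        )
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"path exits the arena at t={self.path.t[i]:.3f} s "
                f"(position {self.path.x[i]:.2f}, {self.path.y[i]:.2f} mm)"
            )

    def _worm_pixels(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """World-pixel (rows, cols) covered by the worm body at a frame."""
        w = self.world
        cal = w.calibration
        cx, cy = self.path.x[index] * cal, self.path.y[index] * cal
        theta = np.radians(self._headings[index])
        ux, uy = np.cos(theta), np.sin(theta)
        nx, ny = -uy, ux
        L = w.worm_length_mm * cal
        radius = max(w.worm_width_mm * cal / 2.0, 1.0)
        s = np.linspace(-L / 2, L / 2, 21)
        phase = 2 * np.pi * w.wiggle_freq_hz * self.path.t[index]
        amp = w.wiggle_amp_mm * cal
        off = amp * np.sin(2 * np.pi * s / L + phase)
        px = cx + s * ux + off * nx
        py = cy + s * uy + off * ny
        # local integer grid around the body
        margin = int(np.ceil(radius)) + 1
        x0, x1 = int(np.floor(px.min())) - margin, int(np.ceil(px.max())) + margin
        y0, y1 = int(np.floor(py.min())) - margin, int(np.ceil(py.max())) + margin
        gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        d2 = np.full(gx.shape, np.inf)
        for bx, by in zip(px, py):
            d2 = np.minimum(d2, (gx - bx) ** 2 + (gy - by) ** 2)
        rows, cols = np.nonzero(d2 <= radius * radius)
        return rows + y0, cols + x0

    def initial_camera(self) -> tuple[float, float]:
        """Camera offset that centres the window on the worm at frame 0."""
        gx, gy = self.ground_truth(0)
        h, w = self.frame_shape
        return (round(gx - (w - 1) / 2.0), round(gy - (h - 1) / 2.0))

    def ground_truth(self, index: int) -> tuple[float, float]:
        """World-pixel centroid (x, y) of the worm blob at a frame."""
        rows, cols = self._worm_pixels(index)
        return float(cols.mean()), float(rows.mean())

    def worm_in_view(self, index: int, cam_x: float, cam_y: float, margin: int = 1) -> bool:
        """True when the whole worm body lies inside the camera window."""
        rows, cols = self._worm_pixels(index)
        h, w = self.frame_shape
        return bool(
            (cols.min() - cam_x >= margin)
            and (cols.max() - cam_x < w - margin)
            and (rows.min() - cam_y >= margin)
            and (rows.max() - cam_y < h - margin)
        )

    # -- FrameSource protocol --------------------------------------------

    def n_frames(self) -> int:
        return len(self.path)

    def timestamp(self, index: int) -> float:
        return float(self.path.t[index])

    def frame(self, index: int, cam_x: float = 0.0, cam_y: float = 0.0) -> np.ndarray:
        w = self.world
        h, wd = self.frame_shape
        cam_x, cam_y = int(round(cam_x)), int(round(cam_y))
        rng = np.random.default_rng([w.seed, index])
        img = np.full((h, wd), w.bg_mean, dtype=float)
        if w.noise_sigma > 0:
            img += rng.normal(0.0, w.noise_sigma, size=(h, wd))
        cal = w.calibration
        yy, xx = np.mgrid[0:h, 0:wd]
        for ax, ay, ar, ai in w.artifacts:
            apx, apy, apr = ax * cal - cam_x, ay * cal - cam_y, ar * cal
            if -apr <= apx <= wd + apr and -apr <= apy <= h + apr:
                img[(xx - apx) ** 2 + (yy - apy) ** 2 <= apr * apr] = ai
        rows, cols = self._worm_pixels(index)
        rows, cols = rows - cam_y, cols - cam_x
        keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < wd)
        img[rows[keep], cols[keep]] = w.worm_intensity
        return np.clip(img, 0, 255).astype(np.uint8)


def render_frames(
    world: WorldSpec,
    path: CentroidPath,
    frame_shape: tuple[int, int] | None = None,
    camera_log: CameraLog | None = None,
) -> tuple[list[Frame], CameraLog, pd.DataFrame]:
    """Render a fixed- (or logged-) camera frame stack for a path.

    Returns the frames, the camera log (all-zero offsets unless one is
    supplied), and a ground-truth table ``frame, t, truth_x, truth_y,
    in_view`` with blob centroids in *frame* pixel coordinates.
    """
    r = WorldRenderer(world, path, frame_shape)
    n = r.n_frames()
    if camera_log is None:
        camera_log = CameraLog(np.arange(n), np.zeros(n), np.zeros(n))
    if len(camera_log) != n:
        raise ValueError("camera log length must match the path")
    frames: list[Frame] = []
    rows = []
    for i in range(n):
        cx, cy = float(camera_log.cam_x[i]), float(camera_log.cam_y[i])
        frames.append(Frame(r.frame(i, cx, cy), index=i, timestamp=float(path.t[i])))
        gx, gy = r.ground_truth(i)
        rows.append((i, path.t[i], gx - cx, gy - cy, r.worm_in_view(i, cx, cy)))
    truth = pd.DataFrame(rows, columns=["frame", "t", "truth_x", "truth_y", "in_view"])
    return frames, camera_log, truth
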