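import numpy as np
import pytest

from wormpath import (
    CentroidPath,
    TrajectorySpec,
    WorldSpec,
    render_frames,
    simulate_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """A 40x30 mm arena at 10 px/mm with three small dark artifacts."""
    return WorldSpec(
        arena_mm=(40.0, 30.0),
        calibration=10.0,
        seed=7,
        artifacts=[(5.0, 5.0, 0.15, 40.0), (30.0, 20.0, 0.12, 35.0), (12.0, 25.0, 0.10, 50.0)],
    )


@pytest.fixture(scope="session")
def rendered_scene(small_world):
    """A short Brownian crawl rendered to frames, with ground truth."""
    spec = TrajectorySpec(
        model="brownian",
        duration_s=30.0,
        dt=0.5,
        speed_mm_s=0.3,
        seed=3,
        start_xy=(20.0, 15.0),
    )
    path, _ = simulate_trajectory(spec)
    frames, log, truth = render_frames(small_world, path)
    return path, frames, log, truth


def straight_path(n=61, dt=1.0, speed=0.5, heading_deg=0.0, t0=0.0):
    t = t0 + dt * np.arange(n)
    h = np.radians(heading_deg)
    x = speed * dt * np.arange(n) * np.cos(h)
    y = speed * dt * np.arange(n) * np.sin(h)
    return CentroidPath(t, x, y, np.ones(n, dtype=bool))
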