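"""Pipeline configuration: every stage parameter in one validated record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All stage parameters with their working defaults.

    Segmentation: ``sigma`` (px), ``threshold_ratio`` (on-worm when
    intensity/local mean < ratio), ``window`` (local-mean box, px),
    ``disk_width`` (closing element diameter, px), ``min_area``/
    ``max_area`` (plausible worm area, px^2), ``reject_border``.

    Geometry/time: ``calibration`` (px per mm), ``fps`` (frame rate when
    frames carry no timestamps), ``delta`` (movement-feature window, s),
    ``dt`` (step-analysis sampling interval, s), ``theta`` (turning-event
    threshold, deg), ``heading_reference`` (outbound/inbound),
    ``cell_size`` (mm), ``tau`` (occupancy interval, s), ``tail_floor``
    (minimum tail size for the power-law fit), ``window_minutes``
    (analysis window for the fit; None = whole recording).

    Tracker: ``rate_hz``, ``crop_size``, ``recenter_frac``,
    ``warmup_frames``, ``polarity``.
    """

    sigma: float = 2.0
    threshold_ratio: float = 0.80
    window: int = 25
    disk_width: int = 5
    min_area: int = 50
    max_area: int = 5000
    reject_border: bool = True

    calibration: float = 128.0
    fps: float = 30.0
    delta: float = 1.0
    dt: float = 1.0
    theta: float = 40.0
    heading_reference: str = "outbound"
    cell_size: float = 1.0
    tau: float = 60.0
    tail_floor: int = 10
    window_minutes: float | None = 20.0

    rate_hz: float = 10.0
    crop_size: int = 128
    recenter_frac: float = 0.25
    warmup_frames: int = 20
    polarity: str = "dark"

    def __post_init__(self) -> None:
        positive = {
            "sigma": self.sigma, "calibration": self.calibration, "fps": self.fps,
            "delta": self.delta, "dt": self.dt, "cell_size": self.cell_size,
            "tau": self.tau, "rate_hz": self.rate_hz,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0.0 < self.threshold_ratio < 1.0):
            raise ValueError("threshold_ratio must be in (0, 1)")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.disk_width < 1:
            raise ValueError("disk_width must be >= 1")
        if not (0 <= self.min_area <= self.max_area):
            raise ValueError("need 0 <= min_area <= max_area")
        if not (0.0 < self.theta < 180.0):
            raise ValueError("theta must be in (0, 180) degrees")
        if self.heading_reference not in ("outbound", "inbound"):
            raise ValueError("heading_reference must be 'outbound' or 'inbound'")
        if self.tail_floor < 2:
            raise ValueError("tail_floor must be >= 2")
        if self.window_minutes is not None and self.window_minutes <= 0:
            raise ValueError("window_minutes must be positive or None")
        if self.polarity not in ("dark", "abs"):
            raise ValueError("polarity must be 'dark' or 'abs'")

    # -- (de)serialisation -----------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from JSON or TOML (by extension)."""
        p = Path(path)
        if p.suffix == ".toml":
            import tomllib

            data = tomllib.loads(p.read_text())
        else:
            data = json.loads(p.read_text())
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
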