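"""Reading frame stacks and writing per-frame segmentation tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import Centroid, Frame

__all__ = [
    "load_frame_stack",
    "segmentation_table",
    "centroids_from_table",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to 8-bit grayscale with the usual luma weights."""
    a = np.asarray(arr)
    if a.ndim == 3:
        a = a[..., :3] @ np.array([0.299, 0.587, 0.114])
    if a.dtype != np.uint8:
        a = np.clip(a, 0, 255).astype(np.uint8)
    return a


def load_frame_stack(source, fps: float = 30.0) -> list[Frame]:
    """Load frames from a directory of images or an AVI/movie file.

    Directory entries are sorted by name; timestamps are assigned at the
    given ``fps``.  Movie decoding goes through imageio and is only
    available when a suitable plugin/codec is installed.
    """
    import imageio.v3 as iio

    p = Path(source)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no image frames found in {p}")
        return [
            Frame(_to_gray(iio.imread(f)), index=i, timestamp=i / fps)
            for i, f in enumerate(files)
        ]
    if not p.exists():
        raise ValueError(f"no such frame source: {p}")
    frames = []
    for i, arr in enumerate(iio.imiter(p)):
        frames.append(Frame(_to_gray(arr), index=i, timestamp=i / fps))
    if not frames:
        raise ValueError(f"no frames decoded from {p}")
    return frames


def segmentation_table(results: list[tuple[Centroid, int]]) -> pd.DataFrame:
    """Per-frame segmentation output: ``frame, cx, cy, area, valid``."""
    return pd.DataFrame(
        [
            {
                "frame": c.frame_index,
                "cx": c.x,
                "cy": c.y,
                "area": area,
                "valid": int(c.valid),
            }
            for c, area in results
        ]
    )


def centroids_from_table(df: pd.DataFrame) -> list[Centroid]:
    """Rebuild Centroid records from a segmentation table."""
    missing = {"frame", "cx", "cy", "valid"} - set(df.columns)
    if missing:
        raise ValueError(f"segmentation table missing columns: {sorted(missing)}")
    return [
        Centroid(row.cx, row.cy, int(row.frame), bool(row.valid))
        for row in df.itertuples()
    ]
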