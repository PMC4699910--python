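"""Segmentation primitives against brute-force oracles and rendered truth."""

import numpy as np
import pytest

from wormpath import (
    Centroid,
    Frame,
    SegmentationConfig,
    adaptive_threshold,
    centroid,
    close_mask,
    gaussian_smooth,
    largest_component,
    segment_frame,
)
from wormpath.imaging import _disk


# ---------------------------------------------------------------- oracles

def windowed_mean_oracle(img, window):
    """Double-loop local mean over the window/image intersection."""
    h, w = img.shape
    r = window // 2
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            patch = img[max(i - r, 0) : i + r + 1, max(j - r, 0) : j + r + 1]
            out[i, j] = patch.mean()
    return out


def closing_oracle(mask, disk_width):
    """Set-operation dilation then erosion with explicit padding."""
    se = _disk(disk_width)
    r = disk_width // 2
    pad = disk_width
    p = np.pad(mask, pad)
    h, w = p.shape
    offs = [(dy - r, dx - r) for dy in range(se.shape[0]) for dx in range(se.shape[1]) if se[dy, dx]]
    dil = np.zeros_like(p)
    for i in range(h):
        for j in range(w):
            dil[i, j] = any(
                0 <= i + dy < h and 0 <= j + dx < w and p[i + dy, j + dx]
                for dy, dx in offs
            )
    ero = np.zeros_like(p)
    for i in range(h):
        for j in range(w):
            ero[i, j] = all(
                0 <= i + dy < h and 0 <= j + dx < w and dil[i + dy, j + dx]
                for dy, dx in offs
            )
    return ero[pad:-pad, pad:-pad]


def flood_fill_components(mask):
    """8-connected component labelling by explicit flood fill."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    cur = 0
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and labels[si, sj] == 0:
                cur += 1
                stack = [(si, sj)]
                labels[si, sj] = cur
                while stack:
                    i, j = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and labels[ni, nj] == 0:
                                labels[ni, nj] = cur
                                stack.append((ni, nj))
    return labels, cur


# ---------------------------------------------------------------- smoothing

def test_gaussian_smooth_preserves_constant_frames():
    frame = np.full((20, 20), 137, dtype=np.uint8)
    out = gaussian_smooth(frame, sigma=3.0)
    assert np.allclose(out, 137.0)


def test_gaussian_smooth_spreads_point_source_symmetrically():
    frame = np.zeros((21, 21))
    frame[10, 10] = 255
    out = gaussian_smooth(frame, sigma=1.0)
    assert np.unravel_index(np.argmax(out), out.shape) == (10, 10)
    assert out[10, 10] < 255  # mass spread out
    assert np.isclose(out[10, 8], out[10, 12]) and np.isclose(out[8, 10], out[12, 10])


def test_gaussian_smooth_matches_direct_convolution(rng):
    frame = rng.integers(0, 256, size=(32, 32)).astype(float)
    sigma = 2.0
    out = gaussian_smooth(frame, sigma)
    # truncated-kernel convolution oracle (interior only, away from borders)
    r = int(4 * sigma)
    ax = np.arange(-r, r + 1)
    k = np.exp(-(ax**2) / (2 * sigma**2))
    k2 = np.outer(k, k) / np.outer(k, k).sum()
    for i, j in [(16, 16), (12, 20), (20, 12)]:
        direct = float((frame[i - r : i + r + 1, j - r : j + r + 1] * k2).sum())
        assert out[i, j] == pytest.approx(direct, rel=1e-3)


def test_gaussian_smooth_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        gaussian_smooth(np.zeros((5, 5)), sigma=0.0)


# ---------------------------------------------------------------- threshold

def test_adaptive_threshold_marks_dark_pixel_below_ratio():
    # pixel of 70 in a neighbourhood averaging ~100: ratio 0.7 < 0.8 -> on
    img = np.full((15, 15), 100.0)
    img[7, 7] = 70.0
    mask = adaptive_threshold(img, window=15, ratio=0.80)
    assert mask[7, 7]


def test_adaptive_threshold_empty_on_uniform_frame():
    img = np.full((20, 20), 150.0)
    assert not adaptive_threshold(img, window=5, ratio=0.80).any()


def test_adaptive_threshold_matches_windowed_mean_oracle(rng):
    for _ in range(5):
        img = rng.integers(60, 200, size=(18, 22)).astype(float)
        img[5:9, 5:12] = rng.integers(10, 50, size=(4, 7))  # dark blob
        for window in (3, 5, 9):
            got = adaptive_threshold(img, window=window, ratio=0.80)
            want = img < 0.80 * windowed_mean_oracle(img, window)
            assert np.array_equal(got, want)


def test_adaptive_threshold_rejects_oversized_window():
    with pytest.raises(ValueError):
        adaptive_threshold(np.zeros((10, 10)) + 1, window=21, ratio=0.8)


# ---------------------------------------------------------------- closing

def test_close_mask_leaves_solid_rectangle_unchanged():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5:15, 4:16] = True
    assert np.array_equal(close_mask(mask, 5), mask)


def test_close_mask_fills_small_hole_in_annulus():
    mask = np.zeros((21, 21), dtype=bool)
    mask[7:14, 7:14] = True
    mask[9:12, 9:12] = False  # 3x3 hole, smaller than the disk
    closed = close_mask(mask, 5)
    assert closed[10, 10]
    assert closed[9:12, 9:12].all()


def test_close_mask_matches_set_operation_oracle(rng):
    for _ in range(5):
        mask = rng.random((16, 16)) < 0.45
        for dw in (3, 5):
            assert np.array_equal(close_mask(mask, dw), closing_oracle(mask, dw))


def test_close_mask_is_idempotent(rng):
    for _ in range(10):
        mask = rng.random((24, 24)) < 0.4
        once = close_mask(mask, 5)
        assert np.array_equal(close_mask(once, 5), once)


# ---------------------------------------------------------------- components

def test_largest_component_keeps_strict_maximum():
    mask = np.zeros((30, 30), dtype=bool)
    mask[2:14, 2:12] = True  # 120 px
    mask[20:21, 20:27] = True  # 7 px
    out = largest_component(mask)
    assert out[5, 5] and not out[20, 22]
    assert out.sum() == 120


def test_largest_component_empty_input_gives_empty_output():
    mask = np.zeros((5, 5), dtype=bool)
    assert not largest_component(mask).any()


def test_largest_component_agrees_with_flood_fill_oracle(rng):
    for _ in range(10):
        mask = rng.random((20, 20)) < 0.3
        out = largest_component(mask)
        labels, n = flood_fill_components(mask)
        if n == 0:
            assert not out.any()
            continue
        sizes = [(labels == k).sum() for k in range(1, n + 1)]
        assert out.sum() == max(sizes)
        # output is exactly one oracle component
        covered = set(labels[out])
        assert len(covered) == 1


# ---------------------------------------------------------------- centroid

def test_centroid_of_single_pixel():
    mask = np.zeros((10, 10), dtype=bool)
    mask[5, 3] = True  # row y=5, col x=3
    c = centroid(mask)
    assert (c.x, c.y, c.valid) == (3.0, 5.0, True)


def test_centroid_of_square_block_is_its_center():
    mask = np.zeros((8, 8), dtype=bool)
    mask[0:2, 0:2] = True
    c = centroid(mask)
    assert (c.x, c.y) == (0.5, 0.5)


def test_centroid_empty_mask_is_invalid_not_crash():
    c = centroid(np.zeros((6, 6), dtype=bool))
    assert not c.valid and np.isnan(c.x)


def test_centroid_matches_brute_force_on_random_masks(rng):
    for _ in range(100):
        mask = rng.random((16, 16)) < 0.3
        c = centroid(mask)
        xs, ys = [], []
        for i in range(16):
            for j in range(16):
                if mask[i, j]:
                    xs.append(j)
                    ys.append(i)
        if not xs:
            assert not c.valid
        else:
            assert c.x == pytest.approx(np.mean(xs))
            assert c.y == pytest.approx(np.mean(ys))


# ---------------------------------------------------------------- pipeline

def test_segment_frame_recovers_rendered_worm(rendered_scene):
    _, frames, _, truth = rendered_scene
    cfg = SegmentationConfig(sigma=1.0, window=15, min_area=10, max_area=300)
    errs = []
    for f, row in zip(frames, truth.itertuples()):
        _, c = segment_frame(f, cfg)
        assert c.valid
        errs.append(np.hypot(c.x - row.truth_x, c.y - row.truth_y))
    assert np.median(errs) < 0.5
    assert max(errs) < 1.0


def test_segment_frame_invalid_on_background_only(small_world):
    import numpy as np

    rng = np.random.default_rng(0)
    frame = np.clip(rng.normal(170, 6, size=(60, 80)), 0, 255).astype(np.uint8)
    cfg = SegmentationConfig(sigma=1.0, window=15, min_area=10, max_area=300)
    _, c = segment_frame(frame, cfg)
    assert not c.valid


def test_segment_frame_ignores_small_artifacts(rendered_scene):
    # the rendered scene contains three dark artifacts; the worm component
    # is larger, so artifacts never win largest_component
    _, frames, _, truth = rendered_scene
    cfg = SegmentationConfig(sigma=1.0, window=15, min_area=10, max_area=300)
    f, row = frames[0], next(truth.itertuples())
    _, c = segment_frame(f, cfg)
    assert np.hypot(c.x - row.truth_x, c.y - row.truth_y) < 1.0
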