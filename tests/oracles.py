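"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_surface_points(data: np.ndarray, spacing) -> np.ndarray:
    """Surface voxel centers by explicit 6-neighbour inspection."""
    fg = np.asarray(data, bool)
    pts = []
    for i, j, k in np.argwhere(fg):
        on_surface = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < fg.shape[0] and 0 <= nj < fg.shape[1] and 0 <= nk < fg.shape[2]):
                on_surface = True  # grid border counts as background
            elif not fg[ni, nj, nk]:
                on_surface = True
        if on_surface:
            pts.append((i, j, k))
    return np.asarray(pts, dtype=float) * np.asarray(spacing)


def brute_pooled_distances(a: np.ndarray, b: np.ndarray, spacing) -> np.ndarray:
    """All-pairs nearest-neighbour surface distances, pooled both ways."""
    pa = brute_surface_points(a, spacing)
    pb = brute_surface_points(b, spacing)
    d = cdist(pa, pb)
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


def brute_asd(a, b, spacing) -> float:
    return float(brute_pooled_distances(a, b, spacing).mean())


def brute_hd95(a, b, spacing) -> float:
    return float(np.percentile(brute_pooled_distances(a, b, spacing), 95))


def brute_dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if not a.any() and not b.any():
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def brute_erode_box(data: np.ndarray) -> np.ndarray:
    """3x3x3 box erosion by explicit neighbourhood check."""
    fg = np.asarray(data, bool)
    out = np.zeros_like(fg)
    for i, j, k in np.argwhere(fg):
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < fg.shape[0] and 0 <= nj < fg.shape[1]
                            and 0 <= nk < fg.shape[2]) or not fg[ni, nj, nk]:
                        ok = False
        out[i, j, k] = ok
    return out
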