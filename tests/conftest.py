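"""Shared fixtures and independent oracles.

The oracles here deliberately take different computational routes from
the library: density counting via full pairwise distance matrices
(against the library's windowed stamping), and circle dice via
rasterized boolean masks (against the analytic lens formula).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.spatial.distance import cdist

from budscan.core import Circle, SlideGeometry

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def brute_force_density(
    points: np.ndarray, geometry: SlideGeometry, radius_um: float
) -> np.ndarray:
    """Per-cell in-disk counts via an explicit distance matrix."""
    rows, cols = geometry.shape
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    counts = np.zeros((rows, cols), dtype=np.int32)
    if pts.shape[0] == 0:
        return counts
    xs = geometry.col_centers()
    ys = geometry.row_centers()
    chunk = max(1, 2_000_000 // max(1, cols * max(1, pts.shape[0])))
    for i0 in range(0, rows, chunk):
        yy = ys[i0 : i0 + chunk]
        centers = np.stack(
            [
                np.broadcast_to(xs, (len(yy), cols)),
                np.broadcast_to(yy[:, None], (len(yy), cols)),
            ],
            axis=-1,
        ).reshape(-1, 2)
        d = cdist(centers, pts)
        counts[i0 : i0 + len(yy), :] = (d <= radius_um).sum(axis=1).reshape(len(yy), cols)
    return counts


def raster_dice(a: Circle, b: Circle, spacing_um: float = 1.0) -> float:
    """Dice of two disks measured on a rasterized pixel grid."""
    x0 = min(a.cx - a.radius, b.cx - b.radius) - spacing_um
    x1 = max(a.cx + a.radius, b.cx + b.radius) + spacing_um
    y0 = min(a.cy - a.radius, b.cy - b.radius) - spacing_um
    y1 = max(a.cy + a.radius, b.cy + b.radius) + spacing_um
    xs = np.arange(x0, x1, spacing_um) + spacing_um / 2
    ys = np.arange(y0, y1, spacing_um) + spacing_um / 2
    xx, yy = np.meshgrid(xs, ys)
    in_a = (xx - a.cx) ** 2 + (yy - a.cy) ** 2 <= a.radius**2
    in_b = (xx - b.cx) ** 2 + (yy - b.cy) ** 2 <= b.radius**2
    denom = in_a.sum() + in_b.sum()
    return 2.0 * np.logical_and(in_a, in_b).sum() / denom if denom else 0.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
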