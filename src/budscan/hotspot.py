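"""Hotspot extraction from density maps and dice-based hotspot matching.

Hotspots are selected greedily: take the raster cell with the highest
in-disk bud count as the next hotspot center, zero every cell within one
disk radius of it, and repeat until ten hotspots are found or the map is
exhausted.  Zeroing within one radius guarantees successive centers are
at least one radius apart, bounding the pairwise overlap of reported
hotspot fields.

An automatic hotspot matches a manual one when the dice overlap of the
two circular fields reaches 0.7.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Circle, Detection, circle_dice, point_in_circle
from .density import DensityMap, compute_density

__all__ = [
    "HotspotSource",
    "Hotspot",
    "HotspotMatchReport",
    "select_hotspots",
    "count_in_circle",
    "match_hotspots",
]

DEFAULT_N_HOTSPOTS = 10
DEFAULT_DICE_THRESHOLD = 0.7


class HotspotSource(str, enum.Enum):
    AUTO = "AUTO"
    MANUAL = "MANUAL"


@dataclass(frozen=True)
class Hotspot:
    """A circular hotspot field with its bud count and selection rank."""

    circle: Circle
    count: int
    rank: int
    source: HotspotSource = HotspotSource.AUTO

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("hotspot count must be non-negative")
        if self.rank < 1:
            raise ValueError("rank starts at 1")


@dataclass(frozen=True)
class HotspotMatchReport:
    """Outcome of matching one manual hotspot against ranked auto hotspots.

    ``best_rank`` is the lowest rank whose dice with the manual circle
    reaches the threshold (None if no rank does); ``best_dice`` is the
    dice at that rank, or the maximum dice observed when nothing matched.
    """

    best_rank: int | None
    best_dice: float
    top3_match: bool
    top10_match: bool
    no_match: bool
    slide_id: str | None = None

    def __post_init__(self) -> None:
        if self.top3_match and not self.top10_match:
            raise ValueError("top3_match implies top10_match")
        if self.top10_match == self.no_match:
            raise ValueError("exactly one of top10_match / no_match must hold")


def select_hotspots(
    dmap: DensityMap,
    k: int = DEFAULT_N_HOTSPOTS,
    radius_um: float | None = None,
    suppression: str = "zero",
    detections: Sequence[Detection] | None = None,
) -> list[Hotspot]:
    """Greedy iterative hotspot selection with overlap suppression.

    Parameters
    ----------
    dmap:
        Density map computed with the same disk radius.
    k:
        Maximum number of hotspots (default 10).  Fewer are returned,
        with a warning, when the density is exhausted first.
    radius_um:
        Suppression/field radius; defaults to the map's own radius.
    suppression:
        ``"zero"`` (default): zero the count grid within one radius of
        each chosen center.  ``"recount"``: remove the buds inside the
        chosen field and recompute the map (requires ``detections``).

    Returns
    -------
    list of Hotspot ordered by rank; centers lie on raster cell centers
    and successive centers are at least one radius apart.

    Notes
    -----
    Argmax ties break to the smallest row-major cell index, which makes
    the selection deterministic across platforms.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if suppression not in ("zero", "recount"):
        raise ValueError(f"unknown suppression mode {suppression!r}")
    if suppression == "recount" and detections is None:
        raise ValueError("recount suppression requires the detection list")
    radius = float(radius_um if radius_um is not None else dmap.radius_um)
    geom = dmap.geometry
    s = geom.spacing_um
    work = dmap.counts.astype(np.int64, copy=True)
    remaining = list(detections) if detections is not None else None

    hotspots: list[Hotspot] = []
    for rank in range(1, k + 1):
        flat = int(np.argmax(work))  # first occurrence = row-major tie-break
        count = int(work.flat[flat])
        if count <= 0:
            warnings.warn(
                f"density exhausted after {len(hotspots)} hotspots (requested {k})",
                stacklevel=2,
            )
            break
        i, j = divmod(flat, work.shape[1])
        cx, cy = geom.pixel_center(i, j)
        circle = Circle(cx, cy, radius)
        hotspots.append(Hotspot(circle=circle, count=count, rank=rank))
        if suppression == "zero":
            _zero_disk(work, geom, cx, cy, radius)
        else:
            remaining = [
                d for d in remaining if not point_in_circle((d.x, d.y), circle)
            ]
            work = compute_density(
                remaining, geom, radius_um=dmap.radius_um
            ).counts.astype(np.int64)
    return hotspots


def _zero_disk(
    grid: np.ndarray, geom, cx: float, cy: float, radius: float
) -> None:
    """Zero all cells whose centers lie within ``radius`` of (cx, cy)."""
    s = geom.spacing_um
    x = cx - geom.origin_x_um
    y = cy - geom.origin_y_um
    rows, cols = grid.shape
    j0 = max(0, int(np.ceil((x - radius) / s - 0.5 - 1e-9)))
    j1 = min(cols - 1, int(np.floor((x + radius) / s - 0.5 + 1e-9)))
    i0 = max(0, int(np.ceil((y - radius) / s - 0.5 - 1e-9)))
    i1 = min(rows - 1, int(np.floor((y + radius) / s - 0.5 + 1e-9)))
    if j1 < j0 or i1 < i0:
        return
    ccx = (np.arange(j0, j1 + 1) + 0.5) * s - x
    ccy = (np.arange(i0, i1 + 1) + 0.5) * s - y
    inside = (ccy[:, None] ** 2 + ccx[None, :] ** 2) <= radius * radius
    sub = grid[i0 : i1 + 1, j0 : j1 + 1]
    sub[inside] = 0


def count_in_circle(
    detections: Sequence[Detection], circle: Circle
) -> int:
    """Number of the given detections inside (or on) the circle.

    Callers select which detections count as buds (cf. the ``tb_only``
    flag of :func:`budscan.density.compute_density`).
    """
    return sum(1 for d in detections if point_in_circle((d.x, d.y), circle))


def match_hotspots(
    manual: Hotspot,
    auto: Sequence[Hotspot],
    dice_threshold: float = DEFAULT_DICE_THRESHOLD,
    slide_id: str | None = None,
) -> HotspotMatchReport:
    """Match a manual hotspot against rank-ordered automatic hotspots.

    The best match is the lowest-rank automatic hotspot whose circle
    dice with the manual field reaches ``dice_threshold``; the report
    flags whether that rank falls in the top 3, the top 10, or nowhere.
    """
    if not (0.0 < dice_threshold <= 1.0):
        raise ValueError("dice_threshold must be in (0, 1]")
    ordered = sorted(auto, key=lambda h: h.rank)
    best_rank: int | None = None
    best_dice = 0.0
    max_dice = 0.0
    for h in ordered:
        d = circle_dice(manual.circle, h.circle)
        max_dice = max(max_dice, d)
        if d >= dice_threshold:
            best_rank = h.rank
            best_dice = d
            break
    matched = best_rank is not None
    return HotspotMatchReport(
        best_rank=best_rank,
        best_dice=best_dice if matched else max_dice,
        top3_match=matched and best_rank <= 3,
        top10_match=matched and best_rank <= 10,
        no_match=not (matched and best_rank <= 10),
        slide_id=slide_id,
    )
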