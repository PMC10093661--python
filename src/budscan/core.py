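"""Shared domain types, coordinate conventions and circle geometry.

All physical coordinates are expressed in micrometers in the slide frame:
x grows rightward, y grows downward, and the slide origin is the top-left
corner of the scanned area.  The tumor-budding hotspot is a circular field
of radius 0.5 mm (area 0.785 mm**2), so the default radius throughout the
package is ``DEFAULT_HOTSPOT_RADIUS_UM`` = 500.

Raster grids (density maps, stain masks) follow the pixel-center
convention: the raster cell at (row i, col j) represents the physical
point ``origin + ((j + 0.5) * spacing, (i + 0.5) * spacing)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_HOTSPOT_RADIUS_UM",
    "Label",
    "Source",
    "Detection",
    "SlideGeometry",
    "Circle",
    "disk_area",
    "point_in_circle",
    "circle_dice",
    "detections_to_array",
]

#: Default hotspot radius in micrometers (0.5 mm circular field).
DEFAULT_HOTSPOT_RADIUS_UM: float = 500.0


class Label(str, enum.Enum):
    """Object class of a candidate: tumor bud, non-bud, or not yet labeled."""

    TB = "TB"
    NON_TB = "NON_TB"
    UNLABELED = "UNLABELED"


class Source(str, enum.Enum):
    """Provenance of a detection record."""

    MANUAL = "MANUAL"
    PSEUDO = "PSEUDO"
    DETECTOR = "DETECTOR"


@dataclass(frozen=True)
class Detection:
    """A single candidate object on a slide.

    Parameters
    ----------
    x, y:
        Position in micrometers, slide frame.
    likelihood:
        Model confidence in [0, 1] that the object is a tumor bud;
        ``None`` when no model score exists (e.g. manual annotations).
    label:
        TB / NON_TB / UNLABELED.
    certainty:
        Supervision weight in [0, 1] (1.0 for manual labels, 0.8 for
        accepted pseudo-labels); ``None`` before weighting.
    source:
        MANUAL, PSEUDO or DETECTOR.
    """

    x: float
    y: float
    likelihood: float | None = None
    label: Label = Label.UNLABELED
    certainty: float | None = None
    source: Source = Source.DETECTOR

    def __post_init__(self) -> None:
        if self.likelihood is not None and not (0.0 <= self.likelihood <= 1.0):
            raise ValueError(f"likelihood must be in [0, 1], got {self.likelihood}")
        if self.certainty is not None and not (0.0 <= self.certainty <= 1.0):
            raise ValueError(f"certainty must be in [0, 1], got {self.certainty}")
        if self.source is Source.MANUAL and self.label is Label.UNLABELED:
            raise ValueError("MANUAL detections must carry a TB or NON_TB label")


@dataclass(frozen=True)
class SlideGeometry:
    """Raster geometry of a slide-aligned grid.

    ``spacing_um`` is the physical side length of one raster cell.  The
    grid covers ``[origin_x, origin_x + width_um] x [origin_y, origin_y +
    height_um]``; cell (i, j) has its center at
    ``(origin_x + (j + 0.5) * spacing_um, origin_y + (i + 0.5) * spacing_um)``.
    """

    width_um: float
    height_um: float
    spacing_um: float
    origin_x_um: float = 0.0
    origin_y_um: float = 0.0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("slide width and height must be positive")
        if self.spacing_um <= 0:
            raise ValueError("raster spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the raster covering the geometry."""
        rows = max(1, int(math.ceil(self.height_um / self.spacing_um - 1e-9)))
        cols = max(1, int(math.ceil(self.width_um / self.spacing_um - 1e-9)))
        return rows, cols

    def pixel_center(self, i: int, j: int) -> tuple[float, float]:
        s = self.spacing_um
        return (self.origin_x_um + (j + 0.5) * s, self.origin_y_um + (i + 0.5) * s)

    def col_centers(self) -> np.ndarray:
        _, cols = self.shape
        return self.origin_x_um + (np.arange(cols) + 0.5) * self.spacing_um

    def row_centers(self) -> np.ndarray:
        rows, _ = self.shape
        return self.origin_y_um + (np.arange(rows) + 0.5) * self.spacing_um

    @classmethod
    def from_points(
        cls,
        points: np.ndarray | Sequence[tuple[float, float]],
        spacing_um: float,
        pad_um: float = DEFAULT_HOTSPOT_RADIUS_UM,
    ) -> "SlideGeometry":
        """Bounding-box geometry of a point set, padded on every side.

        The pad defaults to one hotspot radius so a disk centered on any
        point lies fully inside the raster.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if pts.size == 0:
            raise ValueError("cannot derive a geometry from an empty point set")
        x0, y0 = pts.min(axis=0) - pad_um
        x1, y1 = pts.max(axis=0) + pad_um
        width = max(x1 - x0, spacing_um)
        height = max(y1 - y0, spacing_um)
        return cls(width, height, spacing_um, origin_x_um=x0, origin_y_um=y0)


@dataclass(frozen=True)
class Circle:
    """A circle in slide coordinates (micrometers)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


def disk_area(radius_um: float) -> float:
    """Area in mm**2 of a disk with the given radius in micrometers.

    The ITBCC hotspot (radius 500 um) has area pi * 0.5**2 = 0.785 mm**2.
    """
    if radius_um <= 0:
        raise ValueError(f"radius must be positive, got {radius_um}")
    return math.pi * (radius_um / 1000.0) ** 2


def point_in_circle(p: tuple[float, float], c: Circle) -> bool:
    """Whether point ``p`` lies inside or on the boundary of circle ``c``.

    Points at exactly radius distance count as inside (closed disk).
    Squared distances are compared, avoiding a square root.
    """
    dx = p[0] - c.cx
    dy = p[1] - c.cy
    return dx * dx + dy * dy <= c.radius * c.radius


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two circles with center distance d (analytic)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    # distance from center 1 to the radical line
    d1 = (d * d - r2 * r2 + r1 * r1) / (2.0 * d)
    d2 = d - d1
    a1 = r1 * r1 * math.acos(max(-1.0, min(1.0, d1 / r1)))
    a2 = r2 * r2 * math.acos(max(-1.0, min(1.0, d2 / r2)))
    t1 = d1 * math.sqrt(max(0.0, r1 * r1 - d1 * d1))
    t2 = d2 * math.sqrt(max(0.0, r2 * r2 - d2 * d2))
    return a1 - t1 + a2 - t2


def circle_dice(a: Circle, b: Circle) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two disks, computed analytically.

    For equal radii r the dice is 1 at center distance 0, decreases
    strictly on (0, 2r), and is 0 for d >= 2r.  A dice of 0.7 — the
    match criterion between automatic and manual hotspots — corresponds
    to a center distance of about 0.476 r for equal radii.
    """
    d = math.hypot(a.cx - b.cx, a.cy - b.cy)
    inter = _lens_area(d, a.radius, b.radius)
    total = math.pi * (a.radius**2 + b.radius**2)
    return 2.0 * inter / total


def detections_to_array(detections: Iterable[Detection]) -> np.ndarray:
    """(n, 2) float array of detection coordinates in micrometers."""
    return np.array([(d.x, d.y) for d in detections], dtype=float).reshape(-1, 2)
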