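"""Synthetic slide generator.

Emulates the point-pattern and imaging structure of a cytokeratin IHC
slide at desk scale so every pipeline stage can be exercised without
any whole-slide data: clustered tumor-bud patterns with a known densest
disk (the planted hotspot), non-bud distractors, a sparse manual
annotation subset, a noisy "teacher" detector, and rendered DAB-blob
imagery obeying the same Beer-Lambert forward model the stain module
inverts.

Defaults describe a realistic tumor region: a 6 x 6 mm tissue with a
background bud intensity of 1 / mm**2, one dominant Gaussian cluster of
25 buds (sd 150 um), distractors at 1 / mm**2, and teacher false
positives at 0.5 / mm**2.  Teacher likelihoods are Beta(8, 2) for true
buds and Beta(2, 8) for false positives, so the 0.80 acceptance
threshold separates them imperfectly, as a real detector would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    DEFAULT_HOTSPOT_RADIUS_UM,
    Circle,
    Detection,
    Label,
    SlideGeometry,
    Source,
)
from .density import DEFAULT_GRID_SPACING_UM
from .stain import HDAB_BASIS, OD_EPS, RgbTile, StainBasis

__all__ = [
    "ClusterSpec",
    "SimulationConfig",
    "SyntheticSlide",
    "simulate_slide",
    "densest_disk_oracle",
    "render_ihc",
]


@dataclass(frozen=True)
class ClusterSpec:
    """An isotropic Gaussian bud cluster."""

    n_buds: int
    sd_um: float = 150.0
    center_mm: tuple[float, float] | None = None  # None: placed at random

    def __post_init__(self) -> None:
        if self.n_buds < 0:
            raise ValueError("n_buds must be non-negative")
        if self.sd_um <= 0:
            raise ValueError("sd_um must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    width_mm: float = 6.0
    height_mm: float = 6.0
    background_rate: float = 1.0  # buds / mm**2
    clusters: tuple[ClusterSpec, ...] = (ClusterSpec(n_buds=25, sd_um=150.0),)
    distractor_rate: float = 1.0  # non-bud objects / mm**2
    teacher_fp_rate: float = 0.5  # false positives / mm**2
    likelihood_true: tuple[float, float] = (8.0, 2.0)  # Beta params
    likelihood_false: tuple[float, float] = (2.0, 8.0)
    n_manual_tb: int = 10
    n_manual_non_tb: int = 8
    radius_um: float = DEFAULT_HOTSPOT_RADIUS_UM
    grid_spacing_um: float = DEFAULT_GRID_SPACING_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("tissue dimensions must be positive")
        for rate in (self.background_rate, self.distractor_rate, self.teacher_fp_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm


@dataclass(frozen=True)
class SyntheticSlide:
    """A generated slide: ground-truth points plus derived observations."""

    true_buds: np.ndarray  # (n, 2) um
    distractors: np.ndarray  # (m, 2) um
    manual_annotations: tuple[Detection, ...]
    teacher_detections: tuple[Detection, ...]
    planted_hotspot: Circle
    planted_count: int
    config: SimulationConfig
    rendered: RgbTile | None = None


def _uniform_points(rng: np.random.Generator, n: int, w_um: float, h_um: float) -> np.ndarray:
    pts = rng.uniform((0.0, 0.0), (w_um, h_um), size=(n, 2))
    return pts.reshape(-1, 2)


def simulate_slide(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
) -> SyntheticSlide:
    """Draw one synthetic slide from the configured generative model.

    Background buds and distractors follow homogeneous Poisson processes
    over the tissue rectangle; cluster buds are isotropic Gaussians
    around their centers (clipped to the tissue).  The planted hotspot
    is the exhaustive densest-disk solution over the density grid, so it
    is the ground truth the hotspot selector should recover.

    With a fixed seed the output is bit-reproducible.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w_um = config.width_mm * 1000.0
    h_um = config.height_mm * 1000.0

    n_bg = rng.poisson(config.background_rate * config.area_mm2)
    parts = [_uniform_points(rng, n_bg, w_um, h_um)]
    for cl in config.clusters:
        if cl.center_mm is None:
            inset = min(3.0 * cl.sd_um, w_um / 2, h_um / 2)
            center = rng.uniform((inset, inset), (w_um - inset, h_um - inset))
        else:
            center = np.array(cl.center_mm, dtype=float) * 1000.0
        pts = rng.normal(center, cl.sd_um, size=(cl.n_buds, 2))
        parts.append(np.clip(pts, 0.0, (w_um, h_um)).reshape(-1, 2))
    true_buds = np.vstack(parts)
    if true_buds.shape[0] == 0:
        raise ValueError("simulation produced no buds; increase rates or clusters")

    n_dis = rng.poisson(config.distractor_rate * config.area_mm2)
    distractors = _uniform_points(rng, n_dis, w_um, h_um)

    manual: list[Detection] = []
    n_tb = min(config.n_manual_tb, len(true_buds))
    for idx in rng.choice(len(true_buds), size=n_tb, replace=False):
        x, y = true_buds[idx]
        manual.append(Detection(x, y, label=Label.TB, source=Source.MANUAL, certainty=1.0))
    n_ntb = min(config.n_manual_non_tb, len(distractors))
    if n_ntb:
        for idx in rng.choice(len(distractors), size=n_ntb, replace=False):
            x, y = distractors[idx]
            manual.append(
                Detection(x, y, label=Label.NON_TB, source=Source.MANUAL, certainty=1.0)
            )

    a_t, b_t = config.likelihood_true
    teacher: list[Detection] = [
        Detection(x, y, likelihood=float(l), source=Source.DETECTOR)
        for (x, y), l in zip(true_buds, rng.beta(a_t, b_t, size=len(true_buds)))
    ]
    n_fp = rng.poisson(config.teacher_fp_rate * config.area_mm2)
    a_f, b_f = config.likelihood_false
    for (x, y), l in zip(
        _uniform_points(rng, n_fp, w_um, h_um), rng.beta(a_f, b_f, size=n_fp)
    ):
        teacher.append(Detection(x, y, likelihood=float(l), source=Source.DETECTOR))

    geometry = SlideGeometry(w_um, h_um, config.grid_spacing_um)
    planted, count = densest_disk_oracle(
        true_buds, config.radius_um, config.grid_spacing_um, geometry=geometry
    )

    return SyntheticSlide(
        true_buds=true_buds,
        distractors=distractors,
        manual_annotations=tuple(manual),
        teacher_detections=tuple(teacher),
        planted_hotspot=planted,
        planted_count=count,
        config=config,
    )


def densest_disk_oracle(
    points: np.ndarray | Sequence[tuple[float, float]],
    radius_um: float = DEFAULT_HOTSPOT_RADIUS_UM,
    grid_spacing_um: float = DEFAULT_GRID_SPACING_UM,
    geometry: SlideGeometry | None = None,
) -> tuple[Circle, int]:
    """Exhaustive densest-disk scan over raster cell centers.

    Counts the points within ``radius_um`` of every cell center of the
    grid (a KD-tree ball query per center — an independent counting
    route from the density module's stamping) and returns the max-count
    disk.  Ties break to the smallest row-major cell index, the same
    rule the hotspot selector uses.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("points must be non-empty")
    if geometry is None:
        geometry = SlideGeometry.from_points(pts, grid_spacing_um, pad_um=radius_um)
    tree = cKDTree(pts)
    rows, cols = geometry.shape
    xs = geometry.col_centers()
    ys = geometry.row_centers()
    best_count = -1
    best_idx = (0, 0)
    chunk = max(1, int(2_000_000 // max(cols, 1)))
    for i0 in range(0, rows, chunk):
        yy = ys[i0 : i0 + chunk]
        centers = np.stack(
            [np.broadcast_to(xs, (len(yy), cols)), np.broadcast_to(yy[:, None], (len(yy), cols))],
            axis=-1,
        ).reshape(-1, 2)
        counts = tree.query_ball_point(centers, radius_um, return_length=True)
        flat = int(np.argmax(counts))
        if counts[flat] > best_count:
            best_count = int(counts[flat])
            best_idx = (i0 + flat // cols, flat % cols)
    cx, cy = geometry.pixel_center(*best_idx)
    return Circle(cx, cy, radius_um), best_count


def render_ihc(
    slide: SyntheticSlide,
    spacing_um: float = 2.0,
    blob_radius_um: float = 6.0,
    dab_amplitude: float = 1.0,
    hema_amplitude: float = 0.6,
    noise_level: float = 2.0,
    basis: StainBasis = HDAB_BASIS,
    quantize: bool = True,
    seed: int | None = None,
) -> RgbTile:
    """Render a slide as a white-background brightfield IHC tile.

    Each bud becomes a DAB-absorbing disk and each distractor a
    hematoxylin-only disk; intensities follow the Beer-Lambert forward
    model ``I = 255 * 10**(-OD) - 1`` (the exact inverse of the stain
    module's deconvolution, including its epsilon offset), with bounded
    additive pixel noise.  Memory scales with the tissue area over
    ``spacing_um**2``; intended for small tissues or cropped regions.
    """
    if blob_radius_um < 2.0 * spacing_um:
        raise ValueError("blob_radius_um must be at least twice the pixel spacing")
    cfg = slide.config
    w_px = max(1, int(round(cfg.width_mm * 1000.0 / spacing_um)))
    h_px = max(1, int(round(cfg.height_mm * 1000.0 / spacing_um)))
    conc = np.zeros((h_px, w_px, 3), dtype=np.float64)
    _stamp_disks(conc[..., 1], slide.true_buds, blob_radius_um, dab_amplitude, spacing_um)
    _stamp_disks(conc[..., 0], slide.distractors, blob_radius_um, hema_amplitude, spacing_um)
    od = conc @ basis.matrix
    img = 255.0 * np.power(10.0, -od) - OD_EPS
    if noise_level > 0:
        rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
        img = img + rng.uniform(-noise_level, noise_level, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    if quantize:
        img = np.round(img).astype(np.uint8)
    return RgbTile(pixels=img, spacing_um=spacing_um, offset_um=(0.0, 0.0))


def _stamp_disks(
    channel: np.ndarray,
    points: np.ndarray,
    radius_um: float,
    amplitude: float,
    spacing_um: float,
) -> None:
    """Set ``channel`` to ``amplitude`` on pixels whose centers fall in a disk."""
    rows, cols = channel.shape
    r2 = radius_um * radius_um
    for x, y in np.asarray(points, dtype=float).reshape(-1, 2):
        j0 = max(0, int(np.floor((x - radius_um) / spacing_um)))
        j1 = min(cols - 1, int(np.ceil((x + radius_um) / spacing_um)))
        i0 = max(0, int(np.floor((y - radius_um) / spacing_um)))
        i1 = min(rows - 1, int(np.ceil((y + radius_um) / spacing_um)))
        if j1 < j0 or i1 < i0:
            continue
        cx = (np.arange(j0, j1 + 1) + 0.5) * spacing_um - x
        cy = (np.arange(i0, i1 + 1) + 0.5) * spacing_um - y
        inside = (cy[:, None] ** 2 + cx[None, :] ** 2) <= r2
        sub = channel[i0 : i1 + 1, j0 : j1 + 1]
        np.maximum(sub, np.where(inside, amplitude, 0.0), out=sub)
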