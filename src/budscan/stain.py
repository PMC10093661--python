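"""H-DAB color deconvolution, DAB masking, and mask-derived candidates.

Brightfield IHC follows Beer-Lambert absorption: a pixel transmitting
intensity I on a 0-255 scale has optical density OD = -log10(I / 255),
and the OD vector of a pixel is a non-negative mixture of per-stain unit
OD vectors.  Inverting that mixture (color deconvolution, after
Ruifrok & Johnston) yields per-stain concentration images; thresholding
the DAB channel isolates cytokeratin-positive epithelium, whose
connected components serve both as the pseudo-label acceptance mask and
as a classical candidate detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .core import Detection, Label, Source

__all__ = [
    "RgbTile",
    "DabMask",
    "MaskComponent",
    "StainBasis",
    "HDAB_BASIS",
    "deconvolve",
    "dab_mask",
    "candidates_from_mask",
]

#: Epsilon added to intensities before the log, avoiding log(0) at I = 0.
OD_EPS = 1.0

DEFAULT_OD_THRESHOLD = 0.15
DEFAULT_MIN_AREA_UM2 = 30.0
DEFAULT_OPENING_RADIUS_PX = 1
#: Plausible bud area band in um**2 for the size-based likelihood heuristic
#: (one to four epithelial cells of ~10 um diameter).
DEFAULT_BUD_AREA_BAND_UM2 = (30.0, 800.0)


@dataclass(frozen=True)
class RgbTile:
    """An RGB image tile with physical pixel size and slide-frame offset.

    ``offset_um`` is the slide-frame position of the top-left corner of
    pixel (0, 0); pixel (i, j) is centered at
    ``offset + ((j + 0.5) * spacing, (i + 0.5) * spacing)``.
    """

    pixels: np.ndarray
    spacing_um: float
    offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")


@dataclass(frozen=True)
class MaskComponent:
    component_id: int
    pixel_count: int
    area_um2: float
    centroid_um: tuple[float, float]


@dataclass(frozen=True)
class DabMask:
    """Binary DAB-positive mask with its connected components."""

    mask: np.ndarray
    spacing_um: float
    offset_um: tuple[float, float] = (0.0, 0.0)
    components: tuple[MaskComponent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass(frozen=True)
class StainBasis:
    """Unit stain OD vectors (rows: hematoxylin, DAB, residual)."""

    matrix: np.ndarray  # 3x3, rows are unit stain vectors in OD space

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3 x 3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain basis is singular")

    @classmethod
    def from_stains(cls, hematoxylin, dab, residual=None) -> "StainBasis":
        h = np.asarray(hematoxylin, float)
        d = np.asarray(dab, float)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        if residual is None:
            r = np.cross(h, d)
        else:
            r = np.asarray(residual, float)
        r = r / np.linalg.norm(r)
        return cls(np.vstack([h, d, r]))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


#: Published Ruifrok-Johnston H-DAB vectors; the residual is the
#: normalized cross product of the two, spanning the remaining OD space.
HDAB_BASIS = StainBasis.from_stains(
    hematoxylin=(0.650, 0.704, 0.286),
    dab=(0.268, 0.570, 0.776),
)


def deconvolve(tile: RgbTile, basis: StainBasis = HDAB_BASIS) -> np.ndarray:
    """Unmix an RGB tile into per-stain concentration images.

    Returns an (H, W, 3) float array with channels (hematoxylin, DAB,
    residual) in optical-density units.  OD is computed per channel as
    ``-log10((I + 1) / 255)``; negative unmixed concentrations are
    clipped to zero.
    """
    px = np.asarray(tile.pixels, dtype=np.float64)
    od = -np.log10((px + OD_EPS) / 255.0)
    conc = od @ basis.inverse
    np.clip(conc, 0.0, None, out=conc)
    return conc


def dab_mask(
    dab: np.ndarray,
    spacing_um: float,
    offset_um: tuple[float, float] = (0.0, 0.0),
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    opening_radius_px: int = DEFAULT_OPENING_RADIUS_PX,
) -> DabMask:
    """Threshold a DAB concentration image into a component-labeled mask.

    Pixels with DAB concentration >= ``od_threshold`` are kept, cleaned
    by a morphological opening with a disk element, grouped into
    8-connected components, and components smaller than
    ``min_area_um2`` are dropped.
    """
    if od_threshold <= 0:
        raise ValueError("od_threshold must be positive")
    mask = np.asarray(dab, dtype=np.float64) >= od_threshold
    if opening_radius_px > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius_px))
    labels = measure.label(mask, connectivity=2)
    px_area = spacing_um * spacing_um
    comps: list[MaskComponent] = []
    cleaned = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if area < min_area_um2:
            continue
        cleaned[labels == region.label] = True
        ci, cj = region.centroid  # row, col in pixel units
        centroid = (
            offset_um[0] + (cj + 0.5) * spacing_um,
            offset_um[1] + (ci + 0.5) * spacing_um,
        )
        comps.append(
            MaskComponent(
                component_id=len(comps) + 1,
                pixel_count=int(region.area),
                area_um2=float(area),
                centroid_um=centroid,
            )
        )
    return DabMask(
        mask=cleaned,
        spacing_um=spacing_um,
        offset_um=offset_um,
        components=tuple(comps),
    )


def candidates_from_mask(
    mask: DabMask,
    bud_area_band_um2: tuple[float, float] = DEFAULT_BUD_AREA_BAND_UM2,
) -> list[Detection]:
    """One unlabeled detection per mask component, at its centroid.

    The likelihood heuristic is size-based: components within the
    plausible bud-area band get likelihood 1.0, everything else 0.5.
    This is a classical stand-in for a learned detector, letting the
    downstream density/hotspot stages run on plain stain masks.
    """
    lo, hi = bud_area_band_um2
    out: list[Detection] = []
    for comp in mask.components:
        like = 1.0 if lo <= comp.area_um2 <= hi else 0.5
        out.append(
            Detection(
                x=comp.centroid_um[0],
                y=comp.centroid_um[1],
                likelihood=like,
                label=Label.UNLABELED,
                source=Source.DETECTOR,
            )
        )
    return out
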