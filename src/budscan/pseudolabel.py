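"""Teacher-student training-set construction from pseudo-labels.

A teacher detector applied to the whole slide produces dense candidate
detections with likelihoods.  Candidates are kept only when the teacher
likelihood is strictly above 0.80 and the candidate falls on the
DAB-positive stain mask; survivors become pseudo-labels with reduced
supervision certainty (0.80), merged with the sparse manual annotations
(certainty 1.0, always retained, and taking precedence over any
pseudo-label at the same object).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Detection, Label, Source
from .stain import DabMask

__all__ = [
    "PseudoLabelConfig",
    "PatchSpec",
    "TrainingManifest",
    "filter_by_likelihood",
    "filter_by_dab",
    "merge_and_weight",
]


@dataclass(frozen=True)
class PseudoLabelConfig:
    """Thresholds and weights for pseudo-label dataset construction."""

    likelihood_threshold: float = 0.80  # strict >
    pseudo_certainty: float = 0.80
    manual_certainty: float = 1.0
    collision_radius_um: float = 15.0
    mask_tolerance_um: float = 0.0
    patch_side_px: int = 1024
    patch_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.likelihood_threshold < 1.0):
            raise ValueError("likelihood_threshold must be in (0, 1)")
        if self.pseudo_certainty > self.manual_certainty:
            raise ValueError("pseudo_certainty must not exceed manual_certainty")


@dataclass(frozen=True)
class PatchSpec:
    center_um: tuple[float, float]
    side_px: int
    spacing_um: float


@dataclass(frozen=True)
class TrainingManifest:
    """Merged, certainty-weighted records plus per-record patch specs."""

    records: tuple[Detection, ...]
    patches: tuple[PatchSpec, ...] = field(default_factory=tuple)

    @property
    def n_manual(self) -> int:
        return sum(1 for r in self.records if r.source is Source.MANUAL)

    @property
    def n_pseudo(self) -> int:
        return sum(1 for r in self.records if r.source is Source.PSEUDO)


def filter_by_likelihood(
    detections: Sequence[Detection], threshold: float = 0.80
) -> list[Detection]:
    """Keep detections with likelihood strictly above the threshold.

    A likelihood of exactly 0.80 is rejected.  Manual annotations bypass
    the filter entirely (they carry no teacher likelihood).
    """
    out = []
    for d in detections:
        if d.source is Source.MANUAL:
            out.append(d)
        elif d.likelihood is not None and d.likelihood > threshold:
            out.append(d)
    return out


def filter_by_dab(
    detections: Sequence[Detection],
    mask: DabMask,
    tolerance_um: float = 0.0,
) -> list[Detection]:
    """Reject candidates not present on the DAB-positive mask.

    A candidate is retained when its point falls on a true mask pixel,
    or within ``tolerance_um`` of one.  Candidates outside the mask
    extent are rejected.  Manual annotations bypass the filter.
    """
    grid = np.asarray(mask.mask, dtype=bool)
    rows, cols = grid.shape
    s = mask.spacing_um
    ox, oy = mask.offset_um
    dist_um: np.ndarray | None = None
    if tolerance_um > 0 and grid.any():
        # distance from each pixel to the nearest mask-true pixel
        dist_um = ndimage.distance_transform_edt(~grid) * s
    out: list[Detection] = []
    for d in detections:
        if d.source is Source.MANUAL:
            out.append(d)
            continue
        j = int(np.floor((d.x - ox) / s))
        i = int(np.floor((d.y - oy) / s))
        if not (0 <= i < rows and 0 <= j < cols):
            continue
        if grid[i, j] or (dist_um is not None and dist_um[i, j] <= tolerance_um):
            out.append(d)
    return out


def merge_and_weight(
    pseudo: Sequence[Detection],
    manual: Sequence[Detection],
    config: PseudoLabelConfig = PseudoLabelConfig(),
) -> TrainingManifest:
    """Merge filtered pseudo-labels with manual annotations.

    Manual records always survive and receive certainty 1.0; pseudo
    records receive certainty 0.80 so the student is penalized less for
    mistakes on them.  A pseudo record within ``collision_radius_um`` of
    any manual record is dropped — the manual label supervises that
    object.  Records are ordered manual-first, then by (x, y) position,
    so the manifest is independent of input ordering.
    """
    manual_w = [
        replace(d, certainty=config.manual_certainty, source=Source.MANUAL)
        for d in manual
    ]
    kept_pseudo: list[Detection] = []
    if manual_w:
        tree = cKDTree(np.array([(d.x, d.y) for d in manual_w]))
        for d in pseudo:
            dist, _ = tree.query((d.x, d.y))
            if dist <= config.collision_radius_um:
                continue
            kept_pseudo.append(_as_pseudo(d, config))
    else:
        kept_pseudo = [_as_pseudo(d, config) for d in pseudo]

    manual_w.sort(key=lambda d: (d.x, d.y))
    kept_pseudo.sort(key=lambda d: (d.x, d.y))
    records = tuple(manual_w + kept_pseudo)
    patches = tuple(
        PatchSpec((r.x, r.y), config.patch_side_px, config.patch_spacing_um)
        for r in records
    )
    return TrainingManifest(records=records, patches=patches)


def _as_pseudo(d: Detection, config: PseudoLabelConfig) -> Detection:
    label = Label.TB if d.label is Label.UNLABELED else d.label
    return replace(d, certainty=config.pseudo_certainty, source=Source.PSEUDO, label=label)
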