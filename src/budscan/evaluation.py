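"""Evaluation metrics: point-detection sensitivity, hotspot-count
comparison, and manual-vs-automatic hotspot agreement.

With sparse candidate references (a labeled subset of objects, not an
exhaustive enumeration) only true positives and false negatives can be
identified, so the detection metric is sensitivity alone — specificity
would require knowing every negative on the slide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .core import Detection, Label
from .hotspot import HotspotMatchReport

__all__ = [
    "SensitivityReport",
    "CountComparison",
    "AgreementFractions",
    "sensitivity",
    "compare_counts",
    "hotspot_agreement",
    "DEFAULT_MATCH_RADIUS_UM",
]

#: Default hit radius for matching a predicted detection to a reference
#: bud; about one bud diameter.
DEFAULT_MATCH_RADIUS_UM = 25.0


@dataclass(frozen=True)
class SensitivityReport:
    n_reference_tb: int
    n_hit: int
    sensitivity: float
    match_radius_um: float


@dataclass(frozen=True)
class CountComparison:
    """Paired manual vs automatic hotspot bud counts."""

    pairs: tuple[tuple[float, float], ...]
    pearson_r: float
    mean_ratio: float  # mean(auto) / mean(manual)


@dataclass(frozen=True)
class AgreementFractions:
    top3: float
    top10: float
    none: float


def sensitivity(
    reference: Sequence[Detection],
    predicted: Sequence[Detection],
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> SensitivityReport:
    """Fraction of reference tumor buds hit by a predicted detection.

    Matching is greedy nearest-first and one-to-one: all (reference TB,
    prediction) pairs within ``match_radius_um`` are sorted by distance
    (ties by reference index, then prediction index) and consumed so
    that each prediction hits at most one reference.

    Raises
    ------
    ValueError
        When the reference contains no TB-labeled object.
    """
    if match_radius_um <= 0:
        raise ValueError("match_radius_um must be positive")
    ref_tb = [d for d in reference if d.label is Label.TB]
    if not ref_tb:
        raise ValueError("sensitivity undefined: no reference tumor buds")
    n_ref = len(ref_tb)
    if not predicted:
        return SensitivityReport(n_ref, 0, 0.0, match_radius_um)
    ref_xy = np.array([(d.x, d.y) for d in ref_tb])
    pred_xy = np.array([(d.x, d.y) for d in predicted])
    tree = cKDTree(pred_xy)
    pairs: list[tuple[float, int, int]] = []
    for ri, xy in enumerate(ref_xy):
        for pi in tree.query_ball_point(xy, match_radius_um):
            dist = float(np.hypot(*(xy - pred_xy[pi])))
            pairs.append((dist, ri, pi))
    pairs.sort()
    used_ref: set[int] = set()
    used_pred: set[int] = set()
    hits = 0
    for _, ri, pi in pairs:
        if ri in used_ref or pi in used_pred:
            continue
        used_ref.add(ri)
        used_pred.add(pi)
        hits += 1
    return SensitivityReport(n_ref, hits, hits / n_ref, match_radius_um)


def compare_counts(
    pairs: Sequence[tuple[float, float]],
) -> CountComparison:
    """Pearson correlation and mean ratio of (manual, auto) count pairs.

    Raises
    ------
    ValueError
        With fewer than 3 pairs or zero variance in either coordinate,
        where the correlation is undefined.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 paired counts")
    manual, auto = arr[:, 0], arr[:, 1]
    if np.ptp(manual) == 0 or np.ptp(auto) == 0:
        raise ValueError("correlation undefined for zero-variance counts")
    r = float(stats.pearsonr(manual, auto).statistic)
    if manual.mean() == 0:
        raise ValueError("mean ratio undefined: manual counts sum to zero")
    return CountComparison(
        pairs=tuple(map(tuple, arr)),
        pearson_r=r,
        mean_ratio=float(auto.mean() / manual.mean()),
    )


def hotspot_agreement(
    reports: Sequence[HotspotMatchReport],
) -> AgreementFractions:
    """Fractions of slides whose manual hotspot matched an automatic one.

    ``top3`` and ``top10`` are the fractions matching within the first
    three and first ten ranks; ``none`` is the remainder, so
    top10 + none = 1 and top3 <= top10.
    """
    if not reports:
        raise ValueError("reports must be non-empty")
    n = len(reports)
    top3 = sum(r.top3_match for r in reports) / n
    top10 = sum(r.top10_match for r in reports) / n
    return AgreementFractions(top3=top3, top10=top10, none=1.0 - top10)
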