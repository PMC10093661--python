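"""Slide-level biomarkers: ITBCC tier, Shannon entropy, dichotomization.

The ITBCC three-tier system converts the bud count of the scoring
hotspot into Bd1 (0-4 buds, low), Bd2 (5-9, intermediate) or Bd3 (>= 10,
high).  The Shannon entropy of a density map quantifies how evenly the
bud burden is spread across the slide — a candidate spatial
heterogeneity biomarker that complements the single-hotspot count.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .density import DensityMap

__all__ = [
    "Tier",
    "BudScore",
    "EntropyScore",
    "UndefinedEntropyError",
    "CutoffRule",
    "itbcc_tier",
    "shannon_entropy",
    "dichotomize",
]


class Tier(str, enum.Enum):
    """ITBCC three-tier budding grade."""

    Bd1 = "Bd1"
    Bd2 = "Bd2"
    Bd3 = "Bd3"


@dataclass(frozen=True)
class BudScore:
    count: int
    tier: Tier


@dataclass(frozen=True)
class EntropyScore:
    """Shannon entropy of a density map.

    ``entropy`` is in nats unless a log base was given; the normalized
    value divides by the entropy of the uniform distribution over all
    raster cells, so it lies in [0, 1].  ``n_support`` counts the cells
    with positive density.
    """

    entropy: float
    normalized_entropy: float
    n_support: int


class UndefinedEntropyError(ValueError):
    """Raised for all-zero density maps, where entropy is undefined."""


class CutoffRule(str, enum.Enum):
    MEDIAN = "MEDIAN"
    ITBCC = "ITBCC"
    FIXED = "FIXED"


def itbcc_tier(count: int) -> Tier:
    """ITBCC tier for a hotspot bud count: 0-4 Bd1, 5-9 Bd2, >= 10 Bd3."""
    if count < 0:
        raise ValueError(f"bud count must be non-negative, got {count}")
    if count <= 4:
        return Tier.Bd1
    if count <= 9:
        return Tier.Bd2
    return Tier.Bd3


def shannon_entropy(dmap: DensityMap, base: float | None = None) -> EntropyScore:
    """Shannon entropy of the bud-density distribution over raster cells.

    The probability of cell j is its count divided by the sum of counts
    over all cells (0 log 0 := 0).  The normalized entropy divides by
    log(K) for a K-cell raster, the entropy of the uniform distribution.

    Raises
    ------
    UndefinedEntropyError
        When the map has no counted buds — an undefined score, distinct
        from the zero entropy of a single-cell point mass.
    """
    counts = np.asarray(dmap.counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise UndefinedEntropyError("entropy undefined for an all-zero density map")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    log_k = math.log(counts.size)
    if base is not None:
        h /= math.log(base)
        log_k /= math.log(base)
    normalized = h / log_k if log_k > 0 else 0.0
    return EntropyScore(entropy=h, normalized_entropy=normalized, n_support=int((counts > 0).sum()))


def dichotomize(
    values: Sequence[float],
    rule: CutoffRule | str = CutoffRule.MEDIAN,
    fixed_cutoff: float | None = None,
    itbcc_high_tier: Tier = Tier.Bd3,
) -> tuple[list[bool], float | None]:
    """Split per-slide scores into low/high groups.

    MEDIAN: high iff value > median (strict; ties go low).
    ITBCC: values are hotspot bud counts; high iff the tier reaches
    ``itbcc_high_tier`` (default Bd3, i.e. count >= 10).
    FIXED: high iff value > ``fixed_cutoff``.

    Returns (labels, cutoff) where labels[i] is True for "high" and
    cutoff is the numeric threshold used (None for the ITBCC rule).
    """
    rule = CutoffRule(rule)
    vals = list(values)
    if not vals:
        raise ValueError("values must be non-empty")
    if rule is CutoffRule.MEDIAN:
        cutoff = float(np.median(vals))
        return [v > cutoff for v in vals], cutoff
    if rule is CutoffRule.FIXED:
        if fixed_cutoff is None:
            raise ValueError("FIXED rule requires fixed_cutoff")
        return [v > fixed_cutoff for v in vals], float(fixed_cutoff)
    # ITBCC on integer hotspot counts
    order = [Tier.Bd1, Tier.Bd2, Tier.Bd3]
    hi = order.index(itbcc_high_tier)
    return [order.index(itbcc_tier(int(v))) >= hi for v in vals], None
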