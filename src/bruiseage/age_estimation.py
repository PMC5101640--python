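"""Bruise age estimation from inflammatory-cell scores.

The age of a bruise is read off two ordinal scores: neutrophil infiltration in
the subcutis and macrophage infiltration in the muscle.  Each nonzero score
maps to a calibrated closed interval of hours post-infliction:

====================  =====  ==========
cell type, tissue     score  age (h)
====================  =====  ==========
neutrophils, subcutis   1      1 to 3
neutrophils, subcutis   2      1 to 8
neutrophils, subcutis   3      4 to 10
macrophages, muscle     1      2 to 9
macrophages, muscle     2      2 to 10
macrophages, muscle     3      4 to 10
====================  =====  ==========

The two intervals are combined to the narrowest interval consistent with both
(set intersection) when they overlap; when they are disjoint the interval of
the cell type with the strictly higher score wins; a single zero score
contributes nothing; two zero scores make the bruise inconclusive.  The
combined interval is then binned into four mutually exclusive categories:
inconclusive, <4 h (entirely below 4), >4 h (lower bound at or above 4), or
overlapping 4 h.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .datamodel import BruiseHistology, CellScore

__all__ = [
    "AgeInterval",
    "AgeCategory",
    "CombinationRule",
    "CellType",
    "AgeResult",
    "score_to_interval",
    "combine_intervals",
    "categorize",
    "estimate_age",
    "full_combination_table",
    "CATEGORY_ORDER",
    "CATEGORY_DISPLAY",
]


@dataclass(frozen=True, order=True)
class AgeInterval:
    """Closed interval [lower_h, upper_h] of hours post-infliction."""

    lower_h: int
    upper_h: int

    def __post_init__(self) -> None:
        if self.lower_h > self.upper_h:
            raise ValueError(f"empty interval: [{self.lower_h}, {self.upper_h}]")
        if self.lower_h < 1 or self.upper_h > 10:
            raise ValueError(
                f"interval [{self.lower_h}, {self.upper_h}] outside the calibrated [1, 10] h range"
            )

    @property
    def width(self) -> int:
        return self.upper_h - self.lower_h

    def overlaps(self, other: "AgeInterval") -> bool:
        return self.lower_h <= other.upper_h and other.lower_h <= self.upper_h

    def intersect(self, other: "AgeInterval") -> "AgeInterval":
        if not self.overlaps(other):
            raise ValueError(f"disjoint intervals: {self} and {other}")
        return AgeInterval(max(self.lower_h, other.lower_h), min(self.upper_h, other.upper_h))

    def __str__(self) -> str:
        return f"[{self.lower_h}, {self.upper_h}] h"


class AgeCategory(enum.Enum):
    INCONCLUSIVE = "inconclusive"
    UNDER_4H = "under_4h"
    OVER_4H = "over_4h"
    OVERLAPPING_4H = "overlapping_4h"


class CombinationRule(enum.Enum):
    INTERSECTION = "intersection"
    DOMINANT_SCORE = "dominant_score"
    SINGLE_CELL_TYPE = "single_cell_type"
    INCONCLUSIVE = "inconclusive"


class CellType(enum.Enum):
    NEUTROPHIL_SUBCUTIS = "neutrophil_subcutis"
    MACROPHAGE_MUSCLE = "macrophage_muscle"


# calibrated score -> interval lookup; score 0 carries no age information
_SCORE_INTERVALS: dict[CellType, dict[int, AgeInterval]] = {
    CellType.NEUTROPHIL_SUBCUTIS: {
        1: AgeInterval(1, 3),
        2: AgeInterval(1, 8),
        3: AgeInterval(4, 10),
    },
    CellType.MACROPHAGE_MUSCLE: {
        1: AgeInterval(2, 9),
        2: AgeInterval(2, 10),
        3: AgeInterval(4, 10),
    },
}

CATEGORY_ORDER = (
    AgeCategory.INCONCLUSIVE,
    AgeCategory.UNDER_4H,
    AgeCategory.OVER_4H,
    AgeCategory.OVERLAPPING_4H,
)

CATEGORY_DISPLAY = {
    AgeCategory.INCONCLUSIVE: "Inconclusive",
    AgeCategory.UNDER_4H: "<4 h",
    AgeCategory.OVER_4H: ">4 h",
    AgeCategory.OVERLAPPING_4H: "Overlapping 4 h",
}


@dataclass(frozen=True)
class AgeResult:
    """Combined age interval (or none) with its category and provenance."""

    interval: Optional[AgeInterval]
    category: AgeCategory
    neutrophil_score: int
    neutrophil_interval: Optional[AgeInterval]
    macrophage_score: int
    macrophage_interval: Optional[AgeInterval]
    rule: CombinationRule

    def __post_init__(self) -> None:
        if (self.interval is None) != (self.category is AgeCategory.INCONCLUSIVE):
            raise ValueError("interval is None iff category is inconclusive")


def score_to_interval(cell_type: CellType, score: int) -> Optional[AgeInterval]:
    """Map one cell score to its calibrated age interval; score 0 -> ``None``."""
    if not isinstance(cell_type, CellType):
        raise TypeError(f"cell_type must be a CellType, got {cell_type!r}")
    score = CellScore(score)
    if score == 0:
        return None
    return _SCORE_INTERVALS[cell_type][int(score)]


def combine_intervals(n_score: int, m_score: int) -> AgeResult:
    """Combine the neutrophil and macrophage evidence for one bruise.

    Rules, in order: both zero -> inconclusive; one zero -> the other cell
    type's interval alone; overlapping intervals -> their intersection (the
    narrowest interval consistent with both); disjoint intervals -> the
    interval of the strictly higher score.  A score tie with disjoint
    intervals is unreachable with the calibrated table and raises rather
    than guessing.
    """
    n_score, m_score = CellScore(n_score), CellScore(m_score)
    n_iv = score_to_interval(CellType.NEUTROPHIL_SUBCUTIS, n_score)
    m_iv = score_to_interval(CellType.MACROPHAGE_MUSCLE, m_score)

    def result(interval: Optional[AgeInterval], rule: CombinationRule) -> AgeResult:
        return AgeResult(
            interval=interval,
            category=categorize(interval),
            neutrophil_score=int(n_score),
            neutrophil_interval=n_iv,
            macrophage_score=int(m_score),
            macrophage_interval=m_iv,
            rule=rule,
        )

    if n_iv is None and m_iv is None:
        return result(None, CombinationRule.INCONCLUSIVE)
    if n_iv is None:
        return result(m_iv, CombinationRule.SINGLE_CELL_TYPE)
    if m_iv is None:
        return result(n_iv, CombinationRule.SINGLE_CELL_TYPE)
    if n_iv.overlaps(m_iv):
        return result(n_iv.intersect(m_iv), CombinationRule.INTERSECTION)
    if n_score == m_score:
        raise ValueError(
            f"equal scores {int(n_score)} with disjoint intervals {n_iv} and {m_iv}: "
            "no combination rule is defined for this case"
        )
    winner = n_iv if n_score > m_score else m_iv
    return result(winner, CombinationRule.DOMINANT_SCORE)


def categorize(interval: Optional[AgeInterval]) -> AgeCategory:
    """Bin a combined interval into the four age categories."""
    if interval is None:
        return AgeCategory.INCONCLUSIVE
    if interval.upper_h < 4:
        return AgeCategory.UNDER_4H
    if interval.lower_h >= 4:
        return AgeCategory.OVER_4H
    return AgeCategory.OVERLAPPING_4H


def estimate_age(bruise: BruiseHistology) -> AgeResult:
    """Estimate one bruise's age from its subcutis-neutrophil and
    muscle-macrophage scores; all other fields are ignored here."""
    return combine_intervals(bruise.subcutis_neutrophils, bruise.muscle_macrophages)


def full_combination_table() -> list[AgeResult]:
    """Enumerate all 16 (neutrophil, macrophage) score pairs.

    The exhaustive oracle surface: every downstream property of the
    combination rules can be checked against these 16 rows.
    """
    return [combine_intervals(n, m) for n in range(4) for m in range(4)]
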