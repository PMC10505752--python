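"""Semiquantitative expression scoring.

A visually assessed tumor receives a percentage score (1-4, from the
fraction of positively stained tumor cells) and an intensity score (0-3).
Their product is the final grade of positivity, binned into expression
categories: 0 = no expression, 1-3 = low, 4-6 = intermediate, 8-12 = high.
Grades 5, 7, 10 and 11 are unreachable products of the two score ranges,
so the bins partition every attainable grade.

When staining is inhomogeneous and more than one-third of the tumor area
shows a higher intensity than the area-majority grade, assessment is
restricted to the strong-signal region (the hotspot rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateRoiError, DomainError

LABELING_PATTERNS = ("cytoplasmic", "membranous", "cytoplasmic_membranous", "none")

CATEGORY_BINS = {
    "no_expression": (0, 0),
    "low": (1, 3),
    "intermediate": (4, 6),
    "high": (8, 12),
}

#: Hotspot rule: restrict scoring to the strong region when more than this
#: fraction of tumor area stains above the area-majority intensity grade.
HOTSPOT_AREA_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class SemiQuantAssessment:
    """Visual assessment of one tumor (consolidated across observers)."""

    percent_positive_cells: float
    intensity_grade: int
    labeling_pattern: str = "cytoplasmic"
    intensity_homogeneous: bool = True
    cell_homogeneous: bool = True
    stroma_positive: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_positive_cells <= 100.0:
            raise DomainError("percent_positive_cells must be in [0, 100]")
        if self.intensity_grade not in (0, 1, 2, 3):
            raise DomainError("intensity_grade must be one of 0, 1, 2, 3")
        if self.labeling_pattern not in LABELING_PATTERNS:
            raise DomainError(f"unknown labeling pattern {self.labeling_pattern!r}")


@dataclass(frozen=True)
class FinalGrade:
    percentage_score: int
    intensity_score: int
    grade: int
    category: str


def percentage_score(percent_positive_cells: float) -> int:
    """Score the fraction of positively stained tumor cells on 1-4.

    Bins: <1% -> 1, 1-10% -> 2, >10-50% -> 3, >50% -> 4.  The bins are
    half-open above 10 and 50 so that any real-valued input maps to
    exactly one score.
    """
    p = float(percent_positive_cells)
    if not 0.0 <= p <= 100.0:
        raise DomainError(f"percentage {p} outside [0, 100]")
    if p < 1.0:
        return 1
    if p <= 10.0:
        return 2
    if p <= 50.0:
        return 3
    return 4


def category_of(grade: int) -> str:
    for name, (lo, hi) in CATEGORY_BINS.items():
        if lo <= grade <= hi:
            return name
    raise DomainError(f"grade {grade} maps to no expression category")


def final_grade(percentage_score: int, intensity_score: int) -> FinalGrade:
    """Multiply the two scores into the final grade of positivity."""
    if percentage_score not in (1, 2, 3, 4):
        raise DomainError("percentage_score must be 1-4")
    if intensity_score not in (0, 1, 2, 3):
        raise DomainError("intensity_score must be 0-3")
    grade = percentage_score * intensity_score
    return FinalGrade(percentage_score, intensity_score, grade, category_of(grade))


def grade_assessment(assessment: SemiQuantAssessment) -> FinalGrade:
    """Convenience: percentage binning plus grading in one step."""
    return final_grade(
        percentage_score(assessment.percent_positive_cells),
        assessment.intensity_grade,
    )


@dataclass(frozen=True)
class RegionalAssessment:
    """One region's share of tumor area with its visual assessment."""

    area_fraction: float
    assessment: SemiQuantAssessment


def hotspot_assessment(
    regions: Sequence[RegionalAssessment],
) -> SemiQuantAssessment:
    """Apply the hotspot rule to regional assessments of one tumor.

    The area-majority intensity grade is the grade holding the largest
    share of tumor area.  If regions at a *higher* grade jointly cover
    more than one-third of the tumor, the returned assessment comes from
    those strong-signal regions (area-weighted percent positive, maximum
    grade); otherwise the whole-tumor summary (area-weighted percent,
    majority grade) is returned.
    """
    if not regions:
        raise DegenerateRoiError("no tumor regions to assess")
    fracs = np.array([r.area_fraction for r in regions], dtype=float)
    if (fracs < 0).any() or fracs.sum() <= 0:
        raise DomainError("region area fractions must be non-negative, sum > 0")
    fracs = fracs / fracs.sum()
    grades = np.array([r.assessment.intensity_grade for r in regions])

    by_grade = {g: float(fracs[grades == g].sum()) for g in np.unique(grades)}
    majority_grade = max(by_grade, key=lambda g: (by_grade[g], g))
    strong = grades > majority_grade
    if float(fracs[strong].sum()) > HOTSPOT_AREA_FRACTION:
        sel = strong
        out_grade = int(grades[sel].max())
        homogeneous = False
    else:
        sel = np.ones_like(strong)
        out_grade = int(majority_grade)
        homogeneous = len(by_grade) == 1
    w = fracs[sel] / fracs[sel].sum()
    pct = float(np.dot(w, [regions[i].assessment.percent_positive_cells
                           for i in np.flatnonzero(sel)]))
    ref = regions[int(np.flatnonzero(sel)[0])].assessment
    return SemiQuantAssessment(
        percent_positive_cells=pct,
        intensity_grade=out_grade,
        labeling_pattern=ref.labeling_pattern,
        intensity_homogeneous=homogeneous,
        cell_homogeneous=ref.cell_homogeneous,
        stroma_positive=ref.stroma_positive,
    )


def regions_from_level_map(
    level_map: np.ndarray,
    tumor_mask: np.ndarray,
    percent_positive_cells: float,
) -> list[RegionalAssessment]:
    """Build regional assessments from a staining-level map.

    Pixel levels are folded onto visual intensity grades (level 0 -> grade
    0, 1 -> 1, 2 -> 2, levels 3 and 4 -> grade 3) and each grade's area
    share becomes one region, all carrying the supplied percent-positive
    estimate.
    """
    mask = np.asarray(tumor_mask, dtype=bool)
    if not mask.any():
        raise DegenerateRoiError("empty tumor mask")
    lv = np.asarray(level_map)[mask]
    grade_of_level = np.array([0, 1, 2, 3, 3])
    g = grade_of_level[lv]
    total = g.size
    return [
        RegionalAssessment(
            area_fraction=float((g == grade).sum()) / total,
            assessment=SemiQuantAssessment(percent_positive_cells, int(grade)),
        )
        for grade in np.unique(g)
    ]


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append percentage_score, intensity_score, final_grade and category
    columns to a per-tumor cohort table.

    Expects columns ``percent_positive_cells`` and ``intensity_grade``.
    """
    out = cohort.copy()
    pscores, grades, cats = [], [], []
    for pct, ig in zip(out["percent_positive_cells"], out["intensity_grade"]):
        fg = final_grade(percentage_score(float(pct)), int(ig))
        pscores.append(fg.percentage_score)
        grades.append(fg.grade)
        cats.append(fg.category)
    out["percentage_score"] = pscores
    out["intensity_score"] = out["intensity_grade"].astype(int)
    out["final_grade"] = grades
    out["category"] = cats
    return out
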