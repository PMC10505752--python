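"""Tumor-to-normal ratios and TASC target-suitability scoring.

The target selection criteria (TASC) rubric scores a molecular target's
suitability for tumor-targeted imaging on seven criteria (maximum 22
points).  For fibroblast activation protein (FAP) four criteria are fixed
literature constants — extracellular localization I=5, prior in-vivo
imaging success V=2, enzymatic activity VI=1, target-mediated
internalization VII=1 — while criteria II-IV are computed per species /
tumor-entity group from immunohistochemistry results:

II  — diffuse overexpression: 4 points when the majority of tumors stain
      >=50% of tumor cells, else 0;
III — tumor-to-normal (T/N) ratio: 3 points when the majority of
      evaluable tumors have T/N > 10, else 0;
IV  — prevalence of overexpression: percentage of tumors with >=10% of
      cells at intermediate-to-strong staining, binned >=90% -> 6,
      70-89% -> 5, 50-69% -> 3, below 50% -> 0.

The "majority" decision defaults to >=50% of the group, which matches the
published per-entity scores (a group at exactly half scores the points);
a strict >50% mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import MajorityMode
from .errors import DomainError

FIXED_FAP_SCORES = {"I": 5, "V": 2, "VI": 1, "VII": 1}
MAX_TASC_SCORE = 22


@dataclass(frozen=True)
class TnRatioInput:
    """A tumor's normalized positive area and its group's control areas.

    Areas are µm² per 2.37 mm².  The control list pools the normalized
    positive areas of all peritumoral and healthy-control measurements
    (muscle, adipose, epidermis/dermis) of the matching group.
    """

    tumor_normalized_positive_area: float
    control_normalized_positive_areas: Sequence[float]

    def __post_init__(self) -> None:
        if self.tumor_normalized_positive_area < 0:
            raise DomainError("tumor area must be non-negative")
        if len(self.control_normalized_positive_areas) == 0:
            raise DomainError("control area list must be nonempty")
        if any(a < 0 for a in self.control_normalized_positive_areas):
            raise DomainError("control areas must be non-negative")


@dataclass(frozen=True)
class CriterionInputs:
    """Per-group counts feeding TASC criteria II-IV.

    ``percent_overexpressing`` optionally overrides the percentage used
    for criterion IV binning (e.g. when working from a published table
    whose printed percentage disagrees with its printed counts); when
    None it is derived from the counts by round-half-up.
    """

    n_tumors: int
    n_diffuse_positive: int
    n_tn_gt10: int
    n_tn_evaluable: int
    n_overexpressing: int
    percent_overexpressing: float | None = None

    def __post_init__(self) -> None:
        if self.n_tumors <= 0:
            raise DomainError("n_tumors must be positive")
        if not 0 <= self.n_diffuse_positive <= self.n_tumors:
            raise DomainError("n_diffuse_positive outside [0, n_tumors]")
        if self.n_tn_evaluable < 0 or self.n_tn_evaluable > self.n_tumors:
            raise DomainError("n_tn_evaluable outside [0, n_tumors]")
        if not 0 <= self.n_tn_gt10 <= max(self.n_tn_evaluable, 0):
            raise DomainError("n_tn_gt10 outside [0, n_tn_evaluable]")
        if not 0 <= self.n_overexpressing <= self.n_tumors:
            raise DomainError("n_overexpressing outside [0, n_tumors]")


@dataclass(frozen=True)
class TascResult:
    criterion_scores: dict[str, int]
    total: int


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Integer percentage with exact .5 rounding upward."""
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def _majority(count: int, total: int, mode: MajorityMode) -> bool:
    if total <= 0:
        raise DomainError("majority decision needs a positive denominator")
    frac = count / total
    return frac >= 0.5 if mode == "gte50" else frac > 0.5


def tn_ratio(inp: TnRatioInput) -> float:
    """Tumor area over the unweighted mean of the pooled control areas."""
    mean_control = float(np.mean(inp.control_normalized_positive_areas))
    if mean_control == 0:
        raise DomainError(
            "mean control area is zero; T/N ratio undefined for this tumor"
        )
    return inp.tumor_normalized_positive_area / mean_control


def criterion_ii(
    n_diffuse_positive: int, n_tumors: int, majority_mode: MajorityMode = "gte50"
) -> int:
    """4 points when the majority of tumors stain >=50% of tumor cells."""
    if not 0 <= n_diffuse_positive <= n_tumors:
        raise DomainError("invalid counts for criterion II")
    return 4 if _majority(n_diffuse_positive, n_tumors, majority_mode) else 0


def criterion_iii(
    n_tn_gt10: int, n_tn_evaluable: int, majority_mode: MajorityMode = "gte50"
) -> int:
    """3 points when the majority of evaluable tumors have T/N > 10."""
    if not 0 <= n_tn_gt10 <= n_tn_evaluable:
        raise DomainError("invalid counts for criterion III")
    return 3 if _majority(n_tn_gt10, n_tn_evaluable, majority_mode) else 0


def criterion_iv(percent_overexpressing: float) -> int:
    """Bin the prevalence of overexpression: >=90 -> 6, 70-89 -> 5,
    50-69 -> 3, below 50 -> 0."""
    p = float(percent_overexpressing)
    if not 0.0 <= p <= 100.0:
        raise DomainError("percentage outside [0, 100]")
    if p >= 90:
        return 6
    if p >= 70:
        return 5
    if p >= 50:
        return 3
    return 0


def tasc_total(
    inputs: CriterionInputs, majority_mode: MajorityMode = "gte50"
) -> TascResult:
    """Score criteria II-IV from group counts and sum with the fixed
    FAP constants (I=5, V=2, VI=1, VII=1)."""
    ii = criterion_ii(inputs.n_diffuse_positive, inputs.n_tumors, majority_mode)
    iii = criterion_iii(inputs.n_tn_gt10, inputs.n_tn_evaluable, majority_mode)
    if inputs.percent_overexpressing is not None:
        pct = float(inputs.percent_overexpressing)
    else:
        pct = round_half_up_percent(inputs.n_overexpressing, inputs.n_tumors)
    iv = criterion_iv(pct)
    scores = {
        "I": FIXED_FAP_SCORES["I"],
        "II": ii,
        "III": iii,
        "IV": iv,
        "V": FIXED_FAP_SCORES["V"],
        "VI": FIXED_FAP_SCORES["VI"],
        "VII": FIXED_FAP_SCORES["VII"],
    }
    return TascResult(criterion_scores=scores, total=sum(scores.values()))


def criterion_inputs_from_cohort(
    cohort: pd.DataFrame,
    tn_threshold: float = 10.0,
    diffuse_threshold: float = 50.0,
    overexpression_threshold: float = 10.0,
    overexpression_strict: bool = False,
) -> CriterionInputs:
    """Derive TASC criterion counts from a per-tumor cohort table.

    Expects ``percent_positive_cells``, ``intensity_grade`` and
    ``tn_ratio`` columns; a missing (NaN) T/N ratio marks a tumor as not
    evaluable for criterion III.  A tumor is *diffusely positive* when at
    least ``diffuse_threshold`` percent of its cells stain, and
    *overexpressing* when at least (or strictly more than, if
    ``overexpression_strict``) ``overexpression_threshold`` percent of
    cells show intermediate-to-strong staining (intensity grade >= 2).
    """
    n = len(cohort)
    if n == 0:
        raise DomainError("empty cohort")
    pct = cohort["percent_positive_cells"].astype(float)
    grade = cohort["intensity_grade"].astype(int)
    tn = cohort["tn_ratio"].astype(float)
    strong = grade >= 2
    if overexpression_strict:
        over = strong & (pct > overexpression_threshold)
    else:
        over = strong & (pct >= overexpression_threshold)
    evaluable = tn.notna()
    return CriterionInputs(
        n_tumors=n,
        n_diffuse_positive=int((pct >= diffuse_threshold).sum()),
        n_tn_gt10=int((tn[evaluable] > tn_threshold).sum()),
        n_tn_evaluable=int(evaluable.sum()),
        n_overexpressing=int(over.sum()),
    )


def tasc_report(
    groups: Iterable[tuple[str, CriterionInputs]],
    majority_mode: MajorityMode = "gte50",
) -> pd.DataFrame:
    """Score several groups and return one report row per group."""
    rows = []
    for label, inputs in groups:
        res = tasc_total(inputs, majority_mode)
        pct = (
            inputs.percent_overexpressing
            if inputs.percent_overexpressing is not None
            else round_half_up_percent(inputs.n_overexpressing, inputs.n_tumors)
        )
        rows.append(
            {
                "group": label,
                "n_tumors": inputs.n_tumors,
                "criterion_I": res.criterion_scores["I"],
                "criterion_II": res.criterion_scores["II"],
                "diffuse_positive": f"{inputs.n_diffuse_positive}/{inputs.n_tumors}",
                "criterion_III": res.criterion_scores["III"],
                "tn_gt10": f"{inputs.n_tn_gt10}/{inputs.n_tn_evaluable}",
                "criterion_IV": res.criterion_scores["IV"],
                "percent_overexpressing": pct,
                "criterion_V": res.criterion_scores["V"],
                "criterion_VI": res.criterion_scores["VI"],
                "criterion_VII": res.criterion_scores["VII"],
                "tasc_total": res.total,
            }
        )
    return pd.DataFrame(rows)
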