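"""Seeded synthetic IHC-like images and cohort tables with known truth.

The simulated "slides" are not photorealistic histology: DAB staining is
encoded directly in the scalar intensity channel (lower value = stronger
brown), with each staining level drawn near its band midpoint so that the
quantifier's fixed thresholds recover the simulated composition.  An
invertible RGB rendering through the standard H-DAB stain matrix lets the
default color-deconvolution route round-trip into the intended bands.
Artifacts are painted in a reserved color so the rule-based detector has
an unambiguous target.  Cohort tables emulate the statistical structure
of a multi-species soft-tissue-sarcoma study: per-entity sample sizes,
grade distributions, percent-positive-cell means/SDs, intensity-grade
distributions and tumor-to-normal ratio dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hed2rgb

from .config import TEN_HPF_AREA_UM2, LevelThresholds
from .errors import SpecificationError
from .quant import ARTIFACT_RGB, DEFAULT_DAB_OD_MAX, RegionOfInterest

#: Band-midpoint pixel value emitted for each staining level.
LEVEL_MIDPOINTS = {0: 216, 1: 153, 2: 115, 3: 85, 4: 35}

#: Maximum +/- jitter around the midpoint; keeps values well inside the
#: band so moderate noise cannot flip a pixel across a band edge.
LEVEL_JITTER = 6


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic IHC image with a single tumor-style ROI.

    ``level_fractions`` are the target area fractions of staining levels
    1-4 preceded by stained-background level 0; remaining ROI area
    defaults to level 0.  ``artifact_fraction`` of the ROI is painted in
    the reserved artifact color.  ``noise_sd`` is Gaussian pixel-value
    noise applied to the intensity map before rendering.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 1.0
    level_fractions: tuple[float, float, float, float, float] = (
        0.3,
        0.1,
        0.1,
        0.1,
        0.1,
    )
    artifact_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    compartment: str = "tumor"
    sample_id: str = "synthetic"
    species: str = "canine"
    entity: str = "PWT"

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise SpecificationError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise SpecificationError("pixel_size_um must be positive")
        if len(self.level_fractions) != 5:
            raise SpecificationError("level_fractions must have five entries")
        if any(f < 0 for f in self.level_fractions):
            raise SpecificationError("level fractions must be non-negative")
        if not 0 <= self.artifact_fraction < 1:
            raise SpecificationError("artifact_fraction must be in [0, 1)")
        if sum(self.level_fractions) + self.artifact_fraction > 1 + 1e-12:
            raise SpecificationError(
                "level fractions plus artifact fraction exceed 1"
            )
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact simulated composition of one synthetic image's ROI.

    Level areas are the *intended* (pre-noise) per-level areas in µm²;
    for a noiseless image the emitted pixels match them exactly.
    """

    level_areas: dict[int, float]
    artifact_area: float
    roi_area: float

    @property
    def total_positive_area(self) -> float:
        return sum(self.level_areas[lvl] for lvl in range(1, 5))


def _render_rgb(values: np.ndarray, dab_od_max: float = DEFAULT_DAB_OD_MAX) -> np.ndarray:
    """Render an intensity map to RGB through the H-DAB stain matrix."""
    od = (1.0 - values.astype(np.float64) / 255.0) * dab_od_max
    hed = np.zeros(values.shape + (3,), dtype=np.float64)
    hed[..., 2] = od
    rgb = np.clip(hed2rgb(hed), 0.0, 1.0)
    return np.rint(rgb * 255.0).astype(np.uint8)


def generate_ihc_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, RegionOfInterest, GroundTruth]:
    """Generate one synthetic IHC image.

    Returns ``(rgb_image, intensity_values, roi, ground_truth)``.  The ROI
    covers the whole frame; pixels are assigned to artifact and staining
    levels at exact counts (largest-remainder apportionment of the target
    fractions) and shuffled into a speckle pattern.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = spec.width_px * spec.height_px

    fracs = list(spec.level_fractions) + [spec.artifact_fraction]
    counts = [int(np.floor(f * n_px)) for f in fracs]
    # largest-remainder top-up so counts sum to the rounded total
    remainders = [f * n_px - c for f, c in zip(fracs, counts)]
    target_total = int(round(sum(fracs) * n_px))
    for i in np.argsort(remainders)[::-1]:
        if sum(counts) >= target_total:
            break
        counts[int(i)] += 1
    n_artifact = counts[5]
    counts[0] += n_px - sum(counts)  # leftover area is stained background

    labels = np.repeat(np.arange(6), counts)  # 0-4 levels, 5 = artifact
    rng.shuffle(labels)
    labels = labels.reshape(spec.height_px, spec.width_px)

    jitter = rng.integers(-LEVEL_JITTER, LEVEL_JITTER + 1, size=labels.shape)
    midpoints = np.array([LEVEL_MIDPOINTS[lvl] for lvl in range(5)] + [0])
    values = midpoints[labels] + jitter
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(np.rint(values), 0, 255).astype(np.uint8)

    rgb = _render_rgb(values)
    artifact = labels == 5
    rgb[artifact] = ARTIFACT_RGB
    values[artifact] = 0  # arbitrary; artifact pixels are excluded anyway

    roi = RegionOfInterest(
        mask=np.ones_like(labels, dtype=bool),
        compartment=spec.compartment,
        sample_id=spec.sample_id,
        species=spec.species,
        entity=spec.entity,
    )
    px_area = spec.pixel_size_um**2
    truth = GroundTruth(
        level_areas={lvl: counts[lvl] * px_area for lvl in range(5)},
        artifact_area=n_artifact * px_area,
        roi_area=n_px * px_area,
    )
    return rgb, values, roi, truth


@dataclass(frozen=True)
class EntitySpec:
    """Simulation parameters for one tumor entity.

    ``grade_probs`` are the proportions of histological grades 1-3;
    ``intensity_probs`` the distribution over visual intensity grades
    0-3; ``tn_log_median``/``tn_log_sd`` parameterize a lognormal
    tumor-to-normal ratio; ``p_tn_evaluable`` is the chance peritumoral
    tissue was available for a tumor.
    """

    species: str
    entity: str
    n: int
    grade_probs: tuple[float, float, float]
    percent_mean: float
    percent_sd: float
    intensity_probs: tuple[float, float, float, float]
    tn_log_median: float = np.log(10.0)
    tn_log_sd: float = 1.0
    p_tn_evaluable: float = 1.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SpecificationError("entity sample size must be positive")
        if abs(sum(self.grade_probs) - 1) > 1e-9:
            raise SpecificationError("grade proportions must sum to 1")
        if abs(sum(self.intensity_probs) - 1) > 1e-9:
            raise SpecificationError("intensity proportions must sum to 1")
        if not 0 <= self.percent_mean <= 100:
            raise SpecificationError("percent mean must be in [0, 100]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    entities: tuple[EntitySpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.entities:
            raise SpecificationError("cohort spec needs at least one entity")


def generate_cohort_table(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate one per-tumor row per synthetic tumor.

    Percent-positive cells are normal draws clipped to [0, 100] (a
    documented bias at the extremes, traded for simplicity); T/N ratios
    are lognormal with NaN where peritumoral tissue is unavailable.  The
    normalized stained area is coupled to the visual assessment — it
    scales with percent positive and intensity grade with lognormal
    scatter — so that association analyses downstream have a known
    positive signal.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for ent in spec.entities:
        grades = rng.choice([1, 2, 3], size=ent.n, p=ent.grade_probs)
        pct = np.clip(
            rng.normal(ent.percent_mean, ent.percent_sd, size=ent.n), 0.0, 100.0
        )
        intensity = rng.choice([0, 1, 2, 3], size=ent.n, p=ent.intensity_probs)
        pct = np.where(intensity == 0, 0.0, pct)
        tn = np.exp(rng.normal(ent.tn_log_median, ent.tn_log_sd, size=ent.n))
        evaluable = rng.random(ent.n) < ent.p_tn_evaluable
        tn = np.where(evaluable, tn, np.nan)
        area = (
            TEN_HPF_AREA_UM2
            * (pct / 100.0)
            * (0.25 + 0.25 * intensity)
            * np.exp(rng.normal(0.0, 0.25, size=ent.n))
        )
        for i in range(ent.n):
            rows.append(
                {
                    "sample_id": f"{ent.species}_{ent.entity}_{i + 1:03d}",
                    "species": ent.species,
                    "entity": ent.entity,
                    "grade": int(grades[i]),
                    "percent_positive_cells": float(pct[i]),
                    "intensity_grade": int(intensity[i]),
                    "tn_ratio": float(tn[i]),
                    "normalized_positive_area_um2": float(area[i]),
                }
            )
    return pd.DataFrame(rows)


def _tn_log_median(p_gt10: float, log_sd: float = 1.0) -> float:
    """Lognormal log-median giving P(T/N > 10) = p_gt10."""
    from scipy.stats import norm

    return float(np.log(10.0) - log_sd * norm.ppf(1.0 - p_gt10))


def study_cohort_spec(seed: int = 0) -> SyntheticCohortSpec:
    """Default cohort: the cross-species soft-tissue-sarcoma study design.

    Entity sample sizes and grade distributions follow the study cohort
    (53 canine STSs split into PWT/STS NOS/cFS, 24 feline fibrosarcomas,
    39 human STSs split into MPNST/UPS/DFSP/MFS); percent-positive means
    and SDs are the per-species values reported for visual assessment;
    T/N lognormal medians are calibrated so that the expected share of
    tumors with T/N > 10 matches the per-entity study fractions; and
    intensity-grade distributions are calibrated to the reported
    no-expression and high-expression marginals per species.
    """
    canine_int = (0.13, 0.10, 0.22, 0.55)
    feline_int = (0.04, 0.08, 0.21, 0.67)
    human_int = (0.26, 0.08, 0.22, 0.44)
    ents = (
        EntitySpec("canine", "PWT", 30, (0.70, 0.27, 0.03), 51.1, 36.2,
                   canine_int, _tn_log_median(12 / 23), 1.0, 23 / 30),
        EntitySpec("canine", "STS_NOS", 16, (0.50, 0.44, 0.06), 51.1, 36.2,
                   canine_int, _tn_log_median(5 / 14), 1.0, 14 / 16),
        EntitySpec("canine", "cFS", 7, (0.57, 0.29, 0.14), 51.1, 36.2,
                   canine_int, _tn_log_median(3 / 7), 1.0, 1.0),
        EntitySpec("feline", "fFS", 24, (0.21, 0.71, 0.08), 56.6, 21.3,
                   feline_int, _tn_log_median(0.5), 1.0, 22 / 24),
        EntitySpec("human", "MPNST", 10, (0.0, 0.2, 0.8), 61.1, 41.7,
                   human_int, _tn_log_median(3 / 9), 1.0, 9 / 10),
        EntitySpec("human", "UPS", 10, (0.0, 0.0, 1.0), 61.1, 41.7,
                   human_int, _tn_log_median(7 / 10), 1.0, 1.0),
        EntitySpec("human", "DFSP", 9, (1 / 3, 1 / 3, 1 / 3), 61.1, 41.7,
                   human_int, _tn_log_median(3 / 7), 1.0, 7 / 9),
        EntitySpec("human", "MFS", 10, (0.0, 0.0, 1.0), 61.1, 41.7,
                   human_int, _tn_log_median(5 / 8), 1.0, 8 / 10),
    )
    return SyntheticCohortSpec(entities=ents, seed=seed)
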