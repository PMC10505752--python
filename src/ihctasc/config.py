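"""Configuration objects shared across the pipeline.

The central constants are the five pixel-value bands that stratify DAB
staining intensity and the high-power-field (HPF) area used to normalize
measured areas across regions of interest of different size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import yaml

#: Area of one x400 high-power field, in square micrometres.
HPF_AREA_UM2 = 237_000.0

#: Standard normalization area: 10 HPF = 2.37 mm^2, in square micrometres.
TEN_HPF_AREA_UM2 = 10 * HPF_AREA_UM2

#: Tissue-compartment vocabulary for regions of interest.
COMPARTMENTS = (
    "tumor",
    "peritumoral_epidermis_dermis",
    "peritumoral_adipose",
    "peritumoral_muscle",
    "control_epidermis_dermis",
    "control_adipose",
    "control_muscle",
    "inflammation",
)

#: Integer codes used in label-mask PNGs (0 = outside any ROI).
COMPARTMENT_CODES = {name: i + 1 for i, name in enumerate(COMPARTMENTS)}


@dataclass(frozen=True)
class LevelThresholds:
    """Closed pixel-value intervals for staining-intensity levels.

    Lower pixel value means stronger brown (DAB) staining.  Level 0 is
    background / negative tissue; levels 1-4 run from weak to very strong
    immunoreactivity.  The five intervals must be disjoint and jointly
    cover [0, 255].
    """

    level1: tuple[int, int] = (131, 175)
    level2: tuple[int, int] = (101, 130)
    level3: tuple[int, int] = (71, 100)
    level4: tuple[int, int] = (0, 70)
    background: tuple[int, int] = (176, 255)

    def __post_init__(self) -> None:
        ivals = self.intervals()
        covered = set()
        for lo, hi in ivals.values():
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"invalid interval [{lo}, {hi}]")
            band = set(range(lo, hi + 1))
            if covered & band:
                raise ValueError("intensity-level intervals overlap")
            covered |= band
        if covered != set(range(256)):
            raise ValueError("intensity-level intervals do not cover [0, 255]")

    def intervals(self) -> dict[int, tuple[int, int]]:
        """Mapping level -> (low, high), both inclusive."""
        return {
            0: self.background,
            1: self.level1,
            2: self.level2,
            3: self.level3,
            4: self.level4,
        }

    def level_of(self, value: int) -> int:
        """Level of a single pixel value (brute-force interval lookup)."""
        for level, (lo, hi) in self.intervals().items():
            if lo <= value <= hi:
                return level
        raise ValueError(f"pixel value {value} outside [0, 255]")


MajorityMode = Literal["gte50", "gt50"]
OverexpressionMode = Literal["gte10", "gt10"]


@dataclass
class PipelineConfig:
    """Top-level knobs for a pipeline run.

    majority_mode
        How a group "majority" is decided for TASC criteria II and III:
        ``gte50`` treats exactly half as a majority (default, matching the
        published per-entity scores), ``gt50`` requires strictly more than
        half.
    overexpression_mode
        Whether a tumor with exactly 10% intermediate-to-strong cells counts
        as overexpressing (``gte10``, default) or not (``gt10``).
    mi_positive_only
        If True, mean intensity is averaged over positively stained pixels
        only instead of all non-artifact ROI pixels.
    """

    thresholds: LevelThresholds = field(default_factory=LevelThresholds)
    ten_hpf_area_um2: float = TEN_HPF_AREA_UM2
    majority_mode: MajorityMode = "gte50"
    overexpression_mode: OverexpressionMode = "gte10"
    mi_positive_only: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if thr is not None:
            cfg.thresholds = LevelThresholds(
                **{k: tuple(v) for k, v in thr.items()}
            )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["thresholds"] = {
            k: list(v) for k, v in asdict(self.thresholds).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
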