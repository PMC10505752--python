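"""Digital quantification of DAB immunostaining.

The analysis operates on a per-pixel *intensity image*: an 8-bit scalar map
where lower values mean stronger brown chromogen.  Pixels are stratified
into five staining-intensity levels by fixed pixel-value bands, artifacts
are excluded, and per-level areas are measured inside annotated regions of
interest (ROIs) and normalized to a standard area of 10 high-power fields
(2.37 mm^2) so that ROIs of different size are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hed

from .config import COMPARTMENTS, TEN_HPF_AREA_UM2, LevelThresholds
from .errors import ConfigurationError, DegenerateRoiError, FormatError

#: Reserved RGB color that marks simulated artifacts unambiguously.
ARTIFACT_RGB = (255, 0, 255)

#: Default maximum DAB optical density (in the H-DAB stain-matrix units
#: used by scikit-image) mapped onto pixel value 0.  Kept modest so that
#: the full intensity range survives an 8-bit RGB round trip.
DEFAULT_DAB_OD_MAX = 0.3


@dataclass(frozen=True)
class IntensityImage:
    """Scalar DAB-intensity map; lower values = stronger brown staining."""

    values: np.ndarray  # 2D uint8
    pixel_size_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise FormatError("intensity image must be 2D")
        if v.min(initial=0) < 0 or v.max(initial=0) > 255:
            raise FormatError("intensity values must lie in [0, 255]")
        if not self.pixel_size_um > 0:
            raise FormatError("pixel_size_um must be positive")
        object.__setattr__(self, "values", v.astype(np.uint8))


@dataclass(frozen=True)
class RegionOfInterest:
    """Boolean pixel mask tagged with a tissue compartment."""

    mask: np.ndarray  # 2D bool, congruent with the image
    compartment: str
    sample_id: str = ""
    species: str = ""
    entity: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise FormatError("ROI mask must be 2D")
        if not m.any():
            raise DegenerateRoiError("ROI mask is empty")
        if self.compartment not in COMPARTMENTS:
            raise FormatError(f"unknown compartment {self.compartment!r}")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class QuantResult:
    """Per-ROI area measurements and mean staining intensity.

    All areas are in µm².  ``level_areas`` maps level 0-4 to raw area;
    ``normalized_areas`` rescales each level (and the positive total) to
    the standard 2.37 mm² (10 HPF) reference area.  ``mean_intensity`` is
    the arithmetic mean pixel value over the pixels it was computed on.
    """

    level_areas: dict[int, float]
    artifact_area: float
    roi_area: float
    total_positive_area: float
    normalized_areas: dict[int, float]
    normalized_total: float
    mean_intensity: float
    sample_id: str = ""
    compartment: str = ""
    species: str = ""
    entity: str = ""


def compute_intensity_image(
    image: np.ndarray,
    pixel_size_um: float = 1.0,
    method: str = "hdab",
    dab_od_max: float = DEFAULT_DAB_OD_MAX,
) -> IntensityImage:
    """Derive the scalar DAB-intensity map from an input image.

    The default ``hdab`` method separates the DAB channel by standard
    H-DAB stain unmixing (color deconvolution) and maps optical density
    linearly onto [0, 255], inverted so that denser brown gives a lower
    pixel value; a pure white pixel maps to 255.  ``passthrough`` accepts
    a single-channel image unchanged (used for synthetic intensity maps).

    The mapping is monotone: higher DAB optical density never yields a
    higher pixel value.
    """
    arr = np.asarray(image)
    if method == "passthrough":
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[..., 0]
        if arr.ndim != 2:
            raise FormatError("passthrough mode requires a single-channel image")
        return IntensityImage(arr, pixel_size_um)
    if method != "hdab":
        raise ConfigurationError(f"unknown intensity method {method!r}")
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError("hdab method requires an 8-bit RGB image")
    rgb = arr[..., :3].astype(np.float64) / 255.0
    dab = rgb2hed(rgb)[..., 2]
    od = np.clip(dab, 0.0, dab_od_max)
    values = np.rint(255.0 * (1.0 - od / dab_od_max)).astype(np.uint8)
    return IntensityImage(values, pixel_size_um)


def classify_levels(
    img: IntensityImage, thresholds: LevelThresholds | None = None
) -> np.ndarray:
    """Assign each pixel its staining-intensity level (0-4).

    Every pixel value belongs to exactly one of the five closed bands; the
    thresholds object guarantees disjoint full coverage of [0, 255].
    """
    thresholds = thresholds or LevelThresholds()
    lut = np.empty(256, dtype=np.uint8)
    lut.fill(255)  # sentinel, unreachable for valid thresholds
    for level, (lo, hi) in thresholds.intervals().items():
        lut[lo : hi + 1] = level
    if (lut == 255).any():
        raise ConfigurationError("thresholds do not cover [0, 255]")
    return lut[img.values]


def detect_artifacts(
    rgb_image: np.ndarray,
    roi: RegionOfInterest | None = None,
    white_threshold: int = 250,
    black_threshold: int = 10,
) -> np.ndarray:
    """Rule-based artifact mask.

    Flags saturated-white glass (all channels >= ``white_threshold``),
    near-black debris (all channels <= ``black_threshold``), and the
    reserved synthetic artifact color.  Single-channel images are checked
    against the white/black rules only.
    """
    arr = np.asarray(rgb_image)
    if arr.ndim == 2:
        mask = (arr >= white_threshold) | (arr <= black_threshold)
    else:
        rgb = arr[..., :3]
        white = (rgb >= white_threshold).all(axis=-1)
        black = (rgb <= black_threshold).all(axis=-1)
        reserved = (rgb == np.array(ARTIFACT_RGB)).all(axis=-1)
        mask = white | black | reserved
    if roi is not None:
        if roi.mask.shape != mask.shape:
            raise FormatError("ROI mask not congruent with image")
        mask = mask & roi.mask
    return mask


def measure_roi(
    img: IntensityImage,
    roi: RegionOfInterest,
    thresholds: LevelThresholds | None = None,
    artifact_mask: np.ndarray | None = None,
    ten_hpf_area_um2: float = TEN_HPF_AREA_UM2,
    mi_positive_only: bool = False,
) -> QuantResult:
    """Measure per-level stained areas and mean intensity inside one ROI.

    Areas are pixel counts times the physical pixel area.  Artifact pixels
    are excluded from every level and from the mean intensity; the
    normalization rescales to the standard 2.37 mm² using the artifact-free
    ROI area as denominator, so positivity is not diluted by non-tissue.

    Raises :class:`DegenerateRoiError` when the ROI is entirely artifact
    (mean intensity undefined).
    """
    thresholds = thresholds or LevelThresholds()
    if img.values.shape != roi.mask.shape:
        raise FormatError("image and ROI mask are not congruent")
    if artifact_mask is None:
        artifact_mask = np.zeros_like(roi.mask)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != roi.mask.shape:
        raise FormatError("artifact mask not congruent with ROI")

    px_area = img.pixel_size_um**2
    in_roi = roi.mask
    artifact_in_roi = in_roi & artifact_mask
    tissue = in_roi & ~artifact_mask
    if not tissue.any():
        raise DegenerateRoiError(
            f"ROI {roi.sample_id}/{roi.compartment} is entirely artifact"
        )

    levels = classify_levels(img, thresholds)
    counts = np.bincount(levels[tissue].astype(np.int64), minlength=5)[:5]
    level_areas = {lvl: float(counts[lvl]) * px_area for lvl in range(5)}
    artifact_area = float(artifact_in_roi.sum()) * px_area
    roi_area = float(in_roi.sum()) * px_area
    total_positive = float(sum(level_areas[lvl] for lvl in range(1, 5)))

    tissue_area = roi_area - artifact_area
    scale = ten_hpf_area_um2 / tissue_area
    normalized = {lvl: a * scale for lvl, a in level_areas.items()}

    if mi_positive_only:
        mi_pixels = tissue & (levels >= 1)
        if not mi_pixels.any():
            mi = float("nan")
        else:
            mi = float(img.values[mi_pixels].mean())
    else:
        mi = float(img.values[tissue].mean())

    return QuantResult(
        level_areas=level_areas,
        artifact_area=artifact_area,
        roi_area=roi_area,
        total_positive_area=total_positive,
        normalized_areas=normalized,
        normalized_total=total_positive * scale,
        mean_intensity=mi,
        sample_id=roi.sample_id,
        compartment=roi.compartment,
        species=roi.species,
        entity=roi.entity,
    )
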