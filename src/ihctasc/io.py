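"""File-format plumbing: images, label masks, tables, manifests.

Images are 8-bit RGB TIFF or PNG; ROI masks are single-channel label PNGs
whose integer codes follow :data:`ihctasc.config.COMPARTMENT_CODES`
(0 = outside any ROI); tables are plain CSV.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
import tifffile

from .config import COMPARTMENT_CODES, COMPARTMENTS
from .errors import FormatError
from .quant import RegionOfInterest


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path))


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    arr = np.asarray(labels, dtype=np.uint8)
    if arr.ndim != 2:
        raise FormatError("label mask must be single-channel")
    Image.fromarray(arr, mode="L").save(path)


def read_label_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-channel")
    return arr


def rois_from_label_mask(
    labels: np.ndarray, sample_id: str = "", species: str = "", entity: str = ""
) -> list[RegionOfInterest]:
    """Split a label mask into one ROI per compartment code present."""
    labels = np.asarray(labels)
    rois = []
    for name in COMPARTMENTS:
        code = COMPARTMENT_CODES[name]
        mask = labels == code
        if mask.any():
            rois.append(
                RegionOfInterest(
                    mask=mask,
                    compartment=name,
                    sample_id=sample_id,
                    species=species,
                    entity=entity,
                )
            )
    return rois


def load_sts_criterion_inputs() -> pd.DataFrame:
    """Bundled per-group TASC criterion inputs for the cross-species
    soft-tissue-sarcoma cohorts (counts plus reported overexpression
    percentages, one row per entity or species total)."""
    with resources.files("ihctasc").joinpath(
        "data/tasc_criterion_inputs_sts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, entries: dict) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True))
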