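"""Radiomic feature extraction: the 107-feature catalog.

Class counts: 14 shape, 18 first order, 24 GLCM, 16 GLRLM, 16 GLSZM,
5 NGTDM, 14 GLDM.  Extraction applies optional SUV conversion, fixed-bin-width
discretization (default 0.25 SUV) anchored at the ROI minimum, and no
resampling or image filters.  Feature names are prefixed with their class,
e.g. ``firstorder_Energy`` or ``glcm_Imc2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grids import BinaryMask, ImageVolume, check_congruent
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .preprocess import DiscretizationSpec, SUVParams, discretize, to_suv
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "CLASS_COUNTS",
    "FEATURE_NAMES",
    "ExtractionConfig",
    "FeatureVector",
    "DiscretizationSpec",
    "SUVParams",
    "discretize",
    "to_suv",
    "extract_all",
    "firstorder_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

CLASS_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "gldm": 14,
}

_CLASS_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

FEATURE_NAMES: list[str] = [
    f"{cls}_{name}" for cls, names in _CLASS_NAMES.items() for name in names
]
assert len(FEATURE_NAMES) == 107


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings: optional SUV conversion and the discretization."""

    bin_width: float = 0.25
    suv: SUVParams | None = None
    gldm_alpha: int = 0


@dataclass
class FeatureVector:
    """107 named feature values with per-feature validity flags.

    Invalid features (degenerate geometry or a single gray level) carry NaN
    and ``valid[name] == False``; they are never silently zero.
    """

    values: dict[str, float]
    valid: dict[str, bool]

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 107 catalog features")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def extract_all(
    image: ImageVolume, mask: BinaryMask, config: ExtractionConfig | None = None
) -> FeatureVector:
    """Extract the full 107-feature vector from one image/mask pair.

    A single-voxel mask yields valid shape-volume and first-order features
    while all texture features are flagged invalid (no voxel pairs exist).
    """
    config = config or ExtractionConfig()
    check_congruent(image, mask)
    if mask.is_empty():
        raise ValueError("mask is empty")

    if config.suv is not None:
        image = to_suv(image, config.suv)
    d = DiscretizationSpec(bin_width=config.bin_width)

    values: dict[str, float] = {}
    valid: dict[str, bool] = {}

    shp, shp_invalid = shape_features(mask)
    fo = firstorder_features(image, mask, d)

    labels, n_levels = discretize(image, mask, d)
    single_voxel = mask.n_voxels < 2
    if single_voxel:
        texture_results = {
            cls: ({n: np.nan for n in names}, set(names))
            for cls, names in _CLASS_NAMES.items()
            if cls not in ("shape", "firstorder")
        }
    else:
        arr = mask.data
        texture_results = {
            "glcm": glcm_features(labels, arr, n_levels),
            "glrlm": glrlm_features(labels, arr, n_levels),
            "glszm": glszm_features(labels, arr, n_levels),
            "ngtdm": ngtdm_features(labels, arr, n_levels),
            "gldm": gldm_features(labels, arr, n_levels, config.gldm_alpha),
        }

    for name in SHAPE_NAMES:
        values[f"shape_{name}"] = shp[name]
        valid[f"shape_{name}"] = name not in shp_invalid
    for name in FIRSTORDER_NAMES:
        values[f"firstorder_{name}"] = fo[name]
        valid[f"firstorder_{name}"] = True
    for cls, (vals, invalid) in texture_results.items():
        for name in _CLASS_NAMES[cls]:
            values[f"{cls}_{name}"] = vals[name]
            valid[f"{cls}_{name}"] = name not in invalid

    ordered = {n: values[n] for n in FEATURE_NAMES}
    return FeatureVector(values=ordered, valid={n: valid[n] for n in FEATURE_NAMES})
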