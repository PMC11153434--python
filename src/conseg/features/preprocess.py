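"""SUV conversion and fixed-bin-width gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import BinaryMask, ImageVolume, check_congruent

__all__ = ["SUVParams", "DiscretizationSpec", "to_suv", "discretize"]


@dataclass(frozen=True)
class SUVParams:
    """Standardized-uptake-value normalization: SUV = concentration * weight / dose.

    Dose and weight must be given in mutually consistent units (the usual
    clinical convention cancels to a dimensionless SUV).
    """

    injected_dose: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-width discretization anchored at the ROI minimum.

    label(x) = floor((x - min_ROI) / bin_width) + 1; the default width is
    0.25 SUV.
    """

    bin_width: float = 0.25

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def to_suv(image: ImageVolume, p: SUVParams) -> ImageVolume:
    """Convert a concentration image to SUV; linear in the input."""
    return ImageVolume(image.data * (p.body_weight / p.injected_dose), image.spacing)


def discretize(
    image: ImageVolume, roi: BinaryMask, d: DiscretizationSpec | None = None
) -> tuple[np.ndarray, int]:
    """Bin ROI intensities into integer gray levels 1..n_levels.

    Returns an integer label volume (0 outside the ROI) and the number of
    levels.  The top intensity is clamped into the last bin against floating
    point fuzz at the bin edge.
    """
    d = d or DiscretizationSpec()
    check_congruent(image, roi)
    if roi.is_empty():
        raise ValueError("ROI is empty")
    vals = image.data[roi.data]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside the ROI")
    mn = vals.min()
    n_levels = int(np.floor((vals.max() - mn) / d.bin_width)) + 1
    labels = np.zeros(image.shape, dtype=np.int32)
    lab = np.floor((vals - mn) / d.bin_width).astype(np.int32) + 1
    np.clip(lab, 1, n_levels, out=lab)
    labels[roi.data] = lab
    return labels, n_levels
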