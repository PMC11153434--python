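"""The 18 first-order intensity statistics.

Definitions follow the public radiomics catalog the wider field uses as a
reference implementation: Energy is the plain sum of squares, TotalEnergy is
Energy scaled by the voxel volume, Kurtosis is *not* excess kurtosis, and
Entropy/Uniformity are computed on the discretized gray-level histogram.
Moment ratios of a constant ROI (Skewness, Kurtosis) are defined as 0.
"""

from __future__ import annotations

import numpy as np

from ..grids import BinaryMask, ImageVolume, check_congruent
from .preprocess import DiscretizationSpec, discretize

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "MeanAbsoluteDeviation",
    "Mean",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]

_EPS = np.spacing(1.0)


def firstorder_features(
    image: ImageVolume,
    roi: BinaryMask,
    d: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """Compute the 18 first-order statistics over the ROI intensities."""
    check_congruent(image, roi)
    if roi.is_empty():
        raise ValueError("ROI is empty")
    x = image.data[roi.data].astype(np.float64)
    n = x.size
    voxvol = image.voxel_volume

    labels, n_levels = discretize(image, roi, d)
    counts = np.bincount(labels[roi.data], minlength=n_levels + 1)[1:]
    p = counts / n

    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(((x - mean) ** 2).mean())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float((((x - mean) / sd) ** 3).mean())
        kurt = float((((x - mean) / sd) ** 4).mean())
    else:
        skew = 0.0
        kurt = 0.0
    robust = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())

    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-(p[p > 0] * np.log2(p[p > 0] + _EPS)).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "TotalEnergy": voxvol * energy,
        "Uniformity": float((p**2).sum()),
        "Variance": var,
    }
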