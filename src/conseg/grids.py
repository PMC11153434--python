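"""Basic spatial containers: scalar image volumes and binary masks on a voxel grid.

All volumes use (z, y, x) axis order with voxel spacing given in cm per axis,
matching a PET acquisition with slice thickness on the first axis and the
in-plane matrix on the last two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "ImageVolume", "BinaryMask", "check_congruent"]


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry: counts per axis and edge lengths in cm per axis."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(int(s) < 8 for s in self.shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {self.shape}")
        if any(not (sp > 0) for sp in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing))


@dataclass
class ImageVolume:
    """A 3-D scalar field (e.g. activity or SUV) with voxel spacing in cm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing)


@dataclass
class BinaryMask:
    """A boolean voxel set aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def contains(self, other: "BinaryMask") -> bool:
        """True if every voxel of *other* is also in this mask."""
        check_congruent(self, other)
        return bool(np.all(~other.data | self.data))

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.spacing)


def check_congruent(*vols: ImageVolume | BinaryMask) -> None:
    """Raise ValueError unless all volumes share shape and spacing (to 1e-6 cm)."""
    if not vols:
        return
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise ValueError(f"incongruent grids: shapes {v.shape} vs {ref.shape}")
        if not np.allclose(v.spacing, ref.spacing, atol=1e-6):
            raise ValueError(
                f"incongruent grids: spacings {v.spacing} vs {ref.spacing}"
            )
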