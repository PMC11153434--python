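"""NIfTI input/output and JSON configuration handling.

Volumes are stored with the affine encoding voxel spacing in mm (the NIfTI
convention); the in-memory containers carry spacing in cm, so spacing is
multiplied by 10 on write and divided by 10 on read.  Masks round-trip
bit-exactly as uint8.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import BinaryMask, ImageVolume

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask", "dump_json"]


def _affine(spacing_cm) -> np.ndarray:
    aff = np.eye(4)
    # array axes (z, y, x) map to NIfTI (x, y, z) via transposition on write
    aff[0, 0], aff[1, 1], aff[2, 2] = (s * 10.0 for s in spacing_cm[::-1])
    return aff


def write_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume (float) or mask (uint8) to a NIfTI file."""
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(vol.spacing))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    spacing_cm = tuple(float(z) / 10.0 for z in zooms[::-1])
    return data, spacing_cm  # type: ignore[return-value]


def read_volume(path: str | Path) -> ImageVolume:
    data, spacing = _load(path)
    return ImageVolume(data.astype(np.float64), spacing)


def read_mask(path: str | Path) -> BinaryMask:
    data, spacing = _load(path)
    return BinaryMask(data > 0, spacing)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_Encoder))
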