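"""Synthetic PET phantoms with known ground truth.

Emulates a static thoracic digital-phantom experiment at desk scale: a body
background, a low-uptake lung region, and an ellipsoidal tumor with smoothly
heterogeneous uptake are rendered on a 200x200 in-plane grid with
0.50 x 0.41 x 0.41 cm voxels; system blur is modelled by a Gaussian PSF and
count noise by scaled Poisson sampling.  Tomographic projection/reconstruction
is deliberately out of scope -- the ground truth is the noise-free voxelized
ellipsoid, independent of any segmentation.

The default suite is 13 tumors whose ground-truth volumes span
3.45-56.40 cm^3 with post-simulation SUVmax around 4.6-7.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, GridSpec, ImageVolume, check_congruent

__all__ = [
    "TumorSpec",
    "DistractorSpec",
    "AcquisitionSpec",
    "MaskParams",
    "SuiteConfig",
    "PhantomCase",
    "make_activity",
    "simulate_pet",
    "make_initial_masks",
    "generate_suite",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = GridSpec(shape=(40, 200, 200), spacing=(0.50, 0.41, 0.41))


@dataclass
class TumorSpec:
    """An ellipsoidal tumor with smooth intra-tumor uptake texture.

    center is in voxel coordinates (z, y, x); radii are semi-axes in cm.
    With het_amplitude = 0 every tumor voxel equals uptake_base exactly.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    uptake_base: float
    het_amplitude: float = 0.15
    het_corr_length: float = 0.6  # cm
    rng_seed: int = 0


@dataclass
class DistractorSpec:
    """Optional nearby high-uptake blob (e.g. a hot node) outside the tumor."""

    center: tuple[float, float, float]  # voxel coordinates
    radius_cm: float
    uptake: float


@dataclass
class AcquisitionSpec:
    """Imaging-chain surrogate: PSF blur, scaled-Poisson noise, backgrounds.

    noise_scale sets the variance of a voxel to noise_scale * blurred value,
    so empirical voxel variance grows linearly with it; 0 disables noise.
    """

    psf_fwhm: float = 6.0  # mm
    noise_scale: float = 0.01
    background_uptake: float = 1.0
    lung_uptake: float = 0.4
    hot_distractor: DistractorSpec | None = None

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class MaskParams:
    """Parameters for the two initial-mask styles."""

    rect_margin: int = 3  # voxels beyond the GT bounding box
    irreg_radius: float = 2.0  # dilation radius in voxels
    perturb_amplitude: float = 1.0  # voxels, boundary roughness
    perturb_sigma: float = 2.0  # voxels, roughness correlation length
    exclude_distractor: bool = True


def _coord_grids_cm(shape, spacing):
    axes = [np.arange(n, dtype=np.float64) * sp for n, sp in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(grid: GridSpec, center_vox, radii_cm) -> np.ndarray:
    zz, yy, xx = _coord_grids_cm(grid.shape, grid.spacing)
    c = [cv * sp for cv, sp in zip(center_vox, grid.spacing)]
    q = (
        ((zz - c[0]) / radii_cm[0]) ** 2
        + ((yy - c[1]) / radii_cm[1]) ** 2
        + ((xx - c[2]) / radii_cm[2]) ** 2
    )
    return q <= 1.0


def make_activity(
    grid: GridSpec, tumor: TumorSpec, acq: AcquisitionSpec
) -> tuple[ImageVolume, BinaryMask]:
    """Render the noise-free activity map and exact voxel ground truth.

    The tumor is an ellipsoid (voxel centers inside count as tumor) placed in
    a low-uptake lung-like region on a body background.  Intra-tumor texture
    is uptake_base * (1 + het_amplitude * (core/rim profile + smoothed seeded
    Gaussian field)); amplitude 0 gives a perfectly flat tumor.
    """
    if tumor.uptake_base <= acq.background_uptake:
        raise ValueError("tumor uptake_base must exceed the background uptake")
    # require a 2-voxel margin between the tumor ellipsoid and the grid edge
    for ax in range(3):
        r_vox = tumor.radii[ax] / grid.spacing[ax]
        lo = tumor.center[ax] - r_vox
        hi = tumor.center[ax] + r_vox
        if lo < 2 or hi > grid.shape[ax] - 3:
            raise ValueError(
                f"tumor does not fit inside the grid with a 2-voxel margin on "
                f"axis {ax}: extent [{lo:.1f}, {hi:.1f}] in a {grid.shape[ax]}-voxel axis"
            )

    gt = _ellipsoid_mask(grid, tumor.center, tumor.radii)

    act = np.full(grid.shape, acq.background_uptake, dtype=np.float64)
    lung_radii = tuple(r + 2.5 for r in tumor.radii)
    lung = _ellipsoid_mask(grid, tumor.center, lung_radii)
    act[lung] = acq.lung_uptake

    if tumor.het_amplitude > 0:
        zz, yy, xx = _coord_grids_cm(grid.shape, grid.spacing)
        c = [cv * sp for cv, sp in zip(tumor.center, grid.spacing)]
        rnorm2 = (
            ((zz - c[0]) / tumor.radii[0]) ** 2
            + ((yy - c[1]) / tumor.radii[1]) ** 2
            + ((xx - c[2]) / tumor.radii[2]) ** 2
        )
        core_rim = 0.5 - rnorm2  # brighter core, dimmer rim, zero-mean-ish
        rng = np.random.default_rng(tumor.rng_seed)
        noise = rng.standard_normal(grid.shape)
        sig = [tumor.het_corr_length / sp for sp in grid.spacing]
        field_ = ndimage.gaussian_filter(noise, sigma=sig)
        sd = field_[gt].std()
        if sd > 0:
            field_ = field_ / sd
        texture = np.clip(0.5 * core_rim + 0.8 * field_, -1.5, 1.5)
        tumor_vals = tumor.uptake_base * (1.0 + tumor.het_amplitude * texture[gt])
        act[gt] = np.clip(tumor_vals, 0.2, None)
    else:
        act[gt] = tumor.uptake_base

    if acq.hot_distractor is not None:
        d = acq.hot_distractor
        dmask = _ellipsoid_mask(grid, d.center, (d.radius_cm,) * 3)
        if (dmask & gt).any():
            raise ValueError("hot distractor overlaps the tumor ground truth")
        act[dmask] = d.uptake

    return ImageVolume(act, grid.spacing), BinaryMask(gt, grid.spacing)


def simulate_pet(
    activity: ImageVolume, acq: AcquisitionSpec, seed: int | None = 0
) -> ImageVolume:
    """Apply Gaussian PSF blur then scaled-Poisson noise.

    With noise_scale s > 0, a voxel with blurred value b is drawn as
    s * Poisson(b / s), so its mean is b and its variance is s * b.
    noise_scale = 0 returns the blurred image exactly.
    """
    data = activity.data
    if np.any(data < 0):
        raise ValueError("activity must be non-negative")
    if not (np.isfinite(acq.psf_fwhm) and np.isfinite(acq.noise_scale)):
        raise ValueError("psf_fwhm and noise_scale must be finite")
    if acq.psf_fwhm > 0:
        fwhm_cm = acq.psf_fwhm / 10.0
        sigma_vox = [fwhm_cm / 2.354820045 / sp for sp in activity.spacing]
        blurred = ndimage.gaussian_filter(data, sigma=sigma_vox)
        np.clip(blurred, 0.0, None, out=blurred)
    else:
        blurred = data.copy()
    if acq.noise_scale == 0:
        return ImageVolume(blurred, activity.spacing)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(blurred / acq.noise_scale).astype(np.float64) * acq.noise_scale
    return ImageVolume(noisy, activity.spacing)


def make_initial_masks(
    gt: BinaryMask,
    style: Literal["rectangular", "irregular"],
    params: MaskParams | None = None,
    seed: int | None = 0,
    distractor: BinaryMask | None = None,
) -> BinaryMask:
    """Build a loose user-style initial mask around the ground truth.

    rectangular: GT bounding box dilated by rect_margin voxels (clipped at the
    grid edge with a logged warning).  irregular: GT dilated by irreg_radius
    voxels with a seeded smooth boundary perturbation, minus any distractor
    region; ground truth is always contained (when the distractor does not
    overlap it).
    """
    if gt.is_empty():
        raise ValueError("ground-truth mask is empty")
    params = params or MaskParams()

    if style == "rectangular":
        idx = np.argwhere(gt.data)
        lo = idx.min(axis=0) - params.rect_margin
        hi = idx.max(axis=0) + params.rect_margin + 1
        clipped_lo = np.maximum(lo, 0)
        clipped_hi = np.minimum(hi, gt.shape)
        if np.any(lo < 0) or np.any(hi > gt.shape):
            logger.warning("rectangular mask clipped at the grid edge")
        out = np.zeros(gt.shape, dtype=bool)
        out[tuple(slice(a, b) for a, b in zip(clipped_lo, clipped_hi))] = True
    elif style == "irregular":
        dist = ndimage.distance_transform_edt(~gt.data)
        rng = np.random.default_rng(seed)
        perturb = ndimage.gaussian_filter(
            rng.standard_normal(gt.shape), sigma=params.perturb_sigma
        )
        sd = perturb.std()
        if sd > 0:
            perturb *= params.perturb_amplitude / sd
        out = dist <= (params.irreg_radius + perturb)
        out |= gt.data
    else:
        raise ValueError(f"unknown initial-mask style: {style!r}")

    if distractor is not None and params.exclude_distractor:
        check_congruent(gt, distractor)
        out &= ~distractor.data

    mask = BinaryMask(out, gt.spacing)
    if distractor is None or not params.exclude_distractor:
        assert mask.contains(gt)
    return mask


@dataclass
class SuiteConfig:
    """Study conditions for the synthetic suite (defaults mirror the target
    experiment: 13 static lung tumors, 200x200 in-plane matrix)."""

    n_cases: int = 13
    grid: GridSpec = field(default_factory=lambda: DEFAULT_GRID)
    volume_range: tuple[float, float] = (3.8, 54.0)  # cm^3, sampled band
    uptake_range: tuple[float, float] = (4.7, 5.9)  # SUV-like
    het_amplitude: float = 0.15
    het_corr_length: float = 0.6
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    mask_params: MaskParams = field(default_factory=MaskParams)


@dataclass
class PhantomCase:
    """One simulated case: PET image, ground truth, and both initial masks."""

    case_id: str
    image: ImageVolume
    gt_mask: BinaryMask
    rect_mask: BinaryMask
    irreg_mask: BinaryMask
    provenance: dict

    def __post_init__(self) -> None:
        check_congruent(self.image, self.gt_mask, self.rect_mask, self.irreg_mask)
        if not (self.rect_mask.contains(self.gt_mask) and self.irreg_mask.contains(self.gt_mask)):
            raise ValueError("initial masks must contain the ground truth")


def generate_suite(config: SuiteConfig | None = None, seed: int = 0) -> list[PhantomCase]:
    """Generate the seeded phantom suite (default 13 cases).

    Target tumor volumes are spaced log-uniformly across the configured
    volume band so the suite spans it; per-case seeds are derived
    deterministically from the master seed.
    """
    config = config or SuiteConfig()
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=(config.n_cases, 4))

    vmin, vmax = config.volume_range
    if config.n_cases == 1:
        targets = np.array([np.sqrt(vmin * vmax)])
    else:
        targets = np.exp(np.linspace(np.log(vmin), np.log(vmax), config.n_cases))

    grid = config.grid
    cases: list[PhantomCase] = []
    for i, (vol, seeds) in enumerate(zip(targets, case_seeds)):
        rng = np.random.default_rng(seeds[0])
        r_iso = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        f1, f2 = rng.uniform(0.85, 1.18, size=2)
        radii = (r_iso * f1, r_iso * f2, r_iso / (f1 * f2))
        # center placement: keep the ellipsoid (and the lung halo) inside
        center = []
        for ax in range(3):
            r_vox = radii[ax] / grid.spacing[ax]
            lo, hi = r_vox + 4, grid.shape[ax] - r_vox - 5
            center.append(float(rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))))
        uptake = float(rng.uniform(*config.uptake_range))
        tumor = TumorSpec(
            center=tuple(center),
            radii=radii,
            uptake_base=uptake,
            het_amplitude=config.het_amplitude,
            het_corr_length=config.het_corr_length,
            rng_seed=int(seeds[1]),
        )
        activity, gt = make_activity(grid, tumor, config.acquisition)
        image = simulate_pet(activity, config.acquisition, seed=int(seeds[2]))
        rect = make_initial_masks(gt, "rectangular", config.mask_params, seed=int(seeds[3]))
        irreg = make_initial_masks(gt, "irregular", config.mask_params, seed=int(seeds[3]))
        cases.append(
            PhantomCase(
                case_id=f"case{i:02d}",
                image=image,
                gt_mask=gt,
                rect_mask=rect,
                irreg_mask=irreg,
                provenance={
                    "tumor": asdict(tumor),
                    "acquisition": asdict(config.acquisition),
                    "mask_params": asdict(config.mask_params),
                    "seeds": [int(s) for s in seeds],
                    "master_seed": int(seed),
                    "target_volume_cm3": float(vol),
                },
            )
        )
    return cases
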