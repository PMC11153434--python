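"""Shared fixtures: small synthetic volumes used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from conseg.grids import BinaryMask, GridSpec, ImageVolume
from conseg.phantom import (
    AcquisitionSpec,
    MaskParams,
    SuiteConfig,
    TumorSpec,
    generate_suite,
    make_activity,
    make_initial_masks,
    simulate_pet,
)

SPACING = (0.5, 0.41, 0.41)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(shape=(24, 64, 64), spacing=SPACING)


@pytest.fixture(scope="session")
def small_case(small_grid):
    """One simulated case on a small grid: (image, gt, rect, irreg)."""
    tumor = TumorSpec(
        center=(12.0, 32.0, 32.0), radii=(1.4, 1.3, 1.5), uptake_base=5.5, rng_seed=7
    )
    acq = AcquisitionSpec()
    activity, gt = make_activity(small_grid, tumor, acq)
    image = simulate_pet(activity, acq, seed=11)
    rect = make_initial_masks(gt, "rectangular", MaskParams(), seed=3)
    irreg = make_initial_masks(gt, "irregular", MaskParams(), seed=3)
    return image, gt, rect, irreg


@pytest.fixture
def two_level():
    """Sharp two-level toy: tumor 8.0 in a 1.0 background, full-grid init."""
    data = np.ones((10, 12, 12))
    data[3:7, 4:9, 4:9] = 8.0
    img = ImageVolume(data, SPACING)
    init = BinaryMask(np.ones_like(data, dtype=bool), SPACING)
    tumor = BinaryMask(data == 8.0, SPACING)
    return img, init, tumor


@pytest.fixture(scope="session")
def tiny_suite_config() -> SuiteConfig:
    """A 3-case suite on a reduced grid for fast end-to-end tests."""
    return SuiteConfig(
        n_cases=3,
        grid=GridSpec(shape=(16, 48, 48), spacing=SPACING),
        volume_range=(3.8, 7.5),
    )


@pytest.fixture(scope="session")
def tiny_suite(tiny_suite_config):
    return generate_suite(tiny_suite_config, seed=5)
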