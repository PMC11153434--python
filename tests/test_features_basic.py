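"""Feature extraction: SUV conversion, discretization, first-order and shape
values, catalog structure, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conseg.features import (
    CLASS_COUNTS,
    FEATURE_NAMES,
    DiscretizationSpec,
    ExtractionConfig,
    SUVParams,
    discretize,
    extract_all,
    to_suv,
)
from conseg.features.firstorder import firstorder_features
from conseg.features.shape import shape_features
from conseg.grids import BinaryMask, ImageVolume

SPACING = (0.5, 0.41, 0.41)
VOXVOL = float(np.prod(SPACING))


def _vol(data):
    return ImageVolume(np.asarray(data, dtype=float), SPACING)


def _roi_with_values(values):
    """Embed a flat list of values into a 3-D volume with a matching ROI."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    data = np.zeros((3, 3, max(3, n)))
    data[1, 1, :n] = values
    roi = np.zeros_like(data, dtype=bool)
    roi[1, 1, :n] = True
    return _vol(data), BinaryMask(roi, SPACING)


class TestSUV:
    def test_dose_equals_weight_is_identity(self):
        img = _vol(np.random.default_rng(0).random((4, 4, 4)))
        out = to_suv(img, SUVParams(injected_dose=70.0, body_weight=70.0))
        assert np.allclose(out.data, img.data)

    def test_doubling_dose_halves_values(self):
        img = _vol(np.full((4, 4, 4), 6.0))
        a = to_suv(img, SUVParams(injected_dose=5.0, body_weight=70.0))
        b = to_suv(img, SUVParams(injected_dose=10.0, body_weight=70.0))
        assert np.allclose(a.data, 2 * b.data)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            SUVParams(injected_dose=0.0, body_weight=70.0)
        with pytest.raises(ValueError):
            SUVParams(injected_dose=5.0, body_weight=-1.0)


class TestDiscretize:
    def test_bin_edge_arithmetic(self):
        img, roi = _roi_with_values([0.0, 0.1, 0.3, 0.6])
        labels, n_levels = discretize(img, roi, DiscretizationSpec(0.25))
        assert list(labels[roi.data]) == [1, 1, 2, 3]
        assert n_levels == 3

    def test_single_voxel_one_level(self):
        img, roi = _roi_with_values([4.2])
        labels, n_levels = discretize(img, roi)
        assert n_levels == 1 and labels[roi.data][0] == 1

    def test_default_width_is_quarter_suv(self):
        assert DiscretizationSpec().bin_width == 0.25

    def test_nonfinite_rejected(self):
        img, roi = _roi_with_values([1.0, np.nan])
        with pytest.raises(ValueError):
            discretize(img, roi)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=30),
        width=st.floats(0.05, 2.0),
    )
    def test_labels_start_at_one_and_are_bounded(self, vals, width):
        img, roi = _roi_with_values(vals)
        labels, n_levels = discretize(img, roi, DiscretizationSpec(width))
        inside = labels[roi.data]
        assert inside.min() == 1
        assert inside.max() <= n_levels
        assert (labels[~roi.data] == 0).all()


class TestFirstOrder:
    def test_direct_arithmetic_on_tiny_roi(self):
        img, roi = _roi_with_values([1.0, 2.0, 3.0])
        fo = firstorder_features(img, roi)
        assert fo["Energy"] == pytest.approx(14.0)
        assert fo["Maximum"] == 3.0
        assert fo["Minimum"] == 1.0
        assert fo["Mean"] == pytest.approx(2.0)
        assert fo["Range"] == pytest.approx(2.0)

    def test_total_energy_is_energy_times_voxel_volume(self):
        rng = np.random.default_rng(3)
        img, roi = _roi_with_values(rng.random(20) * 5)
        fo = firstorder_features(img, roi)
        assert fo["TotalEnergy"] == pytest.approx(fo["Energy"] * VOXVOL)

    def test_90th_percentile_matches_sort_oracle(self):
        vals = np.arange(1.0, 101.0)
        img, roi = _roi_with_values(vals)
        fo = firstorder_features(img, roi)
        # linear interpolation between order statistics
        s = np.sort(vals)
        pos = 0.9 * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expect = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert fo["90Percentile"] == pytest.approx(expect)

    def test_constant_roi_moments_defined(self):
        img, roi = _roi_with_values([2.0] * 10)
        fo = firstorder_features(img, roi)
        assert fo["Variance"] == 0.0
        assert fo["Skewness"] == 0.0
        assert fo["Uniformity"] == 1.0


class TestShape:
    def test_cuboid_mesh_volume(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:8, 2:9, 2:10] = True  # 6 x 7 x 8 voxels
        shp, invalid = shape_features(BinaryMask(mask, SPACING))
        expect = 6 * 7 * 8 * VOXVOL
        # the mesh passes through the voxel faces but chamfers the 12 edges,
        # so the mesh volume sits a few percent below the exact cuboid volume
        assert abs(shp["MeshVolume"] - expect) <= 0.05 * expect
        assert shp["MeshVolume"] < expect
        assert shp["VoxelVolume"] == pytest.approx(expect)
        assert not invalid

    def test_sphere_sphericity_near_isoperimetric_bound(self):
        iso = (0.5, 0.5, 0.5)
        for r in (2.5, 4.5, 6.5):
            n = 16
            zz, yy, xx = np.mgrid[:n, :n, :n]
            mask = (zz - n / 2) ** 2 + (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= r**2
            shp, _ = shape_features(BinaryMask(mask, iso))
            assert 0.85 <= shp["Sphericity"] <= 1.0

    def test_exactly_14_values(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        shp, _ = shape_features(BinaryMask(mask, SPACING))
        assert len(shp) == 14

    def test_single_voxel_flags_degenerate_not_crash(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4, 4, 4] = True
        shp, invalid = shape_features(BinaryMask(mask, SPACING))
        assert "Elongation" in invalid
        assert np.isfinite(shp["VoxelVolume"])


class TestExtractAll:
    def test_catalog_structure(self, small_case):
        img, gt, _, _ = small_case
        fv = extract_all(img, gt)
        assert len(fv) == 107
        for cls, count in CLASS_COUNTS.items():
            assert sum(1 for n in fv.values if n.startswith(cls + "_")) == count

    def test_flip_invariance(self, small_case):
        img, gt, _, _ = small_case
        fv = extract_all(img, gt)
        for axis in range(3):
            flipped = extract_all(
                ImageVolume(np.flip(img.data, axis).copy(), img.spacing),
                BinaryMask(np.flip(gt.data, axis).copy(), gt.spacing),
            )
            for name in FEATURE_NAMES:
                if fv.valid[name]:
                    assert fv.values[name] == pytest.approx(
                        flipped.values[name], rel=1e-9, abs=1e-12
                    ), name

    def test_translation_invariance(self, small_case):
        img, gt, _, _ = small_case
        shifted_img = ImageVolume(np.roll(img.data, (2, 3, -2), axis=(0, 1, 2)), img.spacing)
        shifted_gt = BinaryMask(np.roll(gt.data, (2, 3, -2), axis=(0, 1, 2)), gt.spacing)
        a = extract_all(img, gt)
        b = extract_all(shifted_img, shifted_gt)
        for name in FEATURE_NAMES:
            if a.valid[name]:
                assert a.values[name] == pytest.approx(b.values[name], rel=1e-9), name

    def test_intensity_scaling_relations(self, small_case):
        img, gt, _, _ = small_case
        k = 3.0
        a = extract_all(img, gt, ExtractionConfig(bin_width=0.25))
        b = extract_all(
            ImageVolume(img.data * k, img.spacing), gt, ExtractionConfig(bin_width=0.25 * k)
        )
        assert b.values["firstorder_Energy"] == pytest.approx(
            k**2 * a.values["firstorder_Energy"], rel=1e-9
        )
        assert b.values["firstorder_Uniformity"] == pytest.approx(
            a.values["firstorder_Uniformity"], rel=1e-9
        )
        assert b.values["firstorder_Entropy"] == pytest.approx(
            a.values["firstorder_Entropy"], rel=1e-9
        )

    def test_single_voxel_mask_contract(self):
        data = np.random.default_rng(1).random((8, 8, 8))
        mask = np.zeros_like(data, dtype=bool)
        mask[4, 4, 4] = True
        fv = extract_all(_vol(data), BinaryMask(mask, SPACING))
        assert len(fv) == 107
        assert np.isfinite(fv.values["firstorder_Mean"])
        for name in FEATURE_NAMES:
            if name.split("_")[0] in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
                assert not fv.valid[name]

    def test_empty_mask_rejected(self):
        data = np.ones((8, 8, 8))
        with pytest.raises(ValueError):
            extract_all(_vol(data), BinaryMask(np.zeros_like(data, dtype=bool), SPACING))

    def test_constant_roi_contrast_zero_correlation_invalid(self):
        data = np.full((8, 8, 8), 2.0)
        mask = np.zeros_like(data, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        fv = extract_all(_vol(data), BinaryMask(mask, SPACING))
        assert fv.values["glcm_Contrast"] == 0.0
        assert not fv.valid["glcm_Correlation"]
        assert not fv.valid["glcm_Imc1"]
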