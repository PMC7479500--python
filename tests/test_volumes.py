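"""Voxel preprocessing: smoothing, downsampling, masking, vectorisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from padtrack.volumes import (
    BrainMask,
    GreyMatterVolume,
    downsample_2x,
    fwhm_to_sigma_voxels,
    scatter,
    smooth_volume,
    threshold_mask,
    vectorize,
)


def vol(values, vox=1.5, **kw):
    return GreyMatterVolume(np.asarray(values, dtype=float), vox, **kw)


class TestSmoothing:
    def test_sigma_conversion(self):
        # FWHM 8 mm at 1.5 mm voxels -> sigma = 3.3972 mm = 2.2648 voxels
        assert fwhm_to_sigma_voxels(8.0, 1.5) == pytest.approx(2.2648, abs=1e-4)

    def test_constant_volume_is_fixed_point(self):
        v = vol(np.full((10, 12, 9), 0.37))
        out = smooth_volume(v, 8.0)
        np.testing.assert_allclose(out.values, 0.37, atol=1e-12)

    def test_interior_impulse_mass_preserved(self):
        values = np.zeros((41, 41, 41))
        values[20, 20, 20] = 1.0
        out = smooth_volume(vol(values), 8.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_non_positive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(vol(np.zeros((4, 4, 4))), 0.0)

    @given(a=st.floats(-3, 3), seed=st.integers(0, 10_000))
    def test_linearity(self, a, seed):
        rng = np.random.default_rng(seed)
        v1, v2 = rng.random((2, 8, 8, 8))
        lhs = smooth_volume(vol(a * v1 + v2)).values
        rhs = a * smooth_volume(vol(v1)).values + smooth_volume(vol(v2)).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestDownsampling:
    def test_constant_halves_shape(self):
        out = downsample_2x(vol(np.full((8, 6, 4), 2.5)))
        assert out.values.shape == (4, 3, 2)
        np.testing.assert_allclose(out.values, 2.5)
        assert out.voxel_size_mm == 3.0

    def test_block_mean_example(self):
        out = downsample_2x(vol(np.arange(8.0).reshape(2, 2, 2)))
        assert out.values.shape == (1, 1, 1)
        assert out.values[0, 0, 0] == pytest.approx(3.5)

    @given(seed=st.integers(0, 10_000))
    def test_mass_identity_even_grids(self, seed):
        v = np.random.default_rng(seed).random((6, 8, 4))
        out = downsample_2x(vol(v))
        assert out.values.sum() * 8 == pytest.approx(v.sum(), rel=1e-12)

    def test_odd_dims_zero_padded(self):
        v = np.ones((3, 4, 4))
        out = downsample_2x(vol(v))
        assert out.values.shape == (2, 2, 2)
        # trailing padded block holds half the mass of a full block
        assert out.values[1, 0, 0] == pytest.approx(0.5)

    def test_block_replicate_roundtrip_idempotent(self, rng):
        v = rng.random((4, 4, 4))
        down = downsample_2x(vol(v))
        up = np.repeat(np.repeat(np.repeat(down.values, 2, 0), 2, 1), 2, 2)
        again = downsample_2x(vol(up, vox=1.5))
        np.testing.assert_allclose(again.values, down.values, atol=1e-12)


class TestMaskAndVectorize:
    def test_single_voxel_mask(self):
        v = np.zeros((4, 4, 4))
        v[1, 2, 3] = 0.5
        mask = threshold_mask([vol(v)])
        assert mask.n_voxels == 1
        assert mask.include[1, 2, 3]

    def test_all_zero_volumes_give_empty_mask(self):
        mask = threshold_mask([vol(np.zeros((4, 4, 4)))])
        assert mask.n_voxels == 0

    def test_union_over_training_volumes(self):
        a, b = np.zeros((4, 4, 4)), np.zeros((4, 4, 4))
        a[0, 0, 0] = 0.2
        b[3, 3, 3] = 0.2
        mask = threshold_mask([vol(a), vol(b)])
        assert mask.n_voxels == 2

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask([vol(np.zeros((4, 4, 4))), vol(np.zeros((4, 4, 2)))])

    def test_vectorize_scatter_roundtrip(self, rng):
        v = rng.random((5, 6, 7))
        mask = BrainMask(v > 0.5, 1.5)
        fv = vectorize(vol(v), mask)
        back = scatter(fv.values, mask)
        np.testing.assert_array_equal(back, np.where(v > 0.5, v, 0.0))

    def test_identical_volumes_identical_features(self, rng):
        v = rng.random((5, 5, 5))
        mask = threshold_mask([vol(v)])
        assert np.array_equal(vectorize(vol(v), mask).values, vectorize(vol(v), mask).values)

    def test_mask_grid_mismatch_rejected(self, rng):
        mask = BrainMask(np.ones((4, 4, 4), bool), 1.5)
        with pytest.raises(ValueError):
            vectorize(vol(np.zeros((5, 5, 5))), mask)
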