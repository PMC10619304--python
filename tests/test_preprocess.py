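"""Resampling, quantile-based histogram matching, normalization, centering."""

import numpy as np
import pytest
from scipy.stats import ks_2samp
from skimage.exposure import match_histograms as skimage_match

from longimap.preprocess import (
    PreprocessConfig,
    ValidationError,
    apply_brain_mask,
    center_brain,
    histogram_match,
    normalize01,
    preprocess_pair,
    resample,
)
from longimap.volume_io import PatientPair, Volume

SMALL = PreprocessConfig(target_shape=(32, 32, 16))


class TestResample:
    def test_identity_when_already_at_target(self, rng):
        v = Volume(rng.random((32, 32, 16)).astype(np.float32))
        out = resample(v, SMALL)
        assert np.array_equal(out.values, v.values)

    def test_output_shape_is_target(self, rng):
        v = Volume(rng.random((20, 28, 10)).astype(np.float32))
        assert resample(v, SMALL).shape == (32, 32, 16)

    def test_default_target_shape(self):
        assert PreprocessConfig().target_shape == (256, 256, 128)

    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((16, 16, 8), 3.5, np.float32))
        out = resample(v, SMALL)
        assert np.allclose(out.values, 3.5, atol=1e-5)

    def test_spacing_rescales(self):
        v = Volume(np.random.default_rng(0).random((16, 16, 16)).astype(np.float32),
                   np.diag([2.0, 2.0, 2.0, 1.0]))
        out = resample(v, SMALL)
        assert out.spacing == pytest.approx((1.0, 1.0, 2.0))

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ValidationError):
            resample(Volume(np.zeros((16, 16, 1), np.float32)), SMALL)


class TestHistogramMatch:
    def test_fixed_point(self, rng):
        v = Volume(rng.random((16, 16, 8)).astype(np.float32))
        out = histogram_match(v, v, SMALL)
        assert np.allclose(out.values, v.values, atol=1e-3)

    def test_shifted_intensities_recover_reference_quantiles(self, rng):
        ref = Volume(rng.normal(50, 10, (16, 16, 8)).astype(np.float32))
        mov = Volume(ref.values + 100.0)
        out = histogram_match(mov, ref, SMALL)
        q = np.linspace(0.05, 0.95, 19)
        assert np.quantile(out.values, q) == pytest.approx(
            np.quantile(ref.values, q), abs=0.5)

    def test_monotone_in_input(self, rng):
        mov = Volume(rng.random((12, 12, 6)).astype(np.float32))
        ref = Volume(rng.normal(0, 5, (12, 12, 6)).astype(np.float32))
        out = histogram_match(mov, ref, SMALL)
        order = np.argsort(mov.values.ravel(), kind="stable")
        assert np.all(np.diff(out.values.ravel()[order]) >= -1e-6)

    def test_agrees_with_skimage_full_matching(self, rng):
        """With dense anchors, quantile mapping approximates exact histogram
        matching as implemented independently in scikit-image."""
        mov = Volume(rng.gamma(2.0, 10.0, (16, 16, 8)).astype(np.float32))
        ref = Volume(rng.normal(100, 20, (16, 16, 8)).astype(np.float32))
        cfg = PreprocessConfig(target_shape=(32, 32, 16), hist_quantiles=2048)
        ours = histogram_match(mov, ref, cfg).values
        theirs = skimage_match(mov.values, ref.values)
        assert np.median(np.abs(ours - theirs)) < 0.5

    def test_constant_reference_rejected(self, rng):
        mov = Volume(rng.random((8, 8, 8)).astype(np.float32))
        with pytest.raises(ValidationError):
            histogram_match(mov, Volume(np.ones((8, 8, 8), np.float32)), SMALL)


class TestNormalize01:
    def test_two_point_map(self):
        v = Volume(np.array([[[2.0, 4.0]]] * 2, np.float32).reshape(2, 1, 2))
        out = normalize01(v)
        assert set(np.unique(out.values)) == {0.0, 1.0}

    def test_exact_bounds_and_order(self, rng):
        v = Volume(rng.normal(0, 50, (10, 10, 10)).astype(np.float32))
        out = normalize01(v)
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        order = np.argsort(v.values.ravel(), kind="stable")
        assert np.all(np.diff(out.values.ravel()[order]) >= 0)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            normalize01(Volume(np.ones((4, 4, 4), np.float32)))


class TestCenterBrain:
    def test_already_centered_is_identity(self):
        m = np.zeros((15, 15, 15), np.float32)
        m[6:9, 6:9, 6:9] = 1
        v = Volume(np.random.default_rng(0).random((15, 15, 15)).astype(np.float32))
        out, _ = center_brain(v, Volume(m))
        assert np.array_equal(out.values, v.values)

    def test_corner_voxel_moves_to_center(self):
        m = np.zeros((15, 15, 15), np.float32)
        m[0, 0, 0] = 1
        v = Volume(np.zeros((15, 15, 15), np.float32))
        v.values[0, 0, 0] = 9.0
        out, mout = center_brain(v, Volume(m))
        assert out.values[7, 7, 7] == 9.0
        assert mout.values[7, 7, 7] == 1.0
        assert out.values.sum() == 9.0

    @pytest.mark.parametrize("seed", range(4))
    def test_centroid_lands_within_half_voxel(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((24, 24, 24), np.float32)
        c = rng.integers(4, 20, 3)
        m[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2, c[2] - 2:c[2] + 2] = 1
        _, mout = center_brain(Volume(m.copy()), Volume(m))
        from scipy.ndimage import center_of_mass
        centroid = np.array(center_of_mass(mout.values > 0.5))
        assert np.all(np.abs(centroid - 11.5) <= 0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            center_brain(Volume(np.ones((4, 4, 4), np.float32)),
                         Volume(np.zeros((4, 4, 4), np.float32)))


class TestApplyBrainMask:
    def test_masking_contracts(self, rng):
        v = Volume(rng.random((8, 8, 8)).astype(np.float32) + 1.0)
        ones = Volume(np.ones((8, 8, 8), np.float32))
        zeros = Volume(np.zeros((8, 8, 8), np.float32))
        assert np.array_equal(apply_brain_mask(v, ones).values, v.values)
        assert np.all(apply_brain_mask(v, zeros).values == 0)
        half = np.zeros((8, 8, 8), np.float32)
        half[:4] = 1
        out = apply_brain_mask(v, Volume(half))
        assert out.values[4:].sum() == 0
        assert np.array_equal(out.values[:4], v.values[:4])


class TestPreprocessPair:
    def _pair(self, rng, shift=0.0):
        base = np.zeros((24, 24, 12), np.float32)
        base[6:18, 6:18, 3:9] = 1.0
        tex = rng.random((24, 24, 12)).astype(np.float32)
        v1 = base * (40 + 20 * tex)
        v2 = base * (40 + 20 * tex) + shift * base
        mask = (base > 0).astype(np.float32)
        return PatientPair(Volume(v1), Volume(v2),
                           Volume(mask.copy()), Volume(mask.copy()))

    def test_identical_inputs_identical_outputs(self, rng):
        pair = self._pair(rng)
        out = preprocess_pair(pair, SMALL)
        assert np.allclose(out.tp1.values, out.tp2.values, atol=1e-4)

    def test_output_shape_and_range(self, rng):
        out = preprocess_pair(self._pair(rng, shift=15.0), SMALL)
        for v in (out.tp1, out.tp2):
            assert v.shape == (32, 32, 16)
            assert v.values.min() >= 0.0 and v.values.max() <= 1.0

    def test_matching_reduces_intensity_shift(self, rng):
        """After matching+normalizing, the in-mask distributions are closer
        than the raw shifted inputs (Kolmogorov-Smirnov distance)."""
        pair = self._pair(rng, shift=25.0)
        raw = ks_2samp(pair.tp1.values.ravel(), pair.tp2.values.ravel()).statistic
        out = preprocess_pair(pair, SMALL)
        a = out.tp1.values[out.brain_mask_tp1.values > 0.5]
        b = out.tp2.values[out.brain_mask_tp2.values > 0.5]
        assert ks_2samp(a, b).statistic < raw

    def test_idempotent_up_to_interpolation(self, rng):
        out1 = preprocess_pair(self._pair(rng, shift=10.0), SMALL)
        out2 = preprocess_pair(out1, SMALL)
        diff = np.abs(out1.tp1.values - out2.tp1.values)
        assert np.quantile(diff, 0.99) < 0.05

    def test_missing_masks_require_flag(self, rng):
        pair = self._pair(rng)
        pair.brain_mask_tp1 = pair.brain_mask_tp2 = None
        with pytest.raises(ValidationError):
            preprocess_pair(pair, SMALL)
        out = preprocess_pair(pair, SMALL, assume_skull_stripped=True)
        assert out.tp1.shape == (32, 32, 16)
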