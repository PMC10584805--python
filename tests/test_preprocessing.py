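"""Preprocessing: normalization, cropping, sampling, thresholds, bias, augment."""

import math

import numpy as np
import pytest

from hippseg.io_volumes import LabelVolume, Volume3D
from hippseg.preprocessing import (AugmentParams, Patch, SamplingError,
                                   apply_augment_record, augment, crop_patch,
                                   correct_bias_field, draw_augment_record,
                                   global_threshold, iterative_threshold,
                                   sample_batch, threshold_mask,
                                   zscore_normalize)
from hippseg.synthetic import (SyntheticSpec, apply_bias_field,
                               generate_subject, polynomial_monomials)


class TestZScore:
    def test_matches_scalar_formula(self):
        x = np.tile(np.array([1.0, 2.0, 3.0]), (4, 4, 2)).reshape(4, 4, 6)
        z = zscore_normalize(x)
        mu, sd = x.mean(), x.std()
        expected = np.vectorize(lambda v: (v - mu) / sd)(x)  # voxelwise oracle
        np.testing.assert_allclose(z, expected, atol=1e-12)

    def test_fixed_point(self):
        rng = np.random.default_rng(0)
        z = zscore_normalize(rng.normal(50, 7, (8, 8, 8)))
        np.testing.assert_allclose(zscore_normalize(z), z, atol=1e-6)
        assert abs(z.mean()) < 1e-6 and abs(z.std() - 1) < 1e-6

    def test_constant_input_maps_to_zeros(self):
        assert np.all(zscore_normalize(np.full((4, 4, 4), 5.0)) == 0)


class TestCropPatch:
    def test_identity_crop(self):
        rng = np.random.default_rng(1)
        v = Volume3D(rng.normal(size=(48, 64, 48)))
        l = LabelVolume(np.zeros((48, 64, 48), dtype=np.int16))
        p = crop_patch(v, l, (48, 64, 48), (24, 32, 24))
        np.testing.assert_array_equal(p.image, v.values)
        assert not p.pad_mask.any()

    def test_minimum_extent_volume_fully_padded_and_conserved(self):
        # smallest per-axis extents seen in the target dataset: 31 x 40 x 24
        rng = np.random.default_rng(2)
        v = Volume3D(rng.uniform(1, 2, (31, 40, 24)))
        l = LabelVolume(np.ones((31, 40, 24), dtype=np.int16))
        p = crop_patch(v, l, (48, 64, 48), (15, 20, 12))
        assert p.image.shape == (48, 64, 48)
        np.testing.assert_allclose(p.image.sum(), v.values.sum(), rtol=1e-12)
        assert p.label.sum() == l.values.sum()
        assert np.all(p.image[p.pad_mask] == 0)
        assert p.pad_mask.sum() == 48 * 64 * 48 - 31 * 40 * 24

    def test_indivisible_size_rejected(self):
        v = Volume3D(np.zeros((48, 64, 48)))
        l = LabelVolume(np.zeros((48, 64, 48), dtype=np.int16))
        with pytest.raises(ValueError, match="2\\^4"):
            crop_patch(v, l, (50, 64, 48), (24, 32, 24))

    def test_center_outside_volume_rejected(self):
        v = Volume3D(np.zeros((32, 32, 32)))
        l = LabelVolume(np.zeros((32, 32, 32), dtype=np.int16))
        with pytest.raises(ValueError, match="center"):
            crop_patch(v, l, (16, 16, 16), (40, 0, 0))


class TestSampleBatch:
    def test_minimum_foreground_count(self, small_dataset):
        rng = np.random.default_rng(3)
        b = sample_batch(small_dataset, 16, rng=rng, patch_size=(16, 32, 16))
        assert sum(p.has_foreground for p in b.patches) >= math.ceil(16 / 3)

    def test_guarantee_holds_over_many_draws(self, small_dataset):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            b = sample_batch(small_dataset, 6, rng=rng,
                             patch_size=(16, 16, 16))
            assert sum(p.has_foreground for p in b.patches) >= 2

    def test_all_foreground_dataset(self, small_dataset):
        # crops centred on foreground always contain foreground
        vol, lab = small_dataset[0]
        dense = LabelVolume(np.ones(lab.shape, dtype=np.int16))
        b = sample_batch([(vol, dense)], 16, rng=np.random.default_rng(5),
                         patch_size=(16, 16, 16))
        assert all(p.has_foreground for p in b.patches)

    def test_zero_batch_size_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            sample_batch(small_dataset, 0)

    def test_no_foreground_anywhere_raises(self):
        vol = Volume3D(np.zeros((32, 32, 32)))
        lab = LabelVolume(np.zeros((32, 32, 32), dtype=np.int16))
        with pytest.raises(SamplingError):
            sample_batch([(vol, lab)], 4, patch_size=(16, 16, 16))


class TestThresholds:
    def test_otsu_separates_bimodal_image(self):
        rng = np.random.default_rng(6)
        img = np.zeros((16, 16, 16))
        hot = rng.random((16, 16, 16)) < 0.3
        img[hot] = 10.0
        mask = threshold_mask(img, "otsu")
        np.testing.assert_array_equal(mask, hot)

    def test_otsu_matches_bruteforce_between_class_variance(self):
        # toy 8-level histogram; oracle = exhaustive search over cut points
        rng = np.random.default_rng(7)
        levels = np.arange(8, dtype=float)
        counts = rng.integers(5, 50, size=8)
        values = np.repeat(levels, counts)
        best, best_var = None, -1.0
        for cut in range(1, 8):  # threshold between cut-1 and cut
            lo, hi = values[values < cut], values[values >= cut]
            w0, w1 = len(lo) / len(values), len(hi) / len(values)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best = var, cut
        from skimage.filters import threshold_otsu
        t = threshold_otsu(values.reshape(-1, 1, 1), nbins=8)
        lo_pkg = values[values <= t]
        assert lo_pkg.max() == best - 1  # same partition as the brute force

    def test_iterative_converges_to_midpoint_on_two_valued_image(self):
        img = np.zeros((10, 10, 10))
        img[:5] = 10.0
        # hand iteration: t0 = 5 -> class means 0 and 10 -> t1 = 5 (fixed)
        assert iterative_threshold(img) == pytest.approx(5.0)
        assert global_threshold(img, "iterative") == pytest.approx(5.0)

    def test_local_methods_return_binary_3d_masks(self, one_subject):
        vol, _ = one_subject
        for method in ("sauvola", "niblack"):
            mask = threshold_mask(vol, method, window=(16, 16, 16))
            assert mask.dtype == bool and mask.shape == vol.shape

    def test_constant_image_yields_empty_mask(self):
        mask = threshold_mask(np.full((8, 8, 8), 3.0), "otsu")
        assert not mask.any()

    def test_unknown_method_rejected(self, one_subject):
        with pytest.raises(ValueError, match="unknown"):
            threshold_mask(one_subject[0], "magic")


class TestBiasCorrection:
    def test_unbiased_homogeneous_foreground_nearly_unchanged(self):
        # nothing to correct: mean relative change within the mask < 2%
        spec = SyntheticSpec(bias_amplitude=0.0, noise_sd=5.0,
                             contrast={0: 100.0, 1: 150.0, 2: 150.0},
                             contrast_jitter=0.0)
        vol, _ = generate_subject(spec, np.random.default_rng([21, 2]))
        mask = threshold_mask(vol, "otsu")
        corr, bias = correct_bias_field(vol, mask)
        rel = np.abs(corr.values[mask] - vol.values[mask]) / vol.values[mask]
        assert rel.mean() < 0.02
        assert np.all(bias.values > 0)

    def test_correction_reduces_within_class_variation(self):
        spec = SyntheticSpec(bias_amplitude=0.0, noise_sd=1.0)
        monos = polynomial_monomials(2)
        coeffs = np.zeros(len(monos))
        coeffs[monos.index((0, 1, 0))] = 0.6  # strong gradient along H
        for s in range(3):
            vol, lab = generate_subject(spec, np.random.default_rng([22, s]))
            biased, _ = apply_bias_field(vol, coeffs)
            mask = threshold_mask(biased, "otsu")
            corr, _ = correct_bias_field(biased, mask)

            def cv(values):
                return np.mean([values[lab.values == c].std()
                                / values[lab.values == c].mean()
                                for c in (1, 2)])

            assert cv(corr.values) < cv(biased.values)

    def test_reconstruction_and_positivity(self, one_subject):
        vol, _ = one_subject
        mask = threshold_mask(vol, "otsu")
        for method in ("n4", "polyfit"):
            corr, bias = correct_bias_field(vol, mask, method=method)
            assert np.all(bias.values > 0)
            np.testing.assert_allclose(corr.values * bias.values, vol.values,
                                       rtol=1e-6)

    def test_empty_mask_rejected(self, one_subject):
        vol, _ = one_subject
        with pytest.raises(ValueError, match="mask"):
            correct_bias_field(vol, np.zeros(vol.shape, dtype=bool))


class TestAugment:
    @pytest.fixture()
    def patch(self, one_subject):
        vol, lab = one_subject
        return crop_patch(vol, lab, (32, 48, 32))

    def test_zero_select_probability_is_identity(self, patch):
        out = augment(patch, AugmentParams(select_p=0.0),
                      np.random.default_rng(0))
        np.testing.assert_array_equal(out.image, patch.image)
        np.testing.assert_array_equal(out.label, patch.label)

    def test_mirror_frequency_and_angle_bounds(self):
        params = AugmentParams(select_p=1.0)
        rng = np.random.default_rng(123)
        hits = np.zeros(3)
        n = 10_000
        for _ in range(n):
            rec = draw_augment_record(params, rng)
            hits += rec.mirror
            assert abs(rec.angle) <= 15.0
        freq = hits / n
        assert np.all(freq >= 0.48) and np.all(freq <= 0.52)

    def test_selection_frequency_near_95_percent(self):
        params = AugmentParams()
        rng = np.random.default_rng(321)
        n = 10_000
        sel = sum(draw_augment_record(params, rng).applied for _ in range(n))
        assert 0.94 < sel / n < 0.96

    def test_shape_and_vocabulary_preserved(self, patch):
        params = AugmentParams(select_p=1.0)
        rng = np.random.default_rng(9)
        for _ in range(5):
            out = augment(patch, params, rng)
            assert out.image.shape == patch.image.shape
            assert set(np.unique(out.label).tolist()) <= {0, 1, 2}

    def test_double_mirror_is_identity(self, patch):
        from hippseg.preprocessing import AugmentRecord
        params = AugmentParams(select_p=1.0, rot_deg=0.0, intensity_frac=0.0)
        rec = AugmentRecord(applied=True, mirror=(True, False, True),
                            rot_axis=0, angle=0.0, intensity_u=0.0)
        once = apply_augment_record(patch, params, rec)
        twice = apply_augment_record(once, params, rec)
        np.testing.assert_array_equal(twice.image, patch.image)
        np.testing.assert_array_equal(twice.label, patch.label)

    def test_geometry_shared_between_image_and_label(self, patch):
        # a pure mirror must move image and label identically
        from hippseg.preprocessing import AugmentRecord
        params = AugmentParams(select_p=1.0, rot_deg=0.0, intensity_frac=0.0)
        rec = AugmentRecord(applied=True, mirror=(True, False, False),
                            rot_axis=0, angle=0.0, intensity_u=0.0)
        out = apply_augment_record(patch, params, rec)
        np.testing.assert_array_equal(out.image, patch.image[::-1])
        np.testing.assert_array_equal(out.label, patch.label[::-1])
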