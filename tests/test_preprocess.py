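"""Normalization, respacing, balanced patch sampling, augmentation."""

import numpy as np
import pandas as pd
import pytest

import breastseg as bs
from breastseg.io import CohortManifest
from breastseg.preprocess import AugmentConfig, PatchConfig, PatchSample


def _vol(data, spacing=(1, 1, 1)):
    return bs.Volume3D(data=np.asarray(data, dtype=np.float32), spacing_mm=spacing)


class TestClampNormalize:
    def test_constant_volume_maps_to_zeros_with_warning(self):
        vol = _vol(np.full((8, 8, 8), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            out, params = bs.clamp_normalize(vol)
        assert np.all(out.data == 0)
        assert params.sd == 0.0

    def test_matches_direct_percentile_zscore_arithmetic(self):
        # oracle: clip at the 0.5/99.5 percentiles of the flat list 0..999,
        # subtract mean, divide by SD - computed independently here
        values = np.arange(1000, dtype=np.float64)
        vol = _vol(values.reshape(10, 10, 10))
        out, params = bs.clamp_normalize(vol)
        lo, hi = np.percentile(values, [0.5, 99.5])
        clipped = np.clip(values, lo, hi)
        expected = (clipped - clipped.mean()) / clipped.std()
        np.testing.assert_allclose(out.data.ravel(), expected, rtol=1e-5)
        assert params.mean == pytest.approx(clipped.mean())
        assert params.sd == pytest.approx(clipped.std())

    def test_output_is_approximately_standardized(self, rng):
        vol = _vol(rng.normal(100, 25, size=(20, 20, 20)))
        out, _ = bs.clamp_normalize(vol)
        assert abs(out.data.mean()) < 1e-3
        assert abs(out.data.std() - 1.0) < 1e-2  # clipping removes a little mass

    def test_normalize_is_idempotent_when_nothing_clipped(self, rng):
        vol = _vol(rng.normal(size=(12, 12, 12)))
        once, _ = bs.clamp_normalize(vol, bs.NormalizationParams(lower_pct=0, upper_pct=100))
        twice, _ = bs.clamp_normalize(once, bs.NormalizationParams(lower_pct=0, upper_pct=100))
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)


class TestTargetSpacing:
    def _manifest_with_spacings(self, tmp_path, spacings):
        rows = []
        for i, sp in enumerate(spacings):
            vol = _vol(np.zeros((8, 8, 8)), spacing=sp)
            path = tmp_path / f"v{i}.nii.gz"
            bs.write_volume(vol, path)
            rows.append({"case_id": f"c{i}", "image_path": str(path), "mask_path": str(path)})
        return CohortManifest(pd.DataFrame(rows))

    def test_mean_of_two_cases(self, tmp_path):
        man = self._manifest_with_spacings(tmp_path, [(1, 1, 1), (1, 1, 2)])
        np.testing.assert_allclose(bs.compute_target_spacing(man), (1, 1, 1.5), rtol=1e-6)

    def test_single_case_identity(self, tmp_path):
        man = self._manifest_with_spacings(tmp_path, [(0.7, 0.7, 1.1)])
        np.testing.assert_allclose(bs.compute_target_spacing(man), (0.7, 0.7, 1.1), rtol=1e-5)

    def test_matches_hand_summed_mean_on_random_spacings(self, tmp_path, rng):
        spacings = [tuple(rng.uniform(0.5, 2.0, 3)) for _ in range(10)]
        man = self._manifest_with_spacings(tmp_path, spacings)
        hand = [sum(s[ax] for s in spacings) / 10 for ax in range(3)]
        np.testing.assert_allclose(bs.compute_target_spacing(man), hand, rtol=1e-5)


class TestResample:
    def test_identity_target_is_identity(self, rng):
        mask = bs.Mask3D(labels=(rng.uniform(size=(10, 10, 10)) > 0.5).astype(np.uint8),
                         spacing_mm=(1, 1, 1))
        out = bs.resample_volume(mask, (1, 1, 1), mode="nearest")
        np.testing.assert_array_equal(out.labels, mask.labels)

    def test_nearest_keeps_mask_binary(self, rng):
        mask = bs.Mask3D(labels=(rng.uniform(size=(12, 12, 12)) > 0.5).astype(np.uint8),
                         spacing_mm=(1, 1, 2))
        out = bs.resample_volume(mask, (0.8, 0.8, 0.8), mode="nearest")
        assert set(np.unique(out.labels)) <= {0, 1}

    def test_sphere_volume_preserved_across_respacing(self, sphere_spec):
        # oracle: the analytic sphere volume at both resolutions
        _, mask, record = bs.generate_phantom(sphere_spec)
        fine = bs.resample_volume(mask, (0.5, 0.5, 0.5), mode="nearest")
        v1 = mask.voxel_volume_mm3
        v2 = fine.voxel_volume_mm3
        assert v2 == pytest.approx(record.analytic_volume_mm3, rel=0.03)
        assert abs(v2 - v1) / v1 < 0.03

    def test_degenerate_target_rejected(self):
        vol = _vol(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            bs.resample_volume(vol, (100, 100, 100))


class TestSamplePatches:
    def _phantom(self):
        spec = bs.PhantomSpec(grid_shape=(48, 48, 48), semi_axes_mm=(8, 7, 6), seed=1)
        vol, mask, _ = bs.generate_phantom(spec)
        return vol, mask

    def test_every_patch_center_is_foreground_when_prob_one(self, rng):
        vol, mask = self._phantom()
        cfg = PatchConfig(patch_size=(16, 16, 16), fg_center_prob=1.0, samples_per_volume=20)
        for s in bs.sample_patches(vol, mask, cfg, rng):
            # center voxel of the patch is inside the lesion unless clipped at border
            assert s.label_patch[8, 8, 8] == 1

    def test_fg_fraction_converges_to_half(self, rng):
        vol, mask = self._phantom()
        cfg = PatchConfig(patch_size=(16, 16, 16), fg_center_prob=0.5, samples_per_volume=2000)
        samples = bs.sample_patches(vol, mask, cfg, rng)
        frac = np.mean([s.label_patch[8, 8, 8] for s in samples])
        se = np.sqrt(0.25 / 2000)
        assert abs(frac - 0.5) < 3 * se

    def test_two_to_one_ratio_supported(self, rng):
        vol, mask = self._phantom()
        cfg = PatchConfig(patch_size=(16, 16, 16), fg_center_prob=2 / 3, samples_per_volume=2000)
        samples = bs.sample_patches(vol, mask, cfg, rng)
        frac = np.mean([s.label_patch[8, 8, 8] for s in samples])
        assert abs(frac - 2 / 3) < 3 * np.sqrt((2 / 3) * (1 / 3) / 2000)

    def test_empty_foreground_falls_back_to_background(self, rng):
        vol, _ = self._phantom()
        empty = bs.Mask3D(labels=np.zeros((48, 48, 48), dtype=np.uint8), spacing_mm=(0.7, 0.7, 1.1))
        cfg = PatchConfig(patch_size=(16, 16, 16), fg_center_prob=1.0, samples_per_volume=3)
        with pytest.warns(UserWarning, match="no foreground"):
            samples = bs.sample_patches(vol, empty, cfg, rng)
        assert len(samples) == 3

    def test_small_volume_zero_padded_to_patch(self, rng):
        vol = _vol(np.ones((10, 10, 10)))
        mask = bs.Mask3D(labels=np.ones((10, 10, 10), dtype=np.uint8), spacing_mm=(1, 1, 1))
        cfg = PatchConfig(patch_size=(16, 16, 16), samples_per_volume=2)
        for s in bs.sample_patches(vol, mask, cfg, rng):
            assert s.image_patch.shape == (16, 16, 16)

    def test_odd_patch_size_rejected(self):
        with pytest.raises(ValueError, match="multiple of 2"):
            PatchConfig(patch_size=(15, 16, 16))


class TestAugment:
    def _sample(self, rng):
        image = rng.normal(size=(16, 16, 16)).astype(np.float32)
        label = (rng.uniform(size=(16, 16, 16)) > 0.7).astype(np.uint8)
        return PatchSample(image_patch=image, label_patch=label, center_index=(8, 8, 8))

    def test_all_disabled_is_bit_identical(self, rng):
        s = self._sample(rng)
        out = bs.augment_patch(s, AugmentConfig.disabled(), rng)
        np.testing.assert_array_equal(out.image_patch, s.image_patch)
        np.testing.assert_array_equal(out.label_patch, s.label_patch)

    def test_rot90_conserves_label_voxel_count(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(p_zoom=0, p_scale_intensity=0, p_shift_intensity=0,
                            p_gaussian_noise=0, p_rot90=1.0, p_elastic=0)
        out = bs.augment_patch(s, cfg, rng)
        assert out.label_patch.sum() == s.label_patch.sum()

    def test_noise_preserves_mean_and_label(self, rng):
        image = np.full((16, 16, 16), 100.0, dtype=np.float32)
        label = (rng.uniform(size=(16, 16, 16)) > 0.5).astype(np.uint8)
        s = PatchSample(image_patch=image, label_patch=label, center_index=(8, 8, 8))
        cfg = AugmentConfig(p_zoom=0, p_scale_intensity=0, p_shift_intensity=0,
                            p_gaussian_noise=1.0, noise_sd_max=10.0, p_rot90=0, p_elastic=0)
        out = bs.augment_patch(s, cfg, rng)
        se = 10.0 / np.sqrt(image.size)
        assert abs(out.image_patch.mean() - 100.0) < 3 * se
        np.testing.assert_array_equal(out.label_patch, label)

    @pytest.mark.parametrize("transform", ["zoom", "rot90", "elastic"])
    def test_geometric_transforms_keep_label_binary(self, rng, transform):
        s = self._sample(rng)
        kwargs = dict(p_zoom=0, p_scale_intensity=0, p_shift_intensity=0,
                      p_gaussian_noise=0, p_rot90=0, p_elastic=0)
        kwargs[f"p_{transform}"] = 1.0
        out = bs.augment_patch(s, AugmentConfig(**kwargs), rng)
        assert set(np.unique(out.label_patch)) <= {0, 1}
        assert out.image_patch.shape == s.image_patch.shape

    def test_zoom_range_must_bracket_one(self):
        with pytest.raises(ValueError, match="bracket"):
            AugmentConfig(zoom_range=(1.1, 1.3))
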