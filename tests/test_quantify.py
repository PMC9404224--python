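"""Shape features, Otsu threshold, cystic decomposition, T staging.

Oracles used here are deliberately independent of the implementation:
brute-force pairwise distances, eigen-decompositions recomputed from raw
coordinates, exhaustive threshold search, and closed-form ellipsoid
geometry from the phantom generator.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breastseg as bs
from breastseg.quantify import StagingRules, remove_small_components
from tests_oracles import otsu_brute_force_min, otsu_within_class_variance


def _mask(labels, spacing=(1, 1, 1)):
    return bs.Mask3D(labels=np.asarray(labels, dtype=np.uint8), spacing_mm=spacing)


def _random_blob_mask(rng, shape=(12, 12, 12), n_target=300):
    labels = np.zeros(shape, dtype=np.uint8)
    idx = rng.choice(np.prod(shape), size=n_target, replace=False)
    labels.reshape(-1)[idx] = 1
    return labels


class TestLargestComponent:
    def test_keeps_biggest_of_two(self):
        labels = np.zeros((20, 20, 20), dtype=np.uint8)
        labels[1:9, 1:9, 1:9] = 1  # 512 voxels
        labels[15:17, 15:17, 15:17] = 1  # 8 voxels
        out = bs.largest_component(_mask(labels))
        assert out.voxel_count == 512
        assert out.labels[16, 16, 16] == 0

    def test_single_component_is_identity(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[2:5, 2:5, 2:5] = 1
        out = bs.largest_component(_mask(labels))
        np.testing.assert_array_equal(out.labels, labels)

    def test_tie_breaks_to_lexicographically_smallest_seed(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[0:2, 0:2, 0:2] = 1
        labels[6:8, 6:8, 6:8] = 1
        out = bs.largest_component(_mask(labels))
        assert out.labels[0, 0, 0] == 1 and out.labels[7, 7, 7] == 0

    def test_empty_mask_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="empty"):
            out = bs.largest_component(_mask(np.zeros((5, 5, 5))))
        assert out.voxel_count == 0


class TestComputeGeometry:
    def test_two_voxel_345_triangle_diameter(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[0, 0, 0] = 1
        labels[3, 4, 0] = 1
        geo = bs.compute_geometry(_mask(labels))
        assert geo.max_3d_diameter_mm == pytest.approx(5.0, abs=1e-9)

    def test_sphere_volumes_and_isotropy(self, sphere_spec):
        _, mask, record = bs.generate_phantom(sphere_spec)
        geo = bs.compute_geometry(mask)
        assert geo.voxel_volume_mm3 == pytest.approx(record.analytic_volume_mm3, rel=0.02)
        assert geo.mesh_volume_mm3 == pytest.approx(record.analytic_volume_mm3, rel=0.02)
        assert geo.maximal_diameter_mm == pytest.approx(geo.minimal_diameter_mm, rel=0.02)

    def test_random_blob_matches_brute_force_and_eigen_oracles(self, rng):
        labels = _random_blob_mask(rng)
        spacing = (0.7, 0.7, 1.1)
        geo = bs.compute_geometry(_mask(labels, spacing))
        coords = np.argwhere(labels) * np.array(spacing)
        # brute force over all voxel pairs
        d2 = ((coords[:, None] - coords[None]) ** 2).sum(-1)
        assert geo.max_3d_diameter_mm == pytest.approx(np.sqrt(d2.max()), rel=1e-9)
        # independent eigen-decomposition of the coordinate covariance
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        assert geo.maximal_diameter_mm == pytest.approx(4 * np.sqrt(lam[0]), rel=1e-9)
        assert geo.minimal_diameter_mm == pytest.approx(4 * np.sqrt(lam[1]), rel=1e-9)

    def test_voxel_volume_exact(self, rng):
        labels = _random_blob_mask(rng, n_target=123)
        geo = bs.compute_geometry(_mask(labels, (0.5, 0.5, 2.0)))
        assert geo.voxel_volume_mm3 == 123 * 0.5 * 0.5 * 2.0

    def test_diameter_invariant_under_translation_and_axis_permutation(self, rng):
        labels = np.zeros((16, 16, 16), dtype=np.uint8)
        labels[2:7, 3:6, 4:9] = 1
        spacing = (0.7, 0.9, 1.1)
        geo = bs.compute_geometry(_mask(labels, spacing))
        rolled = np.roll(labels, (3, 2, 1), axis=(0, 1, 2))
        geo_t = bs.compute_geometry(_mask(rolled, spacing))
        assert geo_t.max_3d_diameter_mm == pytest.approx(geo.max_3d_diameter_mm, rel=1e-9)
        perm = labels.transpose(2, 0, 1)
        geo_p = bs.compute_geometry(_mask(perm, (1.1, 0.7, 0.9)))
        assert geo_p.max_3d_diameter_mm == pytest.approx(geo.max_3d_diameter_mm, rel=1e-9)

    def test_single_voxel_mask_reports_zero_diameters(self):
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels[2, 2, 2] = 1
        with pytest.warns(UserWarning, match="single-voxel"):
            geo = bs.compute_geometry(_mask(labels))
        assert geo.max_3d_diameter_mm == 0.0
        assert geo.voxel_volume_mm3 == 1.0
        assert geo.mesh_volume_mm3 >= 0.0

    def test_mesh_to_voxel_volume_ratio_approaches_one(self, sphere_spec):
        _, mask, _ = bs.generate_phantom(sphere_spec)
        geo = bs.compute_geometry(mask)
        assert geo.mesh_volume_mm3 / geo.voxel_volume_mm3 == pytest.approx(1.0, abs=0.02)


class TestOtsu:
    def test_perfectly_bimodal_input_separated(self):
        values = np.array([50.0] * 100 + [200.0] * 100)
        t = bs.otsu_threshold(values)
        assert 50.0 < t <= 200.0
        assert np.all(values[values < t] == 50.0)
        assert np.all(values[values >= t] == 200.0)

    def test_achieves_exhaustive_search_minimum_on_random_inputs(self, rng):
        for _ in range(20):
            values = np.concatenate(
                [
                    rng.normal(rng.uniform(50, 150), rng.uniform(5, 30), size=rng.integers(50, 400)),
                    rng.normal(rng.uniform(200, 400), rng.uniform(5, 30), size=rng.integers(50, 400)),
                ]
            )
            t = bs.otsu_threshold(values)
            achieved = otsu_within_class_variance(values, t)
            optimum = otsu_brute_force_min(values)
            assert achieved == pytest.approx(optimum, rel=1e-9)

    def test_well_separated_mixture_threshold_in_gap(self, rng):
        values = np.concatenate(
            [rng.normal(100, 10, size=1000), rng.normal(300, 10, size=1000)]
        )
        assert 150 < bs.otsu_threshold(values) < 250

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bs.otsu_threshold(np.full(100, 5.0))

    def test_threshold_strictly_inside_range(self, rng):
        values = rng.uniform(0, 1, size=500)
        t = bs.otsu_threshold(values)
        assert values.min() < t < values.max()


class TestSegmentCystic:
    def _cored_phantom(self, noise_sd):
        spec = bs.PhantomSpec(
            grid_shape=(48, 48, 48),
            spacing_mm=(1, 1, 1),
            semi_axes_mm=(14, 12, 11),
            core=bs.CoreSpec(core_semi_axes_mm=(6, 6, 6), core_intensity=100.0),
            noise_sd=noise_sd,
            seed=8,
        )
        return spec, bs.generate_phantom(spec)

    def test_noise_free_cyst_mask_equals_core_exactly(self):
        spec, (vol, mask, record) = self._cored_phantom(0.0)
        cyst_mask, report = bs.segment_cystic(vol, mask)
        core = vol.data == 100.0
        np.testing.assert_array_equal(cyst_mask.labels.astype(bool), core)
        assert report.cyst_volume_mm3 == pytest.approx(record.core_volume_mm3, rel=0.05)

    def test_noisy_cyst_volume_within_5pct_of_analytic(self):
        # noise sd = 10% of the 200-unit rim/core contrast
        spec, (vol, mask, record) = self._cored_phantom(20.0)
        _, report = bs.segment_cystic(vol, mask)
        assert report.cyst_volume_mm3 == pytest.approx(record.core_volume_mm3, rel=0.05)

    def test_no_surviving_component_below_30_voxels(self):
        spec, (vol, mask, _) = self._cored_phantom(20.0)
        cyst_mask, _ = bs.segment_cystic(vol, mask)
        from scipy import ndimage

        comp, n = ndimage.label(cyst_mask.labels, structure=np.ones((3, 3, 3)))
        if n:
            assert np.bincount(comp.ravel())[1:].min() >= 30

    def test_cyst_mean_below_lesion_mean_when_found(self):
        spec, (vol, mask, _) = self._cored_phantom(20.0)
        _, report = bs.segment_cystic(vol, mask)
        assert report.n_cyst_components >= 1
        assert report.cyst_mean_intensity < report.lesion_mean_intensity

    def test_degenerate_histogram_reports_no_cyst(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[2:6, 2:6, 2:6] = 1
        vol = bs.Volume3D(data=np.full((8, 8, 8), 42.0), spacing_mm=(1, 1, 1))
        cyst, report = bs.segment_cystic(vol, _mask(labels))
        assert cyst.voxel_count == 0
        assert report.otsu_threshold is None


class TestStaging:
    @pytest.mark.parametrize(
        "diameter,stage",
        [
            (27.41, "T2"),  # cohort-scale mean maximal diameter
            (20.0, "T1"),
            (50.0, "T2"),
            (60.0, "T3"),
            (5.0, "T1"),
            (20.01, "T2"),
            (50.01, "T3"),
        ],
    )
    def test_boundary_policy(self, diameter, stage):
        assert bs.classify_t_stage(diameter) == stage

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bs.classify_t_stage(-1.0)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            StagingRules(t1_max_mm=50, t2_max_mm=20)


class TestRemoveSmallComponents:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_no_surviving_component_below_threshold(self, seed):
        rng = np.random.default_rng(seed)
        labels = (rng.uniform(size=(14, 14, 14)) > 0.8).astype(np.uint8)
        out = remove_small_components(labels, 30)
        from scipy import ndimage

        comp, n = ndimage.label(out, structure=np.ones((3, 3, 3)))
        if n:
            assert np.bincount(comp.ravel())[1:].min() >= 30
        # idempotent
        np.testing.assert_array_equal(remove_small_components(out, 30), out)
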