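"""Sphere segmentation and the RC / CoV / CRC / CNR / lung-error suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phantomiq as pq
from phantomiq.metrics import PlacementError, SegmentationError

from conftest import TEST_SHAPE


def _scaled(grid: pq.Grid3D, c: float) -> pq.Grid3D:
    return pq.Grid3D(grid.values * c, grid.spacing, grid.origin)


class TestSegmentation:
    def test_binary_sphere_reduces_to_half_max(self):
        """With zero background the mask is exactly the >= 50%-max voxels."""
        spec = pq.PhantomSpec(
            sphere_diameters=(17.0,), sphere_centers=((0.0, 0.0, 0.0),),
            background_activity=0.0, sphere_activity=10.0,
            wall_thickness=0.0, lung_insert=None,
        )
        g = pq.rasterize_phantom(spec, shape=(40, 40, 40), supersampling=4)
        mask = pq.segment_sphere(g, (0.0, 0.0, 0.0), 0.0, 17.0)
        assert np.array_equal(mask, g.values >= 0.5 * g.values.max())

    def test_uniform_image_raises(self):
        g = pq.Grid3D(np.full((30, 30, 30), 5.3), (1.65, 1.65, 1.5), (0, 0, 0))
        with pytest.raises(SegmentationError, match="suprathreshold"):
            pq.segment_sphere(g, (24.0, 24.0, 22.0), 5.3, 17.0)

    def test_mask_volume_near_truth_ratio8(self, nema_truth_r8, nema_spec_r8):
        """Isocontour volume of the blurred 37-mm sphere tracks the real volume."""
        deg = pq.DegradationSpec(system_fwhm=4.5, nuclide=None, target_trues=None)
        img = pq.blur_image(nema_truth_r8, deg)
        spec = nema_spec_r8
        i = spec.sphere_diameters.index(37.0)
        mask = pq.segment_sphere(
            img, spec.sphere_centers[i], spec.background_activity, 37.0
        )
        vol = mask.sum() * img.voxel_volume_ml
        true_vol = (4.0 / 3.0) * math.pi * 18.5**3 / 1000.0
        assert abs(vol - true_vol) / true_vol < 0.15


class TestBackgroundVois:
    def test_uniform_field_stats(self, nema_truth, nema_spec):
        """On the unblurred phantom the VOIs are exactly uniform background."""
        bg = pq.place_background_vois(nema_truth, nema_spec)
        assert bg.mean == pytest.approx(5.3, rel=1e-12)
        assert bg.cov_bg == 0.0
        assert all(v >= 61.0 for v in bg.voi_volumes_ml)

    def test_deterministic_and_disjoint(self, nema_truth, nema_spec):
        a = pq.place_background_vois(nema_truth, nema_spec)
        b = pq.place_background_vois(nema_truth, nema_spec)
        for ma, mb in zip(a.voi_masks, b.voi_masks):
            assert np.array_equal(ma, mb)
        union_count = sum(m.sum() for m in a.voi_masks)
        union = np.zeros_like(a.voi_masks[0])
        for m in a.voi_masks:
            union |= m
        assert union.sum() == union_count  # pairwise disjoint

    def test_cov_matches_poisson_prediction(self, nema_truth, nema_spec):
        deg = pq.DegradationSpec(
            system_fwhm=4.5, nuclide=None, target_trues=7.1e7, seed=3
        )
        img = pq.degrade_image(nema_truth, deg)
        bg = pq.place_background_vois(img, nema_spec)
        predicted = pq.expected_cov(deg, 5.3, nema_truth)
        assert bg.cov_bg == pytest.approx(predicted, rel=0.10)

    def test_unsatisfiable_clearance_raises(self, nema_truth, nema_spec):
        with pytest.raises(PlacementError):
            pq.place_background_vois(nema_truth, nema_spec, ring_radius=40.0)
        with pytest.raises(PlacementError):
            pq.place_background_vois(nema_truth, nema_spec, axial_offset=20.0)


class TestRecoveryCoefficients:
    def test_identity_and_homogeneity(self, nema_truth, nema_spec):
        """Unblurred sphere recovers (1,1,1); doubling the image doubles RCs."""
        spec = nema_spec
        i = spec.sphere_diameters.index(28.0)
        mask = (
            nema_truth.distance2_field(spec.sphere_centers[i]) <= 10.0**2
        )  # strictly interior voxels
        rc = pq.recovery_coefficients(nema_truth, mask, spec.sphere_activity)
        assert rc == pytest.approx((1.0, 1.0, 1.0), rel=1e-12)
        rc2 = pq.recovery_coefficients(
            _scaled(nema_truth, 2.0), mask, spec.sphere_activity
        )
        assert rc2 == pytest.approx((2.0, 2.0, 2.0), rel=1e-12)

    def test_blurred_rc_mean_matches_continuum_oracle(self, nema_truth, nema_spec):
        """37-mm rc_mean agrees with the analytic isocontour integral (0.917)."""
        deg = pq.DegradationSpec(system_fwhm=4.5, nuclide=None, target_trues=None)
        img = pq.blur_image(nema_truth, deg)
        spec = nema_spec
        rc = {}
        for c, d in zip(spec.sphere_centers, spec.sphere_diameters):
            mask = pq.segment_sphere(img, c, spec.background_activity, d)
            rc[d] = pq.recovery_coefficients(img, mask, spec.sphere_activity)
        # frozen from the continuum isocontour-mask integral of the blurred
        # sphere profile (scipy.integrate.quad on the closed-form profile)
        assert rc[37.0][0] == pytest.approx(0.917, abs=0.02)
        assert rc[10.0][0] < rc[37.0][0]
        for d, (rc_mean, rc_max, rc_peak) in rc.items():
            assert rc_max >= rc_peak >= 0.0
            assert rc_max >= rc_mean

    def test_invalid_inputs(self, nema_truth):
        mask = np.zeros(TEST_SHAPE, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            pq.recovery_coefficients(nema_truth, mask, 21.2)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="true_activity"):
            pq.recovery_coefficients(nema_truth, mask, 0.0)


class TestContrastMetrics:
    def test_crc_endpoints_and_arithmetic(self):
        assert pq.contrast_recovery(42.4, 5.3, 42.4, 5.3) == pytest.approx(100.0)
        assert pq.contrast_recovery(5.3, 5.3, 42.4, 5.3) == pytest.approx(0.0)
        assert pq.contrast_recovery(8.0, 1.1, 8.0, 1.0) == pytest.approx(
            100.0 * (8.0 / 1.1 - 1.0) / 7.0
        )
        assert pq.contrast_recovery(8.0, 1.1, 8.0, 1.0) == pytest.approx(89.6, abs=0.05)

    def test_crc_invalid(self):
        with pytest.raises(ValueError):
            pq.contrast_recovery(8.0, 1.0, 5.0, 5.0)
        with pytest.raises(ValueError):
            pq.contrast_recovery(8.0, 0.0, 8.0, 1.0)

    def test_cnr(self):
        assert pq.contrast_noise_ratio(8.0, 1.0, 0.1) == pytest.approx(70.0)
        assert pq.contrast_noise_ratio(5.0, 5.0, 0.1) == 0.0
        assert pq.contrast_noise_ratio(8.0, 1.0, 0.05) == pytest.approx(140.0)
        with pytest.raises(ValueError, match="noiseless"):
            pq.contrast_noise_ratio(8.0, 1.0, 0.0)


class TestLungError:
    def test_cold_insert_is_zero_unblurred(self, nema_truth, nema_spec):
        bg = pq.place_background_vois(nema_truth, nema_spec)
        lung = pq.lung_count_error(nema_truth, nema_spec, bg)
        assert lung.relative_count_error == 0.0

    def test_filled_insert_reads_100(self):
        spec = pq.PhantomSpec.nema(
            ratio=4.0, lung_insert=pq.LungInsert(activity=5.3)
        )
        g = pq.rasterize_phantom(spec, shape=TEST_SHAPE, supersampling=2)
        bg = pq.place_background_vois(g, spec)
        lung = pq.lung_count_error(g, spec, bg)
        assert lung.relative_count_error == pytest.approx(100.0, rel=1e-9)

    def test_monotone_in_blur(self, nema_truth, nema_spec):
        errs = []
        for fwhm in (4.5, 8.0, 12.0, 16.0):
            deg = pq.DegradationSpec(
                system_fwhm=fwhm, nuclide=None, target_trues=None
            )
            img = pq.blur_image(nema_truth, deg)
            bg = pq.place_background_vois(img, nema_spec)
            errs.append(
                pq.lung_count_error(img, nema_spec, bg).relative_count_error
            )
        assert all(b >= a - 1e-9 for a, b in zip(errs, errs[1:]))
        assert 0.0 <= errs[0] <= errs[-1] <= 15.0


class TestScaleInvariance:
    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(c=st.floats(0.1, 10.0))
    def test_metrics_invariant_under_global_rescale(
        self, c, noisy_image, nema_spec
    ):
        """RC, CRC, CoV, CNR and lung error ignore the intensity scale."""
        img = noisy_image
        spec = nema_spec
        scaled = _scaled(img, c)
        bg1 = pq.place_background_vois(img, spec)
        bg2 = pq.place_background_vois(scaled, spec)
        assert bg2.cov_bg == pytest.approx(bg1.cov_bg, rel=1e-9)
        i = spec.sphere_diameters.index(22.0)
        m1 = pq.segment_sphere(img, spec.sphere_centers[i], bg1.mean, 22.0)
        m2 = pq.segment_sphere(scaled, spec.sphere_centers[i], bg2.mean, 22.0)
        assert np.array_equal(m1, m2)
        rc1 = pq.recovery_coefficients(img, m1, spec.sphere_activity)
        rc2 = pq.recovery_coefficients(scaled, m2, c * spec.sphere_activity)
        assert rc2 == pytest.approx(rc1, rel=1e-9)
        crc1 = pq.contrast_recovery(
            rc1[0] * spec.sphere_activity, bg1.mean,
            spec.sphere_activity, spec.background_activity,
        )
        crc2 = pq.contrast_recovery(
            rc2[0] * c * spec.sphere_activity, bg2.mean,
            c * spec.sphere_activity, c * spec.background_activity,
        )
        assert crc2 == pytest.approx(crc1, rel=1e-9)
        cnr1 = pq.contrast_noise_ratio(rc1[0] * spec.sphere_activity, bg1.mean, bg1.sd)
        cnr2 = pq.contrast_noise_ratio(
            rc2[0] * c * spec.sphere_activity, bg2.mean, bg2.sd
        )
        assert cnr2 == pytest.approx(cnr1, rel=1e-9)
        lung1 = pq.lung_count_error(img, spec, bg1).relative_count_error
        lung2 = pq.lung_count_error(scaled, spec, bg2).relative_count_error
        assert lung2 == pytest.approx(lung1, rel=1e-9, abs=1e-12)


class TestEdgeEnhancement:
    def test_small_sphere_overshoot_exceeds_large(self, nema_truth, nema_spec):
        """With the unsharp-mask artifact on, the 10-mm rc_max tops the 37-mm."""
        deg = pq.DegradationSpec(
            system_fwhm=4.5, nuclide=None, target_trues=None,
            edge_enhancement=(0.7, 4.0),
        )
        img = pq.blur_image(nema_truth, deg)
        spec = nema_spec
        bg = pq.place_background_vois(img, spec)
        rc = {}
        for c, d in zip(spec.sphere_centers, spec.sphere_diameters):
            mask = pq.segment_sphere(img, c, bg.mean, d)
            rc[d] = pq.recovery_coefficients(img, mask, spec.sphere_activity)
        assert rc[10.0][1] > rc[37.0][1]


def test_analyze_image_end_to_end(noisy_image, nema_spec):
    spheres, bg, lung = pq.analyze_image(noisy_image, nema_spec)
    assert [s.diameter for s in spheres] == sorted(nema_spec.sphere_diameters)
    for s in spheres:
        assert s.mask.any()
        assert s.rc_max >= s.rc_peak >= 0.0
        assert s.rc_max >= s.rc_mean > 0.0
        assert np.isfinite(s.cnr)
    assert bg.cov_bg > 0.0
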