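"""NEMA SNR/CNR, liver VOI placement, liver SNR and tumour CNR."""

import numpy as np
import pytest

from petiq import (
    build_nema_fixture,
    liver_snr,
    nema_background_rois,
    nema_metrics,
    place_liver_voi,
    tumour_cnr,
)
from petiq.metrics import NEMA_SPHERE_DIAMETERS_MM, MetricsError
from petiq.sim import ReconImage


@pytest.fixture(scope="module")
def fixture():
    return build_nema_fixture()


class TestNemaRois:
    def test_sixty_rois_per_diameter(self, fixture):
        for d in NEMA_SPHERE_DIAMETERS_MM:
            assert len(nema_background_rois(fixture.geometry, d)) == 60

    def test_rois_disjoint_in_plane(self, fixture):
        rois = nema_background_rois(fixture.geometry, 37.0)
        central = [m for m in rois if m[:, :, fixture.geometry.central_slice].any()]
        assert len(central) == 12
        stack = np.array([m[:, :, fixture.geometry.central_slice] for m in central])
        assert np.all(stack.sum(axis=0) <= 1)

    def test_rois_inside_background(self, fixture):
        sph = np.zeros(fixture.geometry.shape, dtype=bool)
        for m in fixture.sphere_masks.values():
            sph |= m
        for m in nema_background_rois(fixture.geometry, 37.0):
            assert fixture.body_mask[m].all()
            assert not (m & sph).any()

    def test_too_small_fixture_errors(self):
        small = build_nema_fixture(body_semi_axes_mm=(80.0, 60.0), sphere_ring_radius_mm=30.0)
        with pytest.raises(MetricsError):
            nema_background_rois(small.geometry, 37.0)


class TestNemaMetrics:
    def test_synthetic_statistics(self, fixture, rng):
        """Flat background mean 100, SD 10, spheres at 400 -> SNR ~ 10,
        CNR ~ 30, each within 5% averaged over seeds."""
        g = fixture.geometry
        snrs, cnrs = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals = r.normal(100.0, 10.0, size=g.shape)
            for m in fixture.sphere_masks.values():
                vals[m] += 300.0
            res = nema_metrics(ReconImage(vals, g.spacing), g, diameters_mm=(37.0,))
            snrs.append(res.snr[37.0])
            cnrs.append(res.cnr[37.0])
        assert np.mean(snrs) == pytest.approx(10.0, rel=0.05)
        assert np.mean(cnrs) == pytest.approx(30.0, rel=0.05)

    def test_degenerate_background_errors(self, fixture):
        g = fixture.geometry
        vals = np.full(g.shape, 7.0)
        with pytest.raises(MetricsError, match="degenerate"):
            nema_metrics(ReconImage(vals, g.spacing), g, diameters_mm=(37.0,))

    def test_equal_means_zero_cnr(self, fixture, rng):
        g = fixture.geometry
        vals = rng.normal(100.0, 10.0, size=g.shape)  # no sphere contrast
        res = nema_metrics(ReconImage(vals, g.spacing), g, diameters_mm=(28.0,))
        assert res.cnr[28.0] == pytest.approx(0.0, abs=0.5)

    def test_affine_equivariance(self, fixture, rng):
        g = fixture.geometry
        vals = rng.normal(100.0, 10.0, size=g.shape)
        for m in fixture.sphere_masks.values():
            vals[m] += 300.0
        r0 = nema_metrics(ReconImage(vals, g.spacing), g, diameters_mm=(37.0,))
        r_shift = nema_metrics(ReconImage(vals + 50.0, g.spacing), g, diameters_mm=(37.0,))
        r_scale = nema_metrics(ReconImage(vals * 3.0, g.spacing), g, diameters_mm=(37.0,))
        assert r_shift.background_sd[37.0] == pytest.approx(r0.background_sd[37.0], rel=1e-9)
        assert r_shift.background_mean[37.0] == pytest.approx(
            r0.background_mean[37.0] + 50.0, rel=1e-9
        )
        assert r_scale.snr[37.0] == pytest.approx(r0.snr[37.0], rel=1e-9)
        assert r_scale.cnr[37.0] == pytest.approx(r0.cnr[37.0], rel=1e-9)


class TestLiverVoi:
    def test_tumour_free_voi_at_inscribed_centre(self, small_phantom):
        """VOI centre maximises liver boundary distance (distance-transform
        oracle computed here independently)."""
        from scipy import ndimage
        from petiq.structures import LIVER

        voi = place_liver_voi(small_phantom, diameter_mm=25.0)
        liver = small_phantom.codes == LIVER
        dist = ndimage.distance_transform_edt(liver, sampling=small_phantom.spacing)
        # the VOI ball sits wholly inside the liver at maximal depth
        assert liver[voi].all()
        ci = np.array(np.nonzero(voi)).mean(axis=1).round().astype(int)
        assert dist[tuple(ci)] >= dist.max() - max(small_phantom.spacing)

    def test_voi_avoids_tumours(self, small_phantom):
        from petiq import grow_tumour_set, place_seeds
        from petiq.structures import LIVER

        liver = small_phantom.codes == LIVER
        seeds = place_seeds(liver, small_phantom.spacing, n=3, min_separation_mm=25, rng_seed=4)
        tset = grow_tumour_set(small_phantom, seeds, (2.0, 3.0, 4.0))
        tmask = tset.combined_mask()
        voi = place_liver_voi(small_phantom, tmask, diameter_mm=25.0)
        assert not (voi & tmask).any()

    def test_liver_smaller_than_voi_errors(self, small_phantom):
        with pytest.raises(MetricsError):
            place_liver_voi(small_phantom, diameter_mm=300.0)


class TestLiverSnrCnr:
    def test_hand_computed_snr(self):
        """VOI values {90, 100, 110}: SNR = 100 / 8.165 (population SD)."""
        vals = np.array([90.0, 100.0, 110.0]).reshape(3, 1, 1)
        voi = np.ones((3, 1, 1), dtype=bool)
        assert liver_snr(vals, voi) == pytest.approx(100.0 / 8.16497, abs=1e-3)

    def test_zero_contrast_zero_cnr(self, rng):
        vals = rng.normal(100.0, 5.0, size=(12, 12, 6))
        voi = np.zeros_like(vals, dtype=bool)
        voi[2:6, 2:6, 1:4] = True
        tum = np.zeros_like(voi)
        tum[8:10, 8:10, 1:3] = True
        vals[tum] = vals[voi].mean()
        cnr, rose = tumour_cnr(vals, tum, voi)
        assert cnr == pytest.approx(0.0, abs=1e-9)
        assert not rose

    def test_rose_boundary_inclusive(self, rng):
        vals = rng.normal(100.0, 5.0, size=(12, 12, 6))
        voi = np.zeros(vals.shape, dtype=bool)
        voi[2:6, 2:6, 1:4] = True
        sd = vals[voi].std()
        tum = np.zeros_like(voi)
        tum[9, 9, 2] = True
        vals[9, 9, 2] = vals[voi].mean() + 5.0 * sd
        cnr, rose = tumour_cnr(vals, tum, voi)
        assert cnr == pytest.approx(5.0, abs=1e-9)
        assert rose

    def test_zero_sd_errors(self):
        vals = np.full((4, 4, 4), 3.0)
        voi = np.ones_like(vals, dtype=bool)
        with pytest.raises(MetricsError):
            liver_snr(vals, voi)


class TestNemaReconRegression:
    def test_37mm_sphere_ratio_with_partial_volume(self, fixture):
        """Reconstructed 37 mm sphere-to-background ratio falls in [3, 4]
        (true ratio 3.98, reduced by partial-volume averaging)."""
        from petiq import reconstruct, simulate_counts

        g = fixture.geometry
        sino = simulate_counts(
            fixture.activity_bq_per_voxel, fixture.mu, t_min=3.0, sensitivity=2e-4,
            background_fraction=0.3, rng_seed=7, pixel_mm=g.spacing[0],
        )
        img = reconstruct(sino, fixture.mu, spacing=g.spacing)
        res = nema_metrics(img, g, diameters_mm=(37.0,))
        ratio = res.sphere_mean[37.0] / res.background_mean[37.0]
        assert 3.0 <= ratio <= 4.0

    def test_true_fixture_ratio_rounds_to_four(self, fixture):
        assert round(fixture.true_ratio) == 4
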