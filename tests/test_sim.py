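"""Acquisition + OSEM reconstruction physics."""

import numpy as np
import pytest

from petiq import attenuation_map, get_projector, reconstruct, simulate_counts
from petiq.sim import MU_WATER_511_MM, Sinogram, expected_sinogram


def _cylinder(n=64, nz=5, radius_mm=100.0, pixel_mm=4.0, act=500.0, water=True):
    xs = (np.arange(n) - (n - 1) / 2) * pixel_mm
    disk = (xs[:, None] ** 2 + xs[None, :] ** 2) <= radius_mm**2
    activity = np.where(disk, act, 0.0)[:, :, None] * np.ones(nz)
    mu = np.where(disk, MU_WATER_511_MM if water else 0.0, 0.0)[:, :, None] * np.ones(nz)
    return activity, mu


class TestAttenuationMap:
    def test_water_and_air_values(self, small_phantom):
        from petiq.structures import AIR, BLADDER

        mu = attenuation_map(small_phantom)
        assert np.all(mu[small_phantom.codes == AIR] == 0.0)
        # bladder contents have density 1.00 -> exactly mu_water
        assert np.allclose(mu[small_phantom.codes == BLADDER], 0.0096)

    def test_200mm_water_transmission(self):
        assert np.exp(-0.0096 * 200.0) == pytest.approx(0.147, abs=5e-4)


class TestSimulateCounts:
    def test_zero_activity_zero_counts(self):
        act, mu = _cylinder(act=0.0)
        sino = simulate_counts(act, mu, background_fraction=0.0, pixel_mm=4.0, n_angles=32)
        assert sino.counts.sum() == 0

    def test_total_expected_counts_no_attenuation(self):
        """With mu=0, b=0: total expected counts = s*t*sum(A)*n_angles."""
        act, mu = _cylinder(water=False)
        proj = get_projector(64, 4.0, 32)
        trues, r = expected_sinogram(act, mu * 0.0, 3.0, 1e-3, 0.0, proj)
        assert r == 0.0
        expected = 1e-3 * 3.0 * act.sum() * 32
        assert trues.sum() == pytest.approx(expected, rel=1e-6)

    def test_background_fraction_of_total(self):
        act, mu = _cylinder()
        proj = get_projector(64, 4.0, 32)
        trues, r = expected_sinogram(act, mu, 3.0, 1e-3, 0.3, proj)
        total = trues.sum() + r * trues.size
        assert r * trues.size / total == pytest.approx(0.3, rel=1e-9)

    def test_doubling_time_doubles_counts(self):
        """Mean total counts over seeds doubles with t (3 sigma Poisson band)."""
        act, mu = _cylinder(n=48, nz=2, act=50.0)
        tot1, tot2 = [], []
        for seed in range(30):
            s1 = simulate_counts(act, mu, t_min=1.0, sensitivity=2e-4, rng_seed=seed,
                                 pixel_mm=4.0, n_angles=32)
            s2 = simulate_counts(act, mu, t_min=2.0, sensitivity=2e-4, rng_seed=1000 + seed,
                                 pixel_mm=4.0, n_angles=32)
            tot1.append(s1.counts.sum())
            tot2.append(s2.counts.sum())
        m1, m2 = np.mean(tot1), np.mean(tot2)
        sigma = np.sqrt(m2 / 30 + 4 * m1 / 30)
        assert abs(m2 - 2 * m1) < 3 * sigma

    def test_reproducible_per_seed(self):
        act, mu = _cylinder(n=48, nz=2)
        a = simulate_counts(act, mu, rng_seed=42, pixel_mm=4.0, n_angles=32)
        b = simulate_counts(act, mu, rng_seed=42, pixel_mm=4.0, n_angles=32)
        assert np.array_equal(a.counts, b.counts)

    def test_mismatched_grids_rejected(self):
        act, mu = _cylinder()
        with pytest.raises(ValueError):
            simulate_counts(act, mu[:, :, :2], pixel_mm=4.0)


class TestReconstruct:
    def test_zero_sinogram_zero_image(self):
        act, mu = _cylinder(n=48, nz=2, act=0.0)
        sino = simulate_counts(act, mu, background_fraction=0.0, pixel_mm=4.0, n_angles=32)
        img = reconstruct(sino, mu, spacing=(4.0, 4.0, 4.0))
        assert np.allclose(img.values, 0.0)

    def test_noiseless_disk_quantitative(self):
        """Many-iteration OSEM on a noiseless uniform disk recovers the
        painted concentration within 2% (no attenuation, no filter)."""
        act, mu = _cylinder(n=64, nz=1, radius_mm=80.0, act=200.0, water=False)
        proj = get_projector(64, 4.0, 32)
        trues, _ = expected_sinogram(act, mu, 3.0, 1e-2, 0.0, proj)
        sino = Sinogram(
            counts=trues.reshape(32, 64, 1), t_min=3.0, sensitivity=1e-2,
            background_fraction=0.0, background_level=0.0, n_angles=32, pixel_mm=4.0,
        )
        img = reconstruct(sino, mu, iterations=20, subsets=8,
                          fwhm_trans_mm=0.0, fwhm_ax_mm=0.0, spacing=(4.0, 4.0, 4.0))
        xs = (np.arange(64) - 31.5) * 4.0
        inner = (xs[:, None] ** 2 + xs[None, :] ** 2) <= 60.0**2
        truth = 200.0 / (4.0 * 4.0 * 4.0 / 1000.0)  # Bq/voxel -> Bq/mL
        assert img.values[:, :, 0][inner].mean() == pytest.approx(truth, rel=0.02)

    def test_point_source_argmax(self):
        """Pre-filter image peaks at the source voxel."""
        act = np.zeros((48, 48, 1))
        act[30, 18, 0] = 1000.0
        mu = np.zeros_like(act)
        proj = get_projector(48, 4.0, 32)
        trues, _ = expected_sinogram(act, mu, 3.0, 1.0, 0.0, proj)
        sino = Sinogram(
            counts=trues.reshape(32, 48, 1), t_min=3.0, sensitivity=1.0,
            background_fraction=0.0, background_level=0.0, n_angles=32, pixel_mm=4.0,
        )
        img = reconstruct(sino, mu, iterations=5, subsets=8,
                          fwhm_trans_mm=0.0, fwhm_ax_mm=0.0, spacing=(4.0, 4.0, 4.0))
        assert np.unravel_index(np.argmax(img.values), img.values.shape) == (30, 18, 0)

    def test_nonneg_and_positivity_preserved(self):
        act, mu = _cylinder(n=48, nz=2, act=20.0)
        sino = simulate_counts(act, mu, rng_seed=0, sensitivity=1e-3, pixel_mm=4.0, n_angles=32)
        img = reconstruct(sino, mu, spacing=(4.0, 4.0, 4.0))
        assert np.all(img.values >= 0.0)

    def test_bad_subset_count_rejected(self):
        act, mu = _cylinder(n=48, nz=1)
        sino = simulate_counts(act, mu, rng_seed=0, pixel_mm=4.0, n_angles=32)
        with pytest.raises(ValueError, match="subsets"):
            reconstruct(sino, mu, subsets=7, spacing=(4.0, 4.0, 4.0))


def _roi_snr(img, n=64, pixel_mm=4.0, radius_mm=40.0):
    xs = (np.arange(n) - (n - 1) / 2) * pixel_mm
    roi = (xs[:, None] ** 2 + xs[None, :] ** 2) <= radius_mm**2
    vals = img.values[roi.nonzero()[0], roi.nonzero()[1], :].ravel()
    return vals.mean() / vals.std()


class TestNoiseScaling:
    def test_snr_scales_as_sqrt_activity_time(self):
        """Quadrupling the time-activity product doubles ROI SNR (+-15%
        over >= 20 seeds) -- the premise of the SNR normalisation."""
        act, mu = _cylinder(n=64, nz=9, radius_mm=110.0, act=60.0)
        ratios = []
        for seed in range(20):
            imgs = []
            for t, sd in ((1.0, seed), (4.0, 5000 + seed)):
                sino = simulate_counts(act, mu, t_min=t, sensitivity=2e-3,
                                       background_fraction=0.3, rng_seed=sd,
                                       pixel_mm=4.0, n_angles=32)
                imgs.append(reconstruct(sino, mu, subsets=8, spacing=(4.0, 4.0, 4.0)))
            ratios.append(_roi_snr(imgs[1]) / _roi_snr(imgs[0]))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_snr_decreases_with_body_size(self):
        """Fixed A*t: widening the water column monotonically lowers SNR
        in a central ROI (3-point habitus monotonicity)."""
        snrs = []
        for radius in (80.0, 105.0, 125.0):
            act, mu = _cylinder(n=64, nz=9, radius_mm=radius, act=60.0)
            vals = []
            for seed in range(5):
                sino = simulate_counts(act, mu, t_min=3.0, sensitivity=2e-3,
                                       background_fraction=0.3, rng_seed=seed,
                                       pixel_mm=4.0, n_angles=32)
                img = reconstruct(sino, mu, subsets=8, spacing=(4.0, 4.0, 4.0))
                vals.append(_roi_snr(img, radius_mm=40.0))
            snrs.append(np.mean(vals))
        assert snrs[0] > snrs[1] > snrs[2]
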