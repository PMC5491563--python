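"""Ring-kernel similarity tests: kernel geometry, correlation, coherence."""

import numpy as np
import pytest
from scipy.signal import coherence as scipy_coherence

from mpdceus import (
    DceusLoop,
    SimilarityConfig,
    ldrw_curve,
    ring_kernel,
    similarity_maps,
    spatiotemporal_correlation,
    spectral_coherence,
)


class TestRingKernel:
    def test_unit_spacing_matches_brute_force(self):
        """At 1 mm spacing the [1.0, 2.5] mm ring holds exactly 20 offsets."""
        offsets = set(ring_kernel(1.0, 1.0, 2.5))
        brute = {
            (dr, dc)
            for dr in range(-3, 4)
            for dc in range(-3, 4)
            if (dr, dc) != (0, 0) and 1.0 <= np.hypot(dr, dc) <= 2.5
        }
        assert offsets == brute
        assert len(offsets) == 20

    def test_coarse_spacing_raises(self):
        with pytest.raises(ValueError):
            ring_kernel(3.0, 1.0, 2.5)

    def test_negation_and_swap_symmetry(self):
        offsets = set(ring_kernel(0.5, 1.0, 2.5))
        assert all((-dr, -dc) in offsets for dr, dc in offsets)
        assert all((dc, dr) in offsets for dr, dc in offsets)


class TestCorrelation:
    def test_identical_neighbors(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        assert spatiotemporal_correlation(x, np.tile(x, (5, 1))) == pytest.approx(1.0)

    def test_mirrored_neighbors(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        mirrored = -(x - x.mean()) + x.mean()
        assert spatiotemporal_correlation(x, mirrored[None, :]) == pytest.approx(-1.0)

    def test_independent_noise_null(self):
        """Mean r over 1000 independent pairs sits within +-0.05 of zero."""
        rng = np.random.default_rng(42)
        vals = [
            spatiotemporal_correlation(rng.standard_normal(64), rng.standard_normal((1, 64)))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_zero_variance_center(self):
        assert np.isnan(spatiotemporal_correlation(np.ones(50), np.random.default_rng(0).standard_normal((3, 50))))

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(80)
        nb = rng.standard_normal((4, 80))
        r1 = spatiotemporal_correlation(x, nb)
        r2 = spatiotemporal_correlation(3.2 * x + 7, 0.5 * nb - 2)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestCoherence:
    def test_identical_signals(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(128)
        assert spectral_coherence(x, x[None, :], fs=4.0) == pytest.approx(1.0)

    def test_gain_and_delay_invariance(self):
        """A scaled, slightly delayed bolus keeps coherence near one."""
        t = np.arange(0, 40, 0.25)
        x = ldrw_curve(t, 1.0, 12.0, 0.8, 3.0) + 0.05 * np.sin(2 * np.pi * 0.3 * t)
        y = 3.0 * ldrw_curve(t, 1.0, 12.0, 0.8, 3.5) + 0.15 * np.sin(2 * np.pi * 0.3 * (t - 0.5))
        assert spectral_coherence(x, y[None, :], fs=4.0) > 0.95

    def test_independent_noise_low(self):
        rng = np.random.default_rng(9)
        vals = [
            spectral_coherence(rng.standard_normal(100), rng.standard_normal((1, 100)), fs=4.0)
            for _ in range(200)
        ]
        assert np.mean(vals) < 0.3

    def test_matches_scipy_estimator(self):
        """Same Welch settings as scipy.signal.coherence, same numbers."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        mine = spectral_coherence(x, y[None, :], fs=4.0, band=(0.0, 2.0), nperseg=64)
        f, c = scipy_coherence(x, y, fs=4.0, nperseg=64)
        ref = c[(f > 0) & (f <= 2.0)].mean()
        assert mine == pytest.approx(ref, abs=1e-10)


@pytest.fixture(scope="module")
def uniform_loop():
    t = np.arange(0, 120, 0.25)
    y = ldrw_curve(t, 1.0, 20.0, 0.7, 6.0)
    frames = np.tile(y[:, None, None], (1, 14, 14))
    return DceusLoop(frames, 4.0, 1.0)


class TestMaps:

    def test_uniform_phantom_r_one(self, uniform_loop):
        maps = similarity_maps(uniform_loop)
        assert np.all(maps.r[maps.valid] == pytest.approx(1.0))
        assert np.all(maps.rho[maps.valid] == pytest.approx(1.0))
        assert maps.valid[7, 7]

    def test_shapes_and_bounds(self, uniform_loop):
        maps = similarity_maps(uniform_loop)
        assert maps.r.shape == (14, 14)
        v = maps.valid
        assert np.all(maps.r[v] >= -1) and np.all(maps.r[v] <= 1)
        assert np.all(maps.rho[v] >= 0) and np.all(maps.rho[v] <= 1)

    def test_border_neighbor_counts(self, uniform_loop):
        maps = similarity_maps(uniform_loop)
        assert maps.n_neighbors[0, 0] < maps.n_neighbors[7, 7]
        # corner pixel has only a quarter of the ring available
        assert maps.n_neighbors[7, 7] == 20

    def test_independent_noise_mean_r_near_zero(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((120, 12, 12)) + 10.0
        maps = similarity_maps(
            DceusLoop(frames, 4.0, 1.0),
            SimilarityConfig(window_pre=100.0, window_post=100.0),
        )
        assert abs(np.nanmean(maps.r[maps.valid])) < 0.05

    def test_class_contrast_by_construction(self, tmp_path):
        """Short malignant coherence scale depresses lesion r below benign r."""
        from mpdceus import FeatureConfig, PhantomConfig, generate_phantom
        from mpdceus.preprocessing import smooth

        cfg = PhantomConfig(frame_rate=4.0, seed=21)
        loop, truth = generate_phantom(cfg)
        maps = similarity_maps(smooth(loop, 0.0, 0.5))
        mal = truth.label_map == 1
        ben = np.zeros_like(mal)
        for roi in truth.rois:
            if roi.label == 0:
                ben |= roi.mask
        assert np.nanmean(maps.r[ben]) > np.nanmean(maps.r[mal])
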