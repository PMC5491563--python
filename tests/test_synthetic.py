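"""Phantom generator tests: kinetic identity, geometry, seeds, noise."""

import dataclasses

import numpy as np
import pytest

from mpdceus import PhantomConfig, generate_cohort, generate_phantom, ldrw_curve
from mpdceus.preprocessing import extract_tic_stack, smooth
from mpdceus.synthetic import NoiseModel, Recirculation


class TestPhantom:
    def test_noiseless_pixel_matches_ldrw(self, noiseless_phantom):
        """Every noiseless, recirculation-free pixel TIC is the exact model curve."""
        _, loop, truth = noiseless_phantom
        pm = truth.parameter_maps
        rng = np.random.default_rng(0)
        for _ in range(10):
            r, c = rng.integers(0, 32, 2)
            expected = ldrw_curve(
                loop.times, pm["alpha"][r, c], pm["mu"][r, c], pm["kappa"][r, c], pm["t0"][r, c]
            ) + pm["echogenicity"][r, c]
            assert np.max(np.abs(loop.frames[:, r, c] - expected)) < 1e-12

    def test_lesion_area_arithmetic(self):
        """2 lesions of 0.5 cm2 at 0.5 mm/px -> 2 components of ~200 px."""
        from scipy.ndimage import label

        cfg = PhantomConfig(seed=4)
        _, truth = generate_phantom(cfg)
        lab, n = label(truth.label_map)
        assert n == 2
        sizes = np.bincount(lab.ravel())[1:]
        assert np.all(np.abs(sizes - 200) < 25)  # rasterization error
        frac = truth.label_map.mean()
        assert frac == pytest.approx(2 * 200 / 64**2, rel=0.15)

    def test_seed_contract(self):
        cfg = PhantomConfig(grid_height=32, grid_width=32, n_lesions=1, lesion_area=0.2,
                            frame_rate=4.0, seed=5)
        loop_a, truth_a = generate_phantom(cfg)
        loop_b, truth_b = generate_phantom(cfg)
        assert np.array_equal(loop_a.frames, loop_b.frames)
        assert np.array_equal(truth_a.label_map, truth_b.label_map)
        cfg2 = dataclasses.replace(cfg, seed=6)
        loop_c, truth_c = generate_phantom(cfg2)
        assert not np.array_equal(loop_a.frames, loop_c.frames)
        # same number of lesion components regardless of seed
        from scipy.ndimage import label

        assert label(truth_a.label_map)[1] == label(truth_c.label_map)[1] == 1

    def test_malignant_pixels_use_malignant_field(self, noiseless_phantom):
        cfg, _, truth = noiseless_phantom
        mal = truth.label_map == 1
        # malignant mu distribution sits near its configured mean, away from benign
        assert abs(truth.parameter_maps["mu"][mal].mean() - cfg.malignant.mu[0]) < 2.0
        assert truth.parameter_maps["mu"][mal].mean() < truth.parameter_maps["mu"][~mal].mean()

    def test_placement_failure_names_constraint(self):
        cfg = PhantomConfig(grid_height=40, grid_width=40, n_lesions=2,
                            lesion_area=0.4, pixel_spacing=0.5, seed=0)
        with pytest.raises((RuntimeError, ValueError), match="lesion|ROI|field"):
            generate_phantom(cfg)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            PhantomConfig(frame_rate=0)
        with pytest.raises(ValueError):
            PhantomConfig(recirculation=Recirculation(45.0, 1.5))

    def test_recirculation_adds_second_pass(self):
        base = PhantomConfig(grid_height=32, grid_width=32, n_lesions=1, lesion_area=0.2,
                             frame_rate=4.0, noise=NoiseModel(0, 0), seed=8)
        loop_rc, truth_rc = generate_phantom(base)
        loop_no, truth_no = generate_phantom(
            dataclasses.replace(base, recirculation=Recirculation(45.0, 0.0))
        )
        late = loop_rc.times > 60
        # compare contrast signal only (echo pedestal removed)
        sig_rc = loop_rc.frames[late] - truth_rc.parameter_maps["echogenicity"]
        sig_no = loop_no.frames[late] - truth_no.parameter_maps["echogenicity"]
        assert sig_rc.sum() > 1.5 * sig_no.sum()


class TestNoiseEffect:
    def test_r2_decreases_with_multiplicative_noise(self):
        """Mean fit R2 falls monotonically over three noise levels."""
        from mpdceus import fit_ldrw_maps

        mask = np.zeros((32, 32), dtype=bool)
        mask[::4, ::4] = True
        means = []
        for sd in (0.05, 0.2, 0.5):
            cfg = PhantomConfig(grid_height=32, grid_width=32, n_lesions=1, lesion_area=0.2,
                                frame_rate=4.0, seed=9, noise=NoiseModel(sd, 0.02))
            loop, _ = generate_phantom(cfg)
            t, tics, _, _ = extract_tic_stack(smooth(loop, 1.0, 0.5))
            maps = fit_ldrw_maps(t, tics.reshape(loop.frames.shape), mask=mask)
            means.append(np.nanmean(maps["r_squared"]))
        assert means[0] > means[1] > means[2]


class TestCohort:
    def test_bounds_and_determinism(self):
        cfg = PhantomConfig(grid_height=32, grid_width=32, n_lesions=1, lesion_area=0.2,
                            frame_rate=4.0, seed=2)
        planes = generate_cohort(cfg, 3, (1, 4), seed=2)
        assert 3 <= len(planes) <= 12
        again = generate_cohort(cfg, 3, (1, 4), seed=2)
        assert len(planes) == len(again)
        assert all(
            np.array_equal(a.loop.frames, b.loop.frames) for a, b in zip(planes, again)
        )

    def test_single_prostate_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(PhantomConfig(), 1)

    def test_prostate_level_shifts_differ(self):
        cfg = PhantomConfig(grid_height=32, grid_width=32, n_lesions=1, lesion_area=0.2,
                            frame_rate=4.0, seed=3)
        planes = generate_cohort(cfg, 3, 1, seed=3)
        mus = [p.truth.parameter_maps["mu"].mean() for p in planes]
        assert np.std(mus) > 0.3
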