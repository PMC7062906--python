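"""Phantom generator: geometry, signal construction, noise, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from marrowfat import (ChannelSignals, PhantomConfig, Tissue, TissueRadii,
                       generate_phantom, ground_truth_summary,
                       sample_cohort_configs)
from marrowfat.errors import GeometryError, ValidationError


def marrow_of(gt):
    return gt.labels == Tissue.MARROW


class TestConstruction:
    def test_noise_free_fat_water_ratio_equals_fat_fraction(self, fast_phantom):
        """fat/(fat+water) equals the nominal FF exactly on marrow voxels."""
        _, fat, water, gt = fast_phantom
        m = marrow_of(gt)
        ratio = fat.data[m] / (fat.data[m] + water.data[m])
        assert np.allclose(ratio, 0.8, atol=0, rtol=1e-12)
        assert np.allclose(gt.ff_map[m], 0.8)

    def test_pixel_counted_marrow_area_matches_analytic_disk(self):
        cfg = PhantomConfig(n_slices=3, grid_size=64, pixel_spacing=0.05,
                            radii=TissueRadii(marrow=0.5, cortical_bone=0.8,
                                              muscle=1.1, subcutaneous_fat=1.4,
                                              skin=1.55),
                            noise_sd=0.0)
        *_, gt = generate_phantom(cfg)
        assert gt.true_marrow_area[0] == pytest.approx(np.pi * 0.5**2, rel=0.02)

    def test_area_discretization_error_shrinks_with_resolution(self):
        """Halving the pixel spacing at least halves the disk-area error."""
        errors = {}
        for ps, n in ((0.08, 60), (0.04, 120)):
            cfg = PhantomConfig(n_slices=3, grid_size=n, pixel_spacing=ps,
                                radii=TissueRadii(marrow=0.53, cortical_bone=0.9,
                                                  muscle=1.3, subcutaneous_fat=1.7,
                                                  skin=1.9),
                                noise_sd=0.0)
            *_, gt = generate_phantom(cfg)
            errors[ps] = abs(gt.true_marrow_area[0] - np.pi * 0.53**2)
        assert errors[0.04] <= errors[0.08] / 2.0

    def test_t1_assigns_same_signal_to_subcut_and_marrow_fat(self, speckled_phantom):
        """Fat is fat: marrow-fat speckles share the subcutaneous-fat T1 level."""
        t1, _, _, gt = speckled_phantom
        subcut_val = t1.data[gt.labels == Tissue.SUBCUT_FAT]
        m = marrow_of(gt)
        marrow_vals = np.unique(t1.data[m])
        assert np.unique(subcut_val).item() in marrow_vals

    def test_speckled_mode_records_realized_fraction(self, speckled_phantom):
        t1, fat, water, gt = speckled_phantom
        m = marrow_of(gt)
        assert gt.speckle_fraction is not None
        # realized fraction fluctuates around the nominal rate
        assert gt.speckle_fraction.mean() == pytest.approx(0.8, abs=0.05)
        # T1 marrow voxels are two-valued (pure fat / pure red marrow)
        assert np.unique(t1.data[m]).size == 2
        # fat/water channels stay homogeneous mixtures
        assert np.allclose(fat.data[m] / (fat.data[m] + water.data[m]), 0.8)


class TestDeterminismAndNoise:
    def test_same_seed_reproduces_bit_identical_stacks(self, noisy_config):
        a = generate_phantom(noisy_config)
        b = generate_phantom(noisy_config)
        for sa, sb in zip(a[:3], b[:3]):
            np.testing.assert_array_equal(sa.data, sb.data)

    def test_different_seeds_differ_under_noise(self, noisy_config):
        a = generate_phantom(noisy_config)
        b = generate_phantom(replace(noisy_config, seed=noisy_config.seed + 1))
        assert not np.array_equal(a[0].data, b[0].data)

    @pytest.mark.parametrize("model", ["rician", "gaussian"])
    def test_noise_keeps_images_non_negative(self, fast_config, model):
        cfg = replace(fast_config, noise_sd=15.0, noise_model=model)
        t1, fat, water, _ = generate_phantom(cfg)
        for st in (t1, fat, water):
            assert (st.data >= 0).all()

    def test_rician_noise_biases_low_signal_upward(self, fast_config):
        """Magnitude noise on near-zero background follows a Rayleigh floor."""
        cfg = replace(fast_config, noise_sd=20.0)
        t1, _, _, gt = generate_phantom(cfg)
        bg = t1.data[gt.labels == Tissue.BACKGROUND]
        # Rayleigh mean for A≈0 is sd*sqrt(pi/2) ≈ 25; Gaussian would stay ≈ 10
        assert bg.mean() > 18.0


class TestGroundTruthSummary:
    def test_zero_fat_fraction_gives_zero_truth(self):
        cfg = PhantomConfig(n_slices=3, grid_size=64, pixel_spacing=0.08,
                            radii=TissueRadii(marrow=0.5, cortical_bone=0.8, muscle=1.4,
                                              subcutaneous_fat=1.9, skin=2.1),
                            marrow_fat_fraction=0.0, noise_sd=0.0)
        t1, _, _, gt = generate_phantom(cfg)
        bmff, bmfv = ground_truth_summary(gt, t1)
        assert bmff == 0.0 and bmfv == 0.0

    def test_bmff_scales_with_fraction(self):
        cfg = PhantomConfig(n_slices=3, grid_size=64, pixel_spacing=0.08,
                            radii=TissueRadii(marrow=0.5, cortical_bone=0.8, muscle=1.4,
                                              subcutaneous_fat=1.9, skin=2.1),
                            marrow_fat_fraction=0.803, noise_sd=0.0)
        t1, _, _, gt = generate_phantom(cfg)
        bmff, _ = ground_truth_summary(gt, t1)
        assert bmff == pytest.approx(80.3, abs=1e-9)

    def test_bmfv_closed_form(self, fast_phantom, fast_config):
        """BMFV = sum of (area × FF) × (thickness + gap) over slices."""
        t1, _, _, gt = fast_phantom
        bmff, bmfv = ground_truth_summary(gt, t1)
        per_slice_area = gt.true_marrow_area[0]
        expected = (fast_config.n_slices * per_slice_area * 0.8
                    * (fast_config.slice_thickness + fast_config.slice_gap))
        assert bmfv == pytest.approx(expected, rel=1e-12)
        assert bmfv == pytest.approx(gt.true_bmfv, rel=1e-12)

    def test_mismatched_grid_raises(self, fast_phantom):
        t1, _, _, gt = fast_phantom
        other = PhantomConfig(n_slices=4, grid_size=96, pixel_spacing=0.08,
                              noise_sd=0.0)
        wrong_stack, *_ = generate_phantom(other)
        with pytest.raises(ValidationError):
            ground_truth_summary(gt, wrong_stack)


class TestValidation:
    def test_non_increasing_radii_rejected(self):
        with pytest.raises(GeometryError):
            TissueRadii(marrow=1.0, cortical_bone=0.9, muscle=2.0,
                        subcutaneous_fat=3.0, skin=3.5)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValidationError):
            ChannelSignals(-1.0, 0.0, 0.0)

    @pytest.mark.parametrize("kwargs", [
        dict(marrow_fat_fraction=1.2),
        dict(n_slices=2),
        dict(noise_sd=-1.0),
        dict(noise_model="poisson"),
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PhantomConfig(**kwargs)


class TestCohortSampling:
    def test_cohort_is_reproducible_and_varied(self):
        a = sample_cohort_configs(6, seed=3)
        b = sample_cohort_configs(6, seed=3)
        assert [c.seed for c in a] == [c.seed for c in b]
        radii = {c.radii.marrow for c in a}
        ffs = {c.marrow_fat_fraction for c in a}
        assert len(radii) == 6 and len(ffs) == 6
        assert all(24 <= c.n_slices <= 34 for c in a)
        assert all(c.speckled for c in a)
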