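import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import lsdenoise as L

from _oracles import conv2d_reflect_oracle


class TestGeneratePhantom:
    def test_empty_scene_is_uniform_background(self):
        img, labels = L.generate_phantom(32, 32, n_bodies=0, seed=1)
        assert labels.max() == 0
        assert img.pixels.max() < 0.2  # low background only

    def test_body_count_matches_connected_components(self):
        _, labels = L.generate_phantom(128, 128, n_bodies=5, seed=7)
        _, n = ndimage.label(labels > 0)
        assert n == 5
        assert set(np.unique(labels)) == {0, 1, 2, 3, 4, 5}

    def test_bitwise_determinism(self):
        a, la = L.generate_phantom(64, 64, n_bodies=4, seed=3)
        b, lb = L.generate_phantom(64, 64, n_bodies=4, seed=3)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(la, lb)

    @pytest.mark.parametrize(
        "kwargs,message",
        [
            (dict(height=0, width=32), "height"),
            (dict(height=32, width=-4), "width"),
            (dict(height=32, width=32, n_bodies=-1), "n_bodies"),
            (dict(height=32, width=32, body_radius_px=(0, 5)), "radii"),
            (dict(height=32, width=32, body_radius_px=(4, 40)), "body_radius_px"),
        ],
    )
    def test_invalid_arguments_name_the_offending_field(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            L.generate_phantom(**kwargs)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bodies_brighter_than_background(self, seed):
        img, labels = L.generate_phantom(64, 64, n_bodies=3, seed=seed)
        assert img.pixels[labels > 0].mean() > img.pixels[labels == 0].mean()


class TestGaussianPsf:
    def test_size_one_is_delta(self):
        psf = L.gaussian_psf(2.0, 1)
        assert psf.weights.shape == (1, 1)
        assert psf.weights[0, 0] == 1.0

    def test_neighbor_to_center_ratio(self):
        # For sigma=2 the ratio of the 4-neighbor weight to the center
        # weight is exp(-1/(2*sigma^2)) = exp(-1/8).
        psf = L.gaussian_psf(2.0, 11)
        c = psf.weights[5, 5]
        assert psf.weights[5, 6] / c == pytest.approx(np.exp(-1 / 8), abs=1e-12)

    def test_rotation_symmetry_and_normalization(self):
        psf = L.gaussian_psf(1.3, 7)
        assert np.allclose(psf.weights, psf.weights[::-1, ::-1])
        assert psf.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            L.gaussian_psf(1.0, 4)


class TestApplyPsf:
    def test_delta_image_recovers_kernel(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        psf = L.gaussian_psf(1.0, 5)
        out = L.apply_psf(L.ImageGrid(img), psf)
        assert np.allclose(out.pixels[6:11, 6:11], psf.weights, atol=1e-12)

    def test_constant_image_preserved(self):
        img = L.ImageGrid(np.full((16, 16), 0.4))
        out = L.apply_psf(img, L.gaussian_psf(1.5, 7))
        assert np.allclose(out.pixels, 0.4, atol=1e-12)

    def test_matches_brute_force_convolution(self, rng):
        img = rng.random((16, 16))
        psf = L.gaussian_psf(1.2, 5)
        out = L.apply_psf(L.ImageGrid(img), psf)
        expected = conv2d_reflect_oracle(img, psf.weights)
        assert np.allclose(out.pixels, np.clip(expected, 0, 1), atol=1e-10)

    def test_kernel_larger_than_image_rejected(self):
        img = L.ImageGrid(np.full((8, 8), 0.5))
        with pytest.raises(ValueError, match="larger"):
            L.apply_psf(img, L.gaussian_psf(2.0, 11))


class TestAddNoise:
    def test_zero_sigma_is_identity(self):
        img = L.ImageGrid(np.full((16, 16), 0.5))
        out = L.add_noise(img, L.NoiseModel("gaussian", gaussian_sigma=0.0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_gaussian_sigma_recovered_empirically(self):
        img = L.ImageGrid(np.full((256, 256), 0.5))
        out = L.add_noise(img, L.NoiseModel("gaussian", gaussian_sigma=0.05, seed=4))
        assert np.std(out.pixels - img.pixels) == pytest.approx(0.05, abs=0.002)

    def test_poisson_variance_scales_with_photons(self):
        photons = 400.0
        img = L.ImageGrid(np.full((256, 256), 0.5))
        out = L.add_noise(
            img, L.NoiseModel("poisson", poisson_photons=photons, seed=4)
        )
        var = np.var(out.pixels - img.pixels)
        assert var == pytest.approx(0.5 / photons, rel=0.1)

    def test_seed_determinism(self):
        img, _ = L.generate_phantom(32, 32, body_radius_px=(4, 8), seed=0)
        model = L.NoiseModel("mixed", gaussian_sigma=0.1, poisson_photons=100, seed=9)
        a = L.add_noise(img, model)
        b = L.add_noise(img, model)
        assert np.array_equal(a.pixels, b.pixels)


class TestMakeNoisyPair:
    def test_zero_sigma_pair_equals_clean(self, phantom64):
        clean, _ = phantom64
        pair = L.make_noisy_pair(
            clean, L.NoiseModel("gaussian", gaussian_sigma=0.0), 1, 2
        )
        assert np.array_equal(pair.y1.pixels, clean.pixels)
        assert np.array_equal(pair.y2.pixels, clean.pixels)

    def test_independent_noise_has_zero_mean_difference(self):
        clean, _ = L.generate_phantom(256, 256, n_bodies=5, seed=2)
        pair = L.make_noisy_pair(
            clean, L.NoiseModel("gaussian", gaussian_sigma=0.1), 11, 22
        )
        assert abs(np.mean(pair.y1.pixels - pair.y2.pixels)) < 0.005

    def test_equal_seeds_flagged_and_identical(self, phantom64):
        clean, _ = phantom64
        with pytest.warns(UserWarning, match="seed1 == seed2"):
            pair = L.make_noisy_pair(
                clean, L.NoiseModel("gaussian", gaussian_sigma=0.1), 5, 5
            )
        assert np.array_equal(pair.y1.pixels, pair.y2.pixels)


class TestModalityPresets:
    @pytest.mark.parametrize(
        "name,laser,power,exposure,aotf",
        [
            ("rayleigh_785", 785, 1, 100, 775),
            ("rayleigh_660", 660, 1, 100, 650),
            ("fluorescence_660", 660, 130, 5000, 694),
            ("raman_660", 660, 130, 5000, 817),
        ],
    )
    def test_acquisition_rows(self, name, laser, power, exposure, aotf):
        p = L.modality_preset(name)
        assert (p.laser_nm, p.power_mw, p.exposure_ms, p.aotf_nm) == (
            laser,
            power,
            exposure,
            aotf,
        )

    def test_weak_signal_modalities_have_stronger_noise(self):
        rayleigh = L.modality_preset("rayleigh_785").noise.gaussian_sigma
        for weak in ("fluorescence_660", "raman_660"):
            assert L.modality_preset(weak).noise.gaussian_sigma > rayleigh

    def test_unknown_name_lists_valid_presets(self):
        with pytest.raises(ValueError, match="rayleigh_785"):
            L.modality_preset("raman_785")


class TestImageGridInvariants:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="min|max"):
            L.ImageGrid(np.full((8, 8), 1.5))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="8x8"):
            L.ImageGrid(np.zeros((4, 4)))

    def test_nonfinite_rejected(self):
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            L.ImageGrid(bad)
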