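import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import lsdenoise as L
from lsdenoise.denoise import DIPInput, EarlyStopper, TrainingTrace, masked_mse
from lsdenoise.nn import NetworkSpec, UNet

TINY = dict(epochs=12, steps_per_epoch=2, network=NetworkSpec(depth=2, base_channels=4))


def tiny_config(method, **over):
    return L.DenoiserConfig(method=method, **{**TINY, **over})


@pytest.fixture()
def noisy32():
    clean, _ = L.generate_phantom(32, 32, n_bodies=2, body_radius_px=(3, 6), seed=1)
    noisy = L.add_noise(clean, L.NoiseModel("gaussian", gaussian_sigma=0.1, seed=42))
    return clean, noisy


class TestEarlyStopper:
    def test_fires_after_exact_plateau_length(self):
        # improves through epoch 3, then a scripted plateau: stopping must
        # occur exactly when 10 consecutive epochs brought no improvement.
        stopper = EarlyStopper(patience=10)
        losses = [1.0, 0.9, 0.8] + [0.8] * 20
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 13  # best at epoch 3 + patience 10

    def test_does_not_fire_while_improving(self):
        stopper = EarlyStopper(patience=10)
        for epoch in range(1, 100):
            assert not stopper.update(epoch, 1.0 / epoch)

    def test_late_improvement_resets_the_clock(self):
        # best at epoch 1, plateau until the improvement at epoch 4 resets
        # the patience window; the 3-epoch plateau after it fires at epoch 7.
        stopper = EarlyStopper(patience=3)
        seq = [1.0, 1.0, 1.0, 0.5, 0.6, 0.6, 0.6]
        results = [stopper.update(e, v) for e, v in enumerate(seq, start=1)]
        assert results == [False, False, False, False, False, False, True]


class TestTrainingTrace:
    def test_inconsistent_epoch_count_rejected(self):
        with pytest.raises(ValueError, match="stopped_epoch"):
            TrainingTrace([0.5, 0.4], stopped_epoch=3, stop_reason="max_epochs")

    def test_bad_stop_reason_rejected(self):
        with pytest.raises(ValueError, match="stop_reason"):
            TrainingTrace([0.5], stopped_epoch=1, stop_reason="crashed")


class TestBlindSpotMask:
    def test_mask_count_from_fraction(self):
        img, _ = L.generate_phantom(128, 128, seed=0)
        masked = L.blind_spot_mask(img, fraction=0.02, seed=1)
        assert masked.mask.sum() == 328  # round(0.02 * 16384)

    def test_single_pixel_floor_case(self):
        img, _ = L.generate_phantom(16, 16, n_bodies=1, body_radius_px=(3, 5), seed=0)
        masked = L.blind_spot_mask(img, fraction=1 / 256, seed=1)
        assert masked.mask.sum() == 1

    def test_unmasked_pixels_untouched(self):
        img, _ = L.generate_phantom(32, 32, body_radius_px=(4, 8), seed=3)
        masked = L.blind_spot_mask(img, fraction=0.05, seed=2)
        assert np.array_equal(
            masked.pixels.pixels[~masked.mask], img.pixels[~masked.mask]
        )

    def test_replacement_comes_from_window_neighbor(self):
        img, _ = L.generate_phantom(32, 32, body_radius_px=(4, 8), seed=4)
        r = 2
        masked = L.blind_spot_mask(img, fraction=0.05, neighbor_radius=r, seed=5)
        for i, j in zip(*np.nonzero(masked.mask)):
            window = img.pixels[
                max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1
            ]
            assert masked.pixels.pixels[i, j] in window

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        img, _ = L.generate_phantom(16, 16, n_bodies=0, seed=0)
        with pytest.raises(ValueError, match="fraction"):
            L.blind_spot_mask(img, fraction=fraction)

    def test_degenerate_window_rejected(self):
        img, _ = L.generate_phantom(16, 16, n_bodies=0, seed=0)
        with pytest.raises(ValueError, match="neighbor_radius"):
            L.blind_spot_mask(img, fraction=0.1, neighbor_radius=0)


class TestMaskedLoss:
    def test_hand_computed_4x4_fixture(self):
        pred = np.array(
            [
                [0.1, 0.2, 0.3, 0.4],
                [0.5, 0.6, 0.7, 0.8],
                [0.9, 0.1, 0.2, 0.3],
                [0.4, 0.5, 0.6, 0.7],
            ]
        )
        target = np.full((4, 4), 0.5)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 2] = mask[3, 3] = True
        # hand-computed: ((0.1-0.5)^2 + (0.7-0.5)^2 + (0.7-0.5)^2) / 3
        expected = (0.16 + 0.04 + 0.04) / 3
        loss, _ = masked_mse(pred, target, mask)
        assert loss == pytest.approx(expected, abs=1e-7)

    def test_loss_invariant_to_unmasked_predictions(self):
        rng = np.random.default_rng(0)
        pred, target = rng.random((4, 4)), rng.random((4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 3] = True
        base, _ = masked_mse(pred, target, mask)
        perturbed = pred.copy()
        perturbed[~mask] += rng.random((4, 4))[~mask]
        after, _ = masked_mse(perturbed, target, mask)
        assert after == base


class TestZsDeconvnet:
    def test_loss_matches_independent_oracle(self, noisy32):
        """The training objective |y - f(h*y')|^2/N recomputed externally."""
        _, noisy = noisy32
        psf = L.gaussian_psf(1.0, 7)
        net = UNet(NetworkSpec(depth=2, base_channels=4), seed=7)
        rng = np.random.default_rng(3)
        y_corrupt = np.clip(
            noisy.pixels + rng.normal(0, 0.05, noisy.pixels.shape), 0, 1
        )
        x_in = ndimage.convolve(y_corrupt, psf.weights, mode="reflect")
        pred = net.forward(x_in)
        loss, _ = masked_mse(pred, noisy.pixels)
        oracle = float(np.sum((noisy.pixels - pred) ** 2)) / noisy.pixels.size
        assert loss == pytest.approx(oracle, abs=1e-12)

    def test_uses_published_schedule_by_default(self):
        cfg = L.DenoiserConfig.default("zs_deconvnet")
        assert (cfg.epochs, cfg.learning_rate, cfg.optimizer_name) == (
            100,
            0.001,
            "adam",
        )

    def test_training_reduces_loss(self, noisy32):
        _, noisy = noisy32
        out, trace, _ = L.train_zs_deconvnet(
            noisy, L.gaussian_psf(1.0, 7), tiny_config("zs_deconvnet"), seed=0
        )
        assert trace.losses[-1] < trace.losses[0]
        assert out.pixels.shape == noisy.pixels.shape


class TestNoise2Noise:
    def test_degenerate_pair_warns(self, noisy32):
        _, noisy = noisy32
        pair = L.NoisyPair(y1=noisy, y2=noisy, clean=noisy)
        with pytest.warns(UserWarning, match="degenerate"):
            L.train_noise2noise(pair, tiny_config("noise2noise"), seed=0)

    def test_noiseless_pair_learns_identity(self):
        # y1 = y2 = clean: the objective is a pure image fit, so a
        # converged run reconstructs the clean image closely.
        clean, _ = L.generate_phantom(
            32, 32, n_bodies=2, body_radius_px=(5, 8), seed=9
        )
        pair = L.make_noisy_pair(
            clean, L.NoiseModel("gaussian", gaussian_sigma=0.0), 1, 2
        )
        with pytest.warns(UserWarning, match="degenerate"):
            out, trace, _ = L.train_noise2noise(
                pair, tiny_config("noise2noise", epochs=250, steps_per_epoch=3),
                seed=0,
            )
        assert L.rmse(out, clean) < 0.02


class TestNoise2Void:
    def test_default_schedule(self):
        cfg = L.DenoiserConfig.default("noise2void")
        assert (cfg.epochs, cfg.learning_rate, cfg.batch_size) == (1000, 0.001, 1)

    def test_smooths_constant_scene(self):
        # A constant scene plus sigma=0.1 noise: blind-spot training should
        # at least halve the pixel scatter. mask_fraction=0.1 keeps the
        # per-epoch masked-loss estimate stable enough for the plateau rule.
        flat = L.ImageGrid(np.full((64, 64), 0.5))
        noisy = L.add_noise(flat, L.NoiseModel("gaussian", gaussian_sigma=0.1, seed=3))
        cfg = L.DenoiserConfig(
            "noise2void", epochs=100, steps_per_epoch=3, mask_fraction=0.1,
            network=NetworkSpec(depth=2, base_channels=8),
        )
        wins = 0
        for seed in range(5):
            out, _, _ = L.train_noise2void(noisy, cfg, seed=seed)
            wins += np.std(out.pixels) < 0.05
        assert wins >= 4


class TestDip:
    def test_input_is_sampled_once(self, noisy32):
        _, noisy = noisy32
        _, _, model = L.train_dip(noisy, tiny_config("dip"), seed=0)
        assert model.dip_input.checksum == DIPInput(
            model.dip_input.z, "uniform01", 0
        ).checksum

    def test_checksum_detects_resampled_input(self, rng):
        dip_in = DIPInput(z=rng.random((16, 16)), distribution="uniform01", seed=0)
        before = dip_in.checksum
        dip_in.z[0, 0] += 0.1
        assert dip_in.checksum != before

    def test_output_strictly_inside_unit_interval(self, noisy32):
        _, noisy = noisy32
        out, _, _ = L.train_dip(noisy, tiny_config("dip"), seed=1)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestSelf2Self:
    def test_invalid_prediction_samples_rejected(self):
        with pytest.raises(ValueError, match="n_prediction_samples"):
            L.DenoiserConfig(method="self2self", n_prediction_samples=0)

    def test_averaging_reduces_prediction_variance(self, noisy32):
        """Mean of 20 dropout passes varies less across seeds than 1 pass."""
        _, noisy = noisy32
        _, _, model = L.train_self2self(
            noisy, tiny_config("self2self", epochs=20), seed=0
        )

        def spread(n_samples):
            preds = []
            for s in range(8):
                variant = dataclasses.replace(
                    model,
                    seed=s,
                    config=dataclasses.replace(
                        model.config, n_prediction_samples=n_samples
                    ),
                )
                preds.append(L.denoise(variant, noisy).pixels)
            return np.var(np.stack(preds), axis=0).mean()

        assert spread(20) < spread(1)


class TestDenoiseContract:
    def test_identity_model_returns_input(self, noisy32):
        _, noisy = noisy32
        out = L.denoise(L.IdentityModel(), noisy)
        assert np.array_equal(out.pixels, noisy.pixels)

    def test_output_in_unit_range_and_deterministic(self, noisy32):
        _, noisy = noisy32
        _, _, model = L.train_noise2void(
            noisy, tiny_config("noise2void"), seed=2
        )
        a = L.denoise(model, noisy)
        b = L.denoise(model, noisy)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0


class TestConfigDefaults:
    @pytest.mark.parametrize(
        "method,epochs",
        [
            ("zs_deconvnet", 100),
            ("noise2noise", 100),
            ("noise2void", 1000),
            ("dip", 1000),
            ("self2self", 1000),
        ],
    )
    def test_published_schedule(self, method, epochs):
        cfg = L.DenoiserConfig.default(method)
        assert cfg.epochs == epochs
        assert cfg.learning_rate == 0.001
        assert cfg.optimizer_name == "adam"
        assert cfg.loss_name == "mse"
        assert cfg.batch_size == 1
        assert cfg.early_stop_patience == 10
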