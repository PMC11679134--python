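import numpy as np
import pytest

import lsdenoise as L

# Standard phantom study: 64x64 scenes, Gaussian sigma=0.1, five seeds.
SEEDS = (0, 1, 2, 3, 4)
NOISE_SIGMA = 0.1


def _run_suite():
    """Train every method on the five seeded phantoms; cache all numbers."""
    records = {m: [] for m in L.METHODS}
    for seed in SEEDS:
        clean, _ = L.generate_phantom(64, 64, n_bodies=3, seed=seed)
        pair = L.make_noisy_pair(
            clean,
            L.NoiseModel("gaussian", gaussian_sigma=NOISE_SIGMA),
            1000 + seed,
            2000 + seed,
        )
        noisy = pair.y1
        base_rmse = L.rmse(noisy, clean)
        base_ssim = L.ssim(noisy, clean)
        for m in L.METHODS:
            out, trace, _model = L.train(m, pair, L.DenoiserConfig.fast(m), seed=seed)
            records[m].append(
                {
                    "seed": seed,
                    "trace": trace,
                    "rmse": L.rmse(out, clean),
                    "ssim": L.ssim(out, clean),
                    "noisy_rmse": base_rmse,
                    "noisy_ssim": base_ssim,
                }
            )
    return records


@pytest.fixture(scope="session")
def efficacy_runs():
    """Session-cached training results for the standard phantom suite."""
    return _run_suite()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def phantom64():
    clean, labels = L.generate_phantom(64, 64, n_bodies=3, seed=0)
    return clean, labels
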