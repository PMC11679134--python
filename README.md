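# lsdenoise

Zero-shot and self-supervised denoising for multi-modal light-sheet
microscopy — a tested, reusable re-implementation of a five-way
comparative benchmark of single-image denoising schemes, with the
four-metric evaluation protocol and a synthetic spheroid-phantom
generator that replaces non-deposited microscopy data.

## The problem

Light-sheet microscopy of 3-D cell cultures (spheroids) in Rayleigh,
fluorescence, and Raman modes produces images degraded by the usual
observation model

```
Y = h ∗ X + n
```

where `X` is the latent clean image, `h` the microscope's point-spread
function, and `n` detector noise. Raman and fluorescence signals are
weak, so noise dominates — but clean training data for supervised
denoisers do not exist. Five schemes that train on the noisy data alone
are compared:

| method | needs | training signal |
|---|---|---|
| **ZS-DeconvNet** | PSF `h` | corrupt `y`, re-blur, predict `y`: `‖y − f(h∗y′)‖²` |
| **Noise2Noise** | a second acquisition | predict `y₂` from `y₁` |
| **Noise2Void** | nothing | blind-spot masking; loss at masked pixels only |
| **DIP** | nothing | fit `y` from a fixed random input `z`, stop early |
| **Self2Self** | nothing | input dropout; loss at dropped pixels; averaged prediction |

All five share one encoder–decoder backbone with skip connections
(Adam, learning rate 0.001, MSE, batch size 1; 100 epochs for
ZS-DeconvNet/Noise2Noise, 1000 for the rest; early stopping after 10
epochs without loss improvement), implemented here as a compact,
seeded, CPU-friendly numpy network with analytic gradients.

Outputs are scored with **PSNR** (dB, `10·log₁₀(MAX²/MSE)`), **SSIM**,
**RMSE**, and **Fourier ring correlation** (per-frequency-ring
normalized cross-spectrum; its mean up to Nyquist is the scalar
summary). On synthetic scenes the retained ground truth is the default
reference; the noisy-input protocol is also available.

## A worked example

```python
import lsdenoise as L

clean, _ = L.generate_phantom(64, 64, n_bodies=3, seed=0)
noisy = L.add_noise(clean, L.NoiseModel("gaussian", gaussian_sigma=0.1, seed=1))
out, trace, model = L.train("noise2void", noisy, L.DenoiserConfig.fast("noise2void"), seed=0)
print(L.rmse(noisy, clean), "->", L.rmse(out, clean))
```

Running `python examples/02_denoise_single_image.py` prints:

```
noisy input: RMSE 0.0837, SSIM 0.9458
noise2void: 44 epochs (early_stop), loss 0.0757 -> 0.0103, RMSE 0.0518, SSIM 0.9781
       dip: 200 epochs (max_epochs), loss 0.0966 -> 0.0011, RMSE 0.0716, SSIM 0.9585
 self2self: 68 epochs (early_stop), loss 0.0952 -> 0.0095, RMSE 0.0499, SSIM 0.9785
```

Each method reduces the pixel error (RMSE 0.084 → 0.05–0.07) and raises
the structural similarity relative to the noisy input, without ever
seeing clean data. The other scripts in `examples/` cover phantom
simulation, paired training and PSF-aware deconvolution, and the full
five-method benchmark (`L.run_benchmark`), which emits a per-method
report table, loss traces, and denoised TIFFs.

A thin CLI wraps the same calls:

```bash
lsdenoise simulate --preset raman_660 --size 128 --bodies 3 --noise gaussian:0.1 --seed 7 --out sim/
lsdenoise denoise --method noise2void --in sim/noisy.tif --out out.tif --fast
lsdenoise benchmark --seed 1 --out run/
lsdenoise report --in run/report.json
```

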