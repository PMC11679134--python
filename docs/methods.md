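# Methods

## Observation model and scope

All images are 2-D grayscale intensity fields normalized to [0, 1]
(`ImageGrid`); 3-D acquisitions are ordered lists of 2-D slices with a
10 µm axial step recorded as metadata, and every training and
evaluation operation is slice-wise. The forward model is
`Y = h ∗ X + n`: a latent clean image `X`, a point-spread function `h`,
and noise `n` that is Gaussian (read noise), Poisson (shot noise at a
configurable photon budget), or both.

The original microscopy data behind this benchmark are not publicly
deposited, so the package ships a synthetic generator whose scenes are
*statistically* spheroid-like rather than replicas: bright ellipsoidal
bodies (mild eccentricity, smooth radial falloff, granular internal
texture from a smoothed Gaussian random field) on a low, gently varying
background, over a field-of-view analogue of 635 µm. Bodies are placed
with a 3 px clearance so the label mask always has exactly `n_bodies`
connected components. What the generator does **not** emulate: the
spectral axis (no hyperspectral Raman cubes), sCMOS-specific noise
statistics (fixed-pattern noise, read-noise maps), optical artifacts
(stripes, shadowing), or sample motion. Passing tests on these phantoms
therefore demonstrate correctness of the algorithms and honest relative
behavior under the stated noise models — not performance claims about
any particular instrument's data.

## PSF

The acquisition hardware's blur is approximated as an isotropic
Gaussian, parameterized in pixels and normalized to sum 1. The default
width is derived from the instrument class's ~8 µm light-sheet beam
waist treated as the FWHM of the blur profile:
`sigma_px = (waist/2.355)/pixel_pitch` (`psf_sigma_from_beam_waist`),
about 0.7 px at a 635 µm field sampled at 128 px. Deconvolution
experiments default to σ = 1.0 px: of the same order as the
beam-waist-derived value, while still leaving measurable signal above
half-Nyquist so frequency-domain recovery is observable. Both are
configurable everywhere a PSF is taken.

## The shared backbone

No deep-learning framework is used: `lsdenoise.nn` is a compact
convolutional network core written on numpy with analytic gradients —
same-padding 3×3 convolutions (im2col), per-channel batch
normalization, ReLU, 2× max-pooling, 2× nearest-neighbor upsampling,
concatenation skip connections, and a sigmoid head that keeps outputs
strictly inside (0, 1). Weights use seeded He initialization, so every
run is bit-reproducible. Backpropagation is verified in the test suite
against central finite differences (directional derivative over all
parameters, relative error ~1e-10).

Default architecture: 3 encoder stages, 16 base channels doubling per
stage. The desk-scale (`fast`) profile uses depth 2 / 8 channels.

## Training regimes

All five trainers share one loop: Adam (lr 0.001, β₁ 0.9, β₂ 0.999),
MSE-type losses, batch size 1 (the full image is the single sample),
and early stopping when the epoch-level loss has not improved for 10
consecutive epochs. Epoch budgets: 100 for ZS-DeconvNet and
Noise2Noise, 1000 for Noise2Void, DIP and Self2Self.

Method-specific choices made where the procedure was underdetermined:

- **ZS-DeconvNet** — each step draws a fresh corruption
  `y′ = y + N(0, σ_c)` (σ_c = 0.05 default), feeds the re-blurred
  `h ∗ y′`, and scores the prediction against the observed `y`; the
  final estimate is `f(h ∗ y)`. A `paired_corruption` flag also
  corrupts the target (the Noise2Noise-style reading); off by default.
- **Noise2Void** — mask fraction 0.02, replacement by a uniformly
  chosen different pixel within a 5×5 window (neighbor swap; zero-fill
  would leak the mask's location). A fresh masking is drawn every step,
  and the loss touches masked positions only, so the gradient from
  unmasked pixels is exactly zero.
- **Self2Self** — input dropout rate 0.3; loss on dropped pixels only;
  the prediction averages 50 independent dropout passes (10 in the fast
  profile).
- **DIP** — `z` is uniform on [0, 1], sampled once (a checksum on the
  model detects re-sampling); the returned image is the network output
  at the best-loss epoch, which is where the patience rule leaves the
  run.
- **Noise2Noise** — trains strictly y₁ → y₂ (no symmetrization).

One "epoch" of single-image training is `steps_per_epoch` gradient
steps (default 1, matching the one-image-one-batch reading; the fast
profile uses 3 so that stochastic losses — fresh masks, fresh
corruptions — are averaged into a stabler per-epoch value for the
plateau rule).

### Desk-scale profile

`DenoiserConfig.fast(method)`: 64×64 scenes, 50 epochs for the
100-epoch methods and 200 for the 1000-epoch methods, 3 steps per
epoch, depth-2/8-channel backbone. These are the problem sizes the test
suite and the acceptance script use; the full schedule remains the
library default.

## Metrics

- **PSNR** uses MAX = 1.0, the representable ceiling of normalized
  images, not the per-image maximum. Zero MSE yields an explicit
  infinity sentinel, serialized as the string `"inf"`.
- **SSIM** defaults to *global* mode — the similarity formula evaluated
  once on whole-image means, population variances, and covariance, with
  C1 = (0.01·L)², C2 = (0.03·L)², L = 1. A *sliding* mode (uniform
  windows, default side 8, unbiased variance/covariance, mean over all
  interior windows) is provided for cross-tool comparison and is
  verified against scikit-image in the tests.
- **FRC** mean-subtracts both images (a `keep_dc` knob disables this),
  takes 2-D FFTs, assigns frequency pixels to rings by rounded integer
  radius, excludes the DC ring, and computes
  `Re(Σ F₁·conj(F₂)) / sqrt(Σ|F₁|² · Σ|F₂|²)` per ring up to Nyquist.
  Taking the real part (standard practice) means ring values — and the
  scalar summary, defined as the **mean of ring correlations** — can be
  negative for anticorrelated frequency content. A threshold-crossing
  convention could never produce a negative summary, which is why the
  mean was chosen; the 1/7-threshold crossing frequency is still
  reported as a secondary column. Non-square inputs are center-cropped.
- The evaluation protocol of scoring against the **noisy input** is
  reproduced (`reference_mode="noisy_input"`), with the documented
  caveat that the identity transform scores perfectly under it. For
  synthetic runs with retained truth the default is `clean_truth`.

## Pipeline

Preprocessing: optional background subtraction (morphological rolling
ball, radius 25 px, or a low-percentile constant — rolling ball is the
default algorithm when enabled) clipped at zero, optional Gaussian
(σ = 1) or odd-window median filtering, then rescaling to [0, 1]. With
every switch off the stage is the identity.

Postprocessing: segmentation by Otsu's threshold floored at the image
mean (for bright-minority-foreground scenes Otsu alone can land inside
the background's upper tail) with small-object removal (min area 10),
and contrast enhancement by a 1–99 percentile stretch. A constant image
segments to an empty mask with a warning, never an error.

The benchmark orchestrator trains every requested method on the same
preprocessed observation (Noise2Noise receives the pair; the others the
first observation), isolates per-method failures as recorded error rows,
assembles rows in the fixed comparative order (ZS-DeconvNet,
Noise2Noise, Noise2Void, DIP, Self2Self), and is byte-reproducible from
(config, master seed): reports carry no timestamps (the run manifest
does). One master seed spawns independent, purpose-keyed substreams
(phantom, noise, masking, weights, dropout, ...), so changing how one
stage consumes randomness does not perturb the others.

## Numerical choices and degenerate inputs

- Intensities are clipped to [0, 1] after blurring and after noise
  (detector saturation; also matches the sigmoid output contract).
- `add_noise` with σ = 0 returns the input bit-identically.
- A noisy pair built with equal seeds is allowed but warned about
  (identical observations degenerate paired training to an identity
  fit); a bit-identical Noise2Noise pair warns likewise.
- The sigmoid pre-activation is clipped at ±30, keeping outputs
  strictly inside (0, 1) after float64 rounding.
- Images whose sides are not divisible by 2^depth are reflect-padded
  for inference and cropped back; plain `forward` rejects them.
- FRC rings with zero energy in either image get correlation 0 rather
  than NaN; ring correlations are clamped to [−1, 1] (tolerance 1e-9).
- 16-bit TIFF round trips are exact to 1/(2·65535); 8-bit writes warn
  when the data need finer quantization; float32 round trips are
  bitwise.

## Limitations

- CPU-only and deliberately small: the numpy backbone is meant for
  desk-scale images (≤256²), not production volumes.
- 2-D only; stacks are processed slice-wise with no axial coupling.
- The phantom generator supports relative comparisons between methods,
  not absolute performance claims about real microscope data.
- Self2Self uses input-dropout masking only (no network-internal
  dropout ensembling beyond the averaged stochastic passes).
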