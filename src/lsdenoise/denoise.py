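"""The five zero-shot / self-supervised denoising schemes.

All five methods share one encoder-decoder backbone and one training
loop (Adam, MSE-type losses, batch size 1, early stopping with patience
10); they differ only in how each optimization step builds the network
input and which pixels the loss is evaluated on:

==============  =====================================================
zs_deconvnet    input = h * (y + gaussian corruption); loss vs y on
                all pixels; final output f(h * y) (deconvolution).
noise2noise     input = y1, loss vs the second observation y2.
noise2void      blind-spot masking: a random pixel subset is replaced
                by random neighbors; loss only at masked pixels vs
                their original values.
dip             input = a fixed random field z; loss vs y; the output
                at the best-loss epoch is returned.
self2self       Bernoulli dropout zeroes input pixels; loss only at
                the dropped pixels; prediction averages several
                stochastic forward passes.
==============  =====================================================
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from ._rng import substream
from .nn import Adam, NetworkSpec, UNet
from .phantom import ImageGrid, NoisyPair, PSFKernel

__all__ = [
    "METHODS",
    "DenoiserConfig",
    "MaskedImage",
    "DIPInput",
    "TrainingTrace",
    "EarlyStopper",
    "TrainedDenoiser",
    "IdentityModel",
    "blind_spot_mask",
    "masked_mse",
    "train_zs_deconvnet",
    "train_noise2noise",
    "train_noise2void",
    "train_dip",
    "train_self2self",
    "train",
    "denoise",
]

METHODS = ("zs_deconvnet", "noise2noise", "noise2void", "dip", "self2self")

# Per-method epoch budgets (the published training schedule).
_DEFAULT_EPOCHS = {
    "zs_deconvnet": 100,
    "noise2noise": 100,
    "noise2void": 1000,
    "dip": 1000,
    "self2self": 1000,
}


@dataclass
class DenoiserConfig:
    """Hyperparameters of one method.

    Defaults follow the shared training schedule: learning rate 0.001,
    Adam, MSE loss, batch size 1, 100 epochs for zs_deconvnet and
    noise2noise, 1000 for noise2void/dip/self2self, early stopping after
    10 epochs without loss improvement.
    """

    method: str
    learning_rate: float = 0.001
    epochs: int = 0  # 0 -> per-method default
    optimizer_name: str = "adam"
    loss_name: str = "mse"
    batch_size: int = 1
    early_stop_patience: int = 10
    steps_per_epoch: int = 1
    network: NetworkSpec = field(default_factory=NetworkSpec)
    # method-specific knobs
    psf_sigma: float = 1.0                # zs_deconvnet (if no PSF given)
    corruption_sigma: float = 0.05        # zs_deconvnet input corruption
    paired_corruption: bool = False       # zs_deconvnet: also corrupt target
    mask_fraction: float = 0.02           # noise2void
    neighbor_radius: int = 2              # noise2void (5x5 window)
    dropout_rate: float = 0.3             # self2self
    n_prediction_samples: int = 50        # self2self
    input_noise_kind: str = "uniform01"   # dip z distribution

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method {self.method!r} not in {METHODS}")
        if self.epochs == 0:
            self.epochs = _DEFAULT_EPOCHS[self.method]
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer_name != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss_name != "mse":
            raise ValueError("only the mse loss is supported")
        if self.batch_size != 1:
            raise ValueError("batch_size is fixed at 1 (single-image training)")
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in (0, 1)")
        if not 0 < self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in (0, 1)")
        if self.n_prediction_samples < 1:
            raise ValueError("n_prediction_samples must be >= 1")
        if self.input_noise_kind not in ("uniform01", "gaussian"):
            raise ValueError("input_noise_kind must be 'uniform01' or 'gaussian'")

    @classmethod
    def default(cls, method: str) -> "DenoiserConfig":
        return cls(method=method)

    @classmethod
    def fast(cls, method: str) -> "DenoiserConfig":
        """Desk-scale profile: small backbone, reduced epochs, CPU-friendly.

        Intended for 64x64 phantoms: 1000-epoch methods run 200 epochs,
        100-epoch methods run 50, with 3 gradient steps per epoch and a
        depth-2 / 8-channel backbone.
        """
        epochs = 200 if _DEFAULT_EPOCHS[method] == 1000 else 50
        return cls(
            method=method,
            epochs=epochs,
            steps_per_epoch=3,
            network=NetworkSpec(depth=2, base_channels=8),
            n_prediction_samples=10,
        )


@dataclass
class MaskedImage:
    """A blind-spot-masked image plus the mask that produced it."""

    pixels: ImageGrid
    mask: np.ndarray  # boolean, True at masked positions
    replacement_rule: str = "neighbor_swap"


@dataclass
class DIPInput:
    """The fixed random input field z; sampled once, never re-sampled."""

    z: np.ndarray
    distribution: str
    seed: int

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.z.tobytes()).hexdigest()


@dataclass
class TrainingTrace:
    """Per-epoch loss record of one training run."""

    losses: list[float]
    stopped_epoch: int
    stop_reason: str  # "max_epochs" | "early_stop"

    def __post_init__(self) -> None:
        if self.stop_reason not in ("max_epochs", "early_stop"):
            raise ValueError(f"bad stop_reason {self.stop_reason!r}")
        if self.stopped_epoch != len(self.losses):
            raise ValueError("stopped_epoch must equal the number of recorded losses")


class EarlyStopper:
    """Stop when the loss has not improved for ``patience`` consecutive epochs."""

    def __init__(self, patience: int = 10) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record the loss of ``epoch`` (1-based); return True to stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            return False
        return epoch - self.best_epoch >= self.patience


def masked_mse(
    pred: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """MSE over ``mask`` (or all pixels) and its gradient w.r.t. ``pred``.

    With a mask, the loss is the mean of squared errors over the masked
    positions only, so its gradient is exactly zero everywhere else.
    """
    diff = pred - target
    if mask is None:
        n = diff.size
        return float(np.mean(diff**2)), 2.0 * diff / n
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no pixels")
    masked = np.where(mask, diff, 0.0)
    loss = float(np.sum(masked**2) / n)
    return loss, 2.0 * masked / n


def blind_spot_mask(
    image: ImageGrid,
    fraction: float,
    neighbor_radius: int = 2,
    seed: int | np.random.Generator = 0,
) -> MaskedImage:
    """Replace a random pixel subset with random in-window neighbors.

    Selects ``round(fraction * N)`` positions uniformly at random; each
    selected pixel's value is overwritten by the value of a uniformly
    chosen *different* pixel inside its (2r+1)x(2r+1) window. Unmasked
    pixels are untouched.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if neighbor_radius < 1:
        raise ValueError("neighbor_radius must be >= 1 (window of size 1 is degenerate)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else substream(seed, "masking")
    )
    h, w = image.pixels.shape
    n_total = h * w
    n_mask = int(round(fraction * n_total))
    flat_idx = rng.choice(n_total, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat_idx, (h, w))

    pixels = image.pixels.copy()
    mask = np.zeros((h, w), dtype=bool)
    r = neighbor_radius
    for i, j in zip(rows, cols):
        while True:
            di = rng.integers(-r, r + 1)
            dj = rng.integers(-r, r + 1)
            if di == 0 and dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w:
                break
        pixels[i, j] = image.pixels[ni, nj]
        mask[i, j] = True
    return MaskedImage(image.with_pixels(pixels), mask, "neighbor_swap")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _run_training(
    config: DenoiserConfig,
    seed: int,
    step_fn: Callable[[UNet, np.random.Generator], tuple[float, np.ndarray]],
    track_best_output: bool = False,
) -> tuple[UNet, TrainingTrace, np.ndarray | None]:
    """Shared loop: build net, run epochs of steps, early-stop on the loss.

    ``step_fn(net, rng)`` performs one forward pass and returns
    ``(loss, dloss_dpred)``; the loop handles backward, the Adam update,
    the per-epoch trace (mean loss over the epoch's steps) and stopping.
    """
    net = UNet(config.network, seed=seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = substream(seed, "masking")
    stopper = EarlyStopper(config.early_stop_patience)
    losses: list[float] = []
    best_output: np.ndarray | None = None
    best_loss = np.inf
    stop_reason = "max_epochs"

    for epoch in range(1, config.epochs + 1):
        epoch_losses = []
        for _ in range(config.steps_per_epoch):
            loss, grad = step_fn(net, rng)
            net.backward(grad)
            opt.step(net.grads())
            epoch_losses.append(loss)
        mean_loss = float(np.mean(epoch_losses))
        losses.append(mean_loss)
        if track_best_output and mean_loss < best_loss:
            best_loss = mean_loss
            best_output = net._last_output.copy()  # set by step_fn
        if stopper.update(epoch, mean_loss):
            stop_reason = "early_stop"
            break

    trace = TrainingTrace(losses, len(losses), stop_reason)
    return net, trace, best_output


@dataclass
class TrainedDenoiser:
    """A trained model plus what it needs to denoise new images."""

    method: str
    net: UNet
    config: DenoiserConfig
    seed: int
    psf: PSFKernel | None = None
    dip_output: np.ndarray | None = None
    dip_input: DIPInput | None = None

    def predict(self, image: ImageGrid) -> ImageGrid:
        return denoise(self, image)


class IdentityModel:
    """Debug model whose prediction is its input, unchanged."""

    method = "identity"

    def predict(self, image: ImageGrid) -> ImageGrid:
        return image.with_pixels(image.pixels.copy())


def denoise(model, image: ImageGrid) -> ImageGrid:
    """Apply a trained (or debug) model to an image.

    Deterministic single forward pass for all methods except self2self,
    whose prediction averages ``n_prediction_samples`` dropout passes.
    Output is clipped to [0, 1].
    """
    if isinstance(model, IdentityModel):
        return model.predict(image)
    if model.method == "zs_deconvnet":
        blurred = ndimage.convolve(
            image.pixels, model.psf.weights, mode="reflect"
        )
        out = model.net.predict(blurred)
    elif model.method == "dip":
        out = model.dip_output
        if out is None:
            out = model.net.predict(model.dip_input.z)
    elif model.method == "self2self":
        rng = substream(model.seed, "prediction")
        rate = model.config.dropout_rate
        acc = np.zeros_like(image.pixels)
        for _ in range(model.config.n_prediction_samples):
            keep = rng.random(image.pixels.shape) >= rate
            acc += model.net.predict(image.pixels * keep)
        out = acc / model.config.n_prediction_samples
    else:  # noise2noise, noise2void: plain forward pass
        out = model.net.predict(image.pixels)
    return image.with_pixels(np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# the five trainers
# ---------------------------------------------------------------------------


def train_zs_deconvnet(
    y: ImageGrid,
    psf: PSFKernel,
    config: DenoiserConfig | None = None,
    seed: int = 0,
) -> tuple[ImageGrid, TrainingTrace, TrainedDenoiser]:
    """Zero-shot deconvolution: learn to invert the PSF from y alone.

    Each step corrupts y with fresh Gaussian noise, re-blurs it with the
    PSF, and trains f to map the blurred corrupted input back to y. The
    returned image is f(h * y), the deconvolved estimate.
    """
    config = config or DenoiserConfig.default("zs_deconvnet")
    target = y.pixels
    corr_rng = substream(seed, "corruption")
    sigma = config.corruption_sigma

    def step(net: UNet, rng: np.random.Generator) -> tuple[float, np.ndarray]:
        y_corrupt = np.clip(
            target + corr_rng.normal(0.0, sigma, target.shape), 0.0, 1.0
        )
        x_in = ndimage.convolve(y_corrupt, psf.weights, mode="reflect")
        pred = net.forward(x_in)
        step_target = target
        if config.paired_corruption:
            step_target = np.clip(
                target + corr_rng.normal(0.0, sigma, target.shape), 0.0, 1.0
            )
        loss, grad = masked_mse(pred, step_target)
        return loss, grad

    net, trace, _ = _run_training(config, seed, step)
    model = TrainedDenoiser("zs_deconvnet", net, config, seed, psf=psf)
    return denoise(model, y), trace, model


def train_noise2noise(
    pair: NoisyPair,
    config: DenoiserConfig | None = None,
    seed: int = 0,
) -> tuple[ImageGrid, TrainingTrace, TrainedDenoiser]:
    """Paired training: predict the second noisy observation from the first."""
    config = config or DenoiserConfig.default("noise2noise")
    y1, y2 = pair.y1.pixels, pair.y2.pixels
    if np.array_equal(y1, y2):
        warnings.warn(
            "noise2noise pair is degenerate (y1 == y2): the model can "
            "learn the identity map",
            UserWarning,
            stacklevel=2,
        )

    def step(net: UNet, rng: np.random.Generator) -> tuple[float, np.ndarray]:
        pred = net.forward(y1)
        return masked_mse(pred, y2)

    net, trace, _ = _run_training(config, seed, step)
    model = TrainedDenoiser("noise2noise", net, config, seed)
    return denoise(model, pair.y1), trace, model


def train_noise2void(
    y: ImageGrid,
    config: DenoiserConfig | None = None,
    seed: int = 0,
) -> tuple[ImageGrid, TrainingTrace, TrainedDenoiser]:
    """Blind-spot training on a single noisy image.

    Every step draws a fresh blind-spot masking; the loss compares the
    prediction to the original pixel values at masked positions only, so
    the network can never copy the noise of the pixel it predicts.
    """
    config = config or DenoiserConfig.default("noise2void")

    def step(net: UNet, rng: np.random.Generator) -> tuple[float, np.ndarray]:
        masked = blind_spot_mask(
            y, config.mask_fraction, config.neighbor_radius, rng
        )
        pred = net.forward(masked.pixels.pixels)
        return masked_mse(pred, y.pixels, masked.mask)

    net, trace, _ = _run_training(config, seed, step)
    model = TrainedDenoiser("noise2void", net, config, seed)
    return denoise(model, y), trace, model


def train_dip(
    y: ImageGrid,
    config: DenoiserConfig | None = None,
    seed: int = 0,
) -> tuple[ImageGrid, TrainingTrace, TrainedDenoiser]:
    """Deep image prior: fit y from a fixed random input z.

    z is sampled once and never re-sampled (its checksum is stored on the
    returned model); the reported image is the network output at the
    best-loss epoch, which is where early stopping leaves the run.
    """
    config = config or DenoiserConfig.default("dip")
    z_rng = substream(seed, "dip_input")
    shape = y.pixels.shape
    if config.input_noise_kind == "uniform01":
        z = z_rng.random(shape)
    else:
        z = z_rng.normal(0.0, 0.1, shape)
    dip_input = DIPInput(z=z, distribution=config.input_noise_kind, seed=seed)
    checksum = dip_input.checksum

    def step(net: UNet, rng: np.random.Generator) -> tuple[float, np.ndarray]:
        if dip_input.checksum != checksum:
            raise RuntimeError("DIP input z was re-sampled mid-run")
        pred = net.forward(z)
        net._last_output = pred
        return masked_mse(pred, y.pixels)

    net, trace, best_output = _run_training(
        config, seed, step, track_best_output=True
    )
    model = TrainedDenoiser(
        "dip", net, config, seed,
        dip_output=np.clip(best_output, 0.0, 1.0),
        dip_input=dip_input,
    )
    return denoise(model, y), trace, model


def train_self2self(
    y: ImageGrid,
    config: DenoiserConfig | None = None,
    seed: int = 0,
) -> tuple[ImageGrid, TrainingTrace, TrainedDenoiser]:
    """Dropout-masked training on a single noisy image.

    Each step zeroes a Bernoulli subset of input pixels and penalizes the
    prediction only at the dropped positions; the final prediction is the
    average of ``n_prediction_samples`` stochastic forward passes.
    """
    config = config or DenoiserConfig.default("self2self")
    drop_rng = substream(seed, "dropout")
    rate = config.dropout_rate

    def step(net: UNet, rng: np.random.Generator) -> tuple[float, np.ndarray]:
        dropped = drop_rng.random(y.pixels.shape) < rate
        pred = net.forward(y.pixels * ~dropped)
        return masked_mse(pred, y.pixels, dropped)

    net, trace, _ = _run_training(config, seed, step)
    model = TrainedDenoiser("self2self", net, config, seed)
    return denoise(model, y), trace, model


def train(
    method: str,
    y: ImageGrid | NoisyPair,
    config: DenoiserConfig | None = None,
    seed: int = 0,
    psf: PSFKernel | None = None,
) -> tuple[ImageGrid, TrainingTrace, TrainedDenoiser]:
    """Dispatch to the right trainer by method name."""
    if method == "zs_deconvnet":
        if psf is None:
            from .phantom import gaussian_psf

            cfg = config or DenoiserConfig.default(method)
            psf = gaussian_psf(cfg.psf_sigma, 9)
        img = y.y1 if isinstance(y, NoisyPair) else y
        return train_zs_deconvnet(img, psf, config, seed)
    if method == "noise2noise":
        if not isinstance(y, NoisyPair):
            raise ValueError("noise2noise requires a NoisyPair")
        return train_noise2noise(y, config, seed)
    img = y.y1 if isinstance(y, NoisyPair) else y
    if method == "noise2void":
        return train_noise2void(img, config, seed)
    if method == "dip":
        return train_dip(img, config, seed)
    if method == "self2self":
        return train_self2self(img, config, seed)
    raise ValueError(f"unknown method {method!r}")
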