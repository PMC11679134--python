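"""Encoder-decoder backbone with skip connections.

The encoder stacks ``depth`` stages of (conv 3x3 -> batch norm -> ReLU ->
2x max-pool); the decoder mirrors it with 2x nearest-neighbor upsampling
and concatenation of the corresponding encoder feature map. A final
convolution maps back to one channel, through a sigmoid by default so
every output pixel lies strictly in (0, 1). Weight initialization is
seeded, so two networks built from the same spec and seed are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import substream
from .layers import BatchNorm2d, Conv2d, MaxPool2, ReLU, Sigmoid, Upsample2


@dataclass
class NetworkSpec:
    """Architecture description of the shared denoising backbone."""

    depth: int = 3
    base_channels: int = 16
    kernel_size: int = 3
    skip_connections: bool = True
    final_activation: str = "sigmoid"
    uses_dropout: bool = False
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.final_activation not in ("sigmoid", "linear"):
            raise ValueError(
                f"final_activation must be 'sigmoid' or 'linear', "
                f"got {self.final_activation!r}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class UNet:
    """Single-channel image-to-image network; input shape (H, W)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = substream(seed, "weights")
        d, base, k = spec.depth, spec.base_channels, spec.kernel_size

        self.enc: list[tuple[Conv2d, BatchNorm2d, ReLU, MaxPool2]] = []
        ch = 1
        for i in range(d):
            out = base * 2**i
            self.enc.append(
                (Conv2d(ch, out, k, rng), BatchNorm2d(out), ReLU(), MaxPool2())
            )
            ch = out

        self.bottleneck = (Conv2d(ch, ch, k, rng), BatchNorm2d(ch), ReLU())

        self.dec: list[tuple[Upsample2, Conv2d, BatchNorm2d, ReLU]] = []
        for i in reversed(range(d)):
            skip_ch = base * 2**i
            in_ch = ch + skip_ch if spec.skip_connections else ch
            self.dec.append(
                (Upsample2(), Conv2d(in_ch, skip_ch, k, rng), BatchNorm2d(skip_ch), ReLU())
            )
            ch = skip_ch

        self.head = Conv2d(ch, 1, k, rng)
        self.out_act = Sigmoid() if spec.final_activation == "sigmoid" else None

    # -- parameter plumbing -------------------------------------------------

    def _layers_with_params(self):
        for conv, bn, _, _ in self.enc:
            yield conv
            yield bn
        yield self.bottleneck[0]
        yield self.bottleneck[1]
        for _, conv, bn, _ in self.dec:
            yield conv
            yield bn
        yield self.head

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self._layers_with_params():
            out.extend(layer.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self._layers_with_params():
            out.extend(layer.grads())
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self._layers_with_params())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={x.ndim}")
        h, w = x.shape
        f = 2**self.spec.depth
        if h % f or w % f:
            raise ValueError(
                f"spatial sides must be divisible by {f} at depth "
                f"{self.spec.depth}; got {h}x{w} (use predict() for padding)"
            )
        t = x[None, :, :]
        self._skips: list[np.ndarray] = []
        for conv, bn, relu, pool in self.enc:
            t = relu.forward(bn.forward(conv.forward(t)))
            self._skips.append(t)
            t = pool.forward(t)
        conv, bn, relu = self.bottleneck
        t = relu.forward(bn.forward(conv.forward(t)))
        for (up, conv, bn, relu), skip in zip(self.dec, reversed(self._skips)):
            t = up.forward(t)
            if self.spec.skip_connections:
                t = np.concatenate([t, skip], axis=0)
            t = relu.forward(bn.forward(conv.forward(t)))
        t = self.head.forward(t)
        if self.out_act is not None:
            t = self.out_act.forward(t)
        return t[0]

    def backward(self, gout: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/d(output)."""
        g = gout[None, :, :]
        if self.out_act is not None:
            g = self.out_act.backward(g)
        g = self.head.backward(g)
        # Decoder stage j (forward order) concatenates encoder stage
        # depth-1-j's feature map; walking the decoder backwards therefore
        # yields skip gradients for encoder stages 0, 1, ..., depth-1.
        skip_grads: list[np.ndarray | None] = []
        for up, conv, bn, relu in reversed(self.dec):
            g = conv.backward(bn.backward(relu.backward(g)))
            if self.spec.skip_connections:
                n_skip = self.enc[len(skip_grads)][0].out_channels
                g_up, g_skip = g[:-n_skip], g[-n_skip:]
                skip_grads.append(g_skip)
                g = up.backward(g_up)
            else:
                skip_grads.append(None)
                g = up.backward(g)
        conv, bn, relu = self.bottleneck
        g = conv.backward(bn.backward(relu.backward(g)))
        for (conv, bn, relu, pool), g_skip in zip(
            reversed(self.enc), reversed(skip_grads)
        ):
            g = pool.backward(g)
            if g_skip is not None:
                g = g + g_skip
            g = conv.backward(bn.backward(relu.backward(g)))

    # -- inference ----------------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass with reflective padding to a pool-compatible size."""
        h, w = x.shape
        f = 2**self.spec.depth
        ph = (-h) % f
        pw = (-w) % f
        if ph or pw:
            xp = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
            out = self.forward(xp)[:h, :w]
        else:
            out = self.forward(x)
        return np.clip(out, 0.0, 1.0)
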