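"""Differentiable layers on (channels, height, width) arrays.

Each layer caches what its backward pass needs on ``forward`` and exposes
``params()`` / ``grads()`` as parallel lists of arrays for the optimizer.
Spatial shapes are preserved by every layer except pooling/upsampling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2d:
    """Same-padding 2-D convolution (cross-correlation) via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        rng = rng if rng is not None else np.random.default_rng(0)
        # He initialization: suits the ReLU stages that follow each conv.
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (c, h, w, k, k) -> (h*w, c*k*k)
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * self.k * self.k)
        self._cols = cols
        self._shape = (h, w)
        out = cols @ self.W.T + self.b
        return out.T.reshape(self.out_channels, h, w)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, w = self._shape
        g = gout.reshape(self.out_channels, h * w).T  # (h*w, out)
        self.gW = g.T @ self._cols
        self.gb = g.sum(axis=0)
        gcols = g @ self.W  # (h*w, c*k*k)
        k, p = self.k, self.k // 2
        gcols = gcols.reshape(h, w, self.in_channels, k, k)
        gxp = np.zeros((self.in_channels, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + h, j : j + w] += gcols[:, :, :, i, j].transpose(
                    2, 0, 1
                )
        return gxp[:, p : p + h, p : p + w]

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class BatchNorm2d:
    """Per-channel normalization over the spatial axes (batch size 1)."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.ggamma = np.zeros(channels)
        self.gbeta = np.zeros(channels)
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._istd: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        self._xhat, self._istd = xhat, istd
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        self.ggamma = (gout * xhat).sum(axis=(1, 2))
        self.gbeta = gout.sum(axis=(1, 2))
        gxhat = gout * self.gamma[:, None, None]
        m1 = gxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return istd * (gxhat - m1 - xhat * m2)

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.ggamma, self.gbeta]

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Sigmoid:
    def forward(self, x: np.ndarray) -> np.ndarray:
        # Clipping the pre-activation at +-30 keeps exp() finite and the
        # output strictly inside (0, 1) even after float64 rounding.
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._y * (1.0 - self._y)


class MaxPool2:
    """2x2 max pooling with stride 2; requires even spatial sides."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial sides must be even for 2x pooling, got {h}x{w}")
        blocks = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
        flat = blocks.reshape(c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (c, h, w)
        return flat.max(axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        gflat = np.zeros((c, h // 2, w // 2, 4))
        np.put_along_axis(
            gflat, self._argmax[..., None], gout[..., None], axis=-1
        )
        return (
            gflat.reshape(c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h, w)
        )


class Upsample2:
    """2x nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, h, w = gout.shape
        return gout.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))
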