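"""Independent brute-force oracles for the image operations and metrics.

These deliberately use naive loops and explicit formulas so that they
share no code path with the package implementations they verify.
"""

from __future__ import annotations

import math

import numpy as np


def conv2d_reflect_oracle(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N^2 k^2) convolution sum with reflective boundaries."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    # convolution: kernel index runs opposite to the image
                    acc += kernel[a, b] * padded[i + kh - 1 - a, j + kw - 1 - b]
            out[i, j] = acc
    return out


def psnr_oracle(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    mse = 0.0
    for xi, yi in zip(x.ravel(), y.ravel()):
        mse += (xi - yi) ** 2
    mse /= x.size
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(max_val * max_val / mse)


def rmse_oracle(x: np.ndarray, y: np.ndarray) -> float:
    acc = 0.0
    for xi, yi in zip(x.ravel(), y.ravel()):
        acc += (xi - yi) ** 2
    return math.sqrt(acc / x.size)


def ssim_global_oracle(
    x: np.ndarray, y: np.ndarray, C1: float = 1e-4, C2: float = 9e-4
) -> float:
    n = x.size
    mux = sum(x.ravel()) / n
    muy = sum(y.ravel()) / n
    varx = sum((v - mux) ** 2 for v in x.ravel()) / n
    vary = sum((v - muy) ** 2 for v in y.ravel()) / n
    cov = sum((a - mux) * (b - muy) for a, b in zip(x.ravel(), y.ravel())) / n
    return ((2 * mux * muy + C1) * (2 * cov + C2)) / (
        (mux**2 + muy**2 + C1) * (varx + vary + C2)
    )


def frc_oracle(x: np.ndarray, y: np.ndarray) -> dict[int, float]:
    """Per-ring correlations by exhaustive loop over frequency pixels.

    Rings are integer rounded radii 1..n//2; images are mean-subtracted.
    Returns {radius: correlation}.
    """
    n = x.shape[0]
    F1 = np.fft.fft2(x - x.mean())
    F2 = np.fft.fft2(y - y.mean())
    cross: dict[int, complex] = {}
    p1: dict[int, float] = {}
    p2: dict[int, float] = {}
    for i in range(n):
        for j in range(n):
            ki = i if i <= n // 2 else i - n
            kj = j if j <= n // 2 else j - n
            r = round(math.hypot(ki, kj))
            if r == 0 or r > n // 2:
                continue
            cross[r] = cross.get(r, 0.0) + F1[i, j] * np.conj(F2[i, j])
            p1[r] = p1.get(r, 0.0) + abs(F1[i, j]) ** 2
            p2[r] = p2.get(r, 0.0) + abs(F2[i, j]) ** 2
    out = {}
    for r in sorted(cross):
        denom = math.sqrt(p1[r] * p2[r])
        out[r] = 0.0 if denom == 0 else float(cross[r].real) / denom
    return out
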