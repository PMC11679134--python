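"""Image-quality metrics: PSNR, SSIM, RMSE, and Fourier ring correlation.

PSNR (dB) and RMSE are the usual pixel-wise fidelity measures on [0, 1]
images with MAX = 1 (the representable ceiling, not the per-image max).
SSIM is provided in two modes: ``global`` evaluates the similarity
formula once on whole-image statistics; ``sliding`` averages it over
local uniform windows (the conventional windowed form). FRC correlates
the two images' Fourier transforms over concentric integer-radius
frequency rings; its scalar summary is the mean ring correlation up to
Nyquist, which (taking the real part of the cross-spectrum) can be
negative for anticorrelated high-frequency content. The frequency at
which the curve first drops below 1/7 is reported as a secondary
resolution proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import ImageGrid

__all__ = [
    "SSIMParams",
    "FRCCurve",
    "MetricReport",
    "psnr",
    "ssim",
    "rmse",
    "frc",
    "evaluate_all",
]


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def psnr(reference, test, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(MAX^2 / MSE), in decibels.

    Identical images have zero MSE; the positive-infinity sentinel is
    returned in that case (serialized as the string "inf" in reports).
    """
    x, y = _pixels(reference), _pixels(test)
    _check_shapes(x, y)
    if max_val <= 0:
        raise ValueError("max_val must be > 0")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val**2 / mse)


def rmse(x, y) -> float:
    """Root-mean-square pixel difference."""
    a, b = _pixels(x), _pixels(y)
    _check_shapes(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class SSIMParams:
    """Stabilization constants and windowing mode for SSIM.

    C1 = (K1*L)^2 and C2 = (K2*L)^2 with the conventional K1=0.01,
    K2=0.03 over dynamic range L (1.0 for normalized images).
    """

    L: float = 1.0
    K1: float = 0.01
    K2: float = 0.03
    windowing: str = "global"
    window_side: int = 8

    def __post_init__(self) -> None:
        if self.windowing not in ("global", "sliding"):
            raise ValueError("windowing must be 'global' or 'sliding'")
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("stabilization constants must be > 0")
        if self.windowing == "sliding" and self.window_side < 2:
            raise ValueError("window_side must be >= 2")

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


def _ssim_stat(
    mux, muy, varx, vary, cov, C1: float, C2: float
):
    return ((2 * mux * muy + C1) * (2 * cov + C2)) / (
        (mux**2 + muy**2 + C1) * (varx + vary + C2)
    )


def ssim(x, y, params: SSIMParams | None = None) -> float:
    """Structural similarity between two equal-shape images.

    Global mode computes the formula once from whole-image means,
    (population) variances and covariance. Sliding mode averages the
    same formula over every fully-interior window of side
    ``params.window_side``, using unbiased variance/covariance, matching
    the standard windowed definition.
    """
    params = params or SSIMParams()
    a, b = _pixels(x), _pixels(y)
    _check_shapes(a, b)
    C1, C2 = params.C1, params.C2

    if params.windowing == "global":
        mux, muy = a.mean(), b.mean()
        varx, vary = a.var(), b.var()
        cov = ((a - mux) * (b - muy)).mean()
        return float(_ssim_stat(mux, muy, varx, vary, cov, C1, C2))

    w = params.window_side
    if min(a.shape) < w:
        raise ValueError(f"image smaller than the {w}x{w} SSIM window")
    from numpy.lib.stride_tricks import sliding_window_view

    wa = sliding_window_view(a, (w, w)).reshape(-1, w * w)
    wb = sliding_window_view(b, (w, w)).reshape(-1, w * w)
    n = w * w
    mux = wa.mean(axis=1)
    muy = wb.mean(axis=1)
    # unbiased second moments, as in the standard windowed definition
    varx = ((wa - mux[:, None]) ** 2).sum(axis=1) / (n - 1)
    vary = ((wb - muy[:, None]) ** 2).sum(axis=1) / (n - 1)
    cov = ((wa - mux[:, None]) * (wb - muy[:, None])).sum(axis=1) / (n - 1)
    return float(_ssim_stat(mux, muy, varx, vary, cov, C1, C2).mean())


@dataclass
class FRCCurve:
    """Per-ring Fourier correlation between two images."""

    ring_frequencies: np.ndarray  # cycles/pixel, strictly increasing, <= 0.5
    correlations: np.ndarray      # real values in [-1, 1]
    ring_pixel_counts: np.ndarray
    summary: float = field(init=False)

    def __post_init__(self) -> None:
        self.ring_frequencies = np.asarray(self.ring_frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.ring_pixel_counts = np.asarray(self.ring_pixel_counts, dtype=int)
        if np.any(np.diff(self.ring_frequencies) <= 0):
            raise ValueError("ring frequencies must be strictly increasing")
        if self.ring_frequencies.size and self.ring_frequencies[-1] > 0.5 + 1e-12:
            raise ValueError("ring frequencies must not exceed Nyquist (0.5)")
        if np.any(np.abs(self.correlations) > 1 + 1e-9):
            raise ValueError("ring correlations must lie in [-1, 1]")
        self.correlations = np.clip(self.correlations, -1.0, 1.0)
        self.summary = float(self.correlations.mean())

    def band_mean(self, fmin: float = 0.0, fmax: float = 0.5) -> float:
        """Mean ring correlation over frequencies in (fmin, fmax]."""
        sel = (self.ring_frequencies > fmin) & (self.ring_frequencies <= fmax)
        if not sel.any():
            raise ValueError(f"no rings in ({fmin}, {fmax}]")
        return float(self.correlations[sel].mean())

    @property
    def threshold_freq(self) -> float:
        """First frequency where the curve drops below 1/7 (0.5 if never)."""
        below = self.correlations < (1.0 / 7.0)
        if not below.any():
            return 0.5
        return float(self.ring_frequencies[int(np.argmax(below))])


def frc(a, b, ring_width: int = 1, keep_dc: bool = False) -> FRCCurve:
    """Fourier ring correlation between two equal-shape square images.

    Both images are mean-subtracted (unless ``keep_dc``), Fourier
    transformed, and correlated ring by ring: frequency-plane pixels are
    assigned to concentric rings by their rounded integer radius, the DC
    ring is excluded, and each ring's correlation is
    Re(sum F1 conj(F2)) / sqrt(sum|F1|^2 sum|F2|^2). Non-square inputs
    are center-cropped to square.
    """
    x, y = _pixels(a), _pixels(b)
    _check_shapes(x, y)
    if min(x.shape) < 8:
        raise ValueError("images must be at least 8x8 for ring statistics")
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    h, w = x.shape
    if h != w:
        n = min(h, w)
        r0, c0 = (h - n) // 2, (w - n) // 2
        x = x[r0 : r0 + n, c0 : c0 + n]
        y = y[r0 : r0 + n, c0 : c0 + n]
    n = x.shape[0]

    if not keep_dc:
        x = x - x.mean()
        y = y - y.mean()
    F1 = np.fft.fft2(x)
    F2 = np.fft.fft2(y)

    k = np.fft.fftfreq(n) * n  # integer frequency coordinates
    kx, ky = np.meshgrid(k, k)
    radius = np.rint(np.hypot(kx, ky)).astype(int)

    r_lo = 0 if keep_dc else 1
    r_hi = n // 2  # Nyquist
    cross = F1 * np.conj(F2)
    p1 = np.abs(F1) ** 2
    p2 = np.abs(F2) ** 2

    freqs, corrs, counts = [], [], []
    for start in range(r_lo, r_hi + 1, ring_width):
        stop = min(start + ring_width - 1, r_hi)
        sel = (radius >= start) & (radius <= stop)
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        denom = np.sqrt(p1[sel].sum() * p2[sel].sum())
        corr = 0.0 if denom == 0 else float(np.real(cross[sel].sum()) / denom)
        freqs.append((start + stop) / 2.0 / n)
        corrs.append(corr)
        counts.append(cnt)
    return FRCCurve(np.array(freqs), np.array(corrs), np.array(counts))


@dataclass
class MetricReport:
    """One evaluation row: all four metrics for one method's output."""

    method: str
    psnr_db: float
    ssim: float
    rmse: float
    frc_summary: float
    frc_threshold_freq: float
    reference_mode: str

    def __post_init__(self) -> None:
        if self.reference_mode not in ("noisy_input", "clean_truth"):
            raise ValueError(f"bad reference_mode {self.reference_mode!r}")

    def as_dict(self) -> dict:
        d = {
            "model": self.method,
            "psnr_db": "inf" if math.isinf(self.psnr_db) else self.psnr_db,
            "ssim": self.ssim,
            "rmse": self.rmse,
            "frc": self.frc_summary,
            "frc_threshold_freq": self.frc_threshold_freq,
            "reference_mode": self.reference_mode,
        }
        return d


def evaluate_all(
    noisy: ImageGrid,
    denoised: ImageGrid,
    clean: ImageGrid | None = None,
    mode: str = "noisy_input",
    method: str = "",
    ssim_params: SSIMParams | None = None,
) -> MetricReport:
    """Assemble the four-metric row for one denoised output.

    ``noisy_input`` mode follows the protocol of scoring against the
    original noisy observation — note that the identity transform scores
    perfectly under it. ``clean_truth`` scores against the retained
    synthetic ground truth and requires ``clean``.
    """
    if mode == "noisy_input":
        ref = noisy
    elif mode == "clean_truth":
        if clean is None:
            raise ValueError("clean_truth mode requires the clean image")
        ref = clean
    else:
        raise ValueError(f"unknown mode {mode!r}")
    curve = frc(ref, denoised)
    return MetricReport(
        method=method,
        psnr_db=psnr(ref, denoised),
        ssim=ssim(ref, denoised, ssim_params),
        rmse=rmse(ref, denoised),
        frc_summary=curve.summary,
        frc_threshold_freq=curve.threshold_freq,
        reference_mode=mode,
    )
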