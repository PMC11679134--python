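"""End-to-end benchmark: preprocess, train all methods, evaluate, report.

`run_benchmark` reproduces the comparative protocol: every requested
method trains on the same preprocessed input (noise2noise receives the
noisy pair, the others the first observation), each output is scored
with the four metrics, and rows are assembled in the fixed canonical
method order regardless of execution order. A failing method yields an
error row, never a failed run. Identical (config, master seed) runs are
byte-identical in their CSV/JSON reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball

from ._rng import substream
from .denoise import METHODS, DenoiserConfig, TrainingTrace, train
from .metrics import MetricReport, evaluate_all
from .phantom import (
    ImageGrid,
    NoiseModel,
    gaussian_psf,
    generate_phantom,
    make_noisy_pair,
    modality_preset,
)

__all__ = [
    "METHOD_ORDER",
    "PreprocessConfig",
    "PostprocessConfig",
    "BenchmarkConfig",
    "BenchmarkReport",
    "preprocess",
    "postprocess",
    "run_benchmark",
    "export_loss_curves",
]

# Fixed report row order, matching the comparative tables.
METHOD_ORDER = ("zs_deconvnet", "noise2noise", "noise2void", "dip", "self2self")


@dataclass
class PreprocessConfig:
    """Background subtraction and smoothing switches (all off = identity)."""

    background: str = "none"          # none | rolling_ball | percentile
    rolling_ball_radius: float = 25.0
    percentile: float = 5.0
    filter: str = "none"              # none | gaussian | median
    gaussian_sigma: float = 1.0
    median_size: int = 3

    def __post_init__(self) -> None:
        if self.background not in ("none", "rolling_ball", "percentile"):
            raise ValueError(f"unknown background mode {self.background!r}")
        if self.filter not in ("none", "gaussian", "median"):
            raise ValueError(f"unknown filter {self.filter!r}")
        if self.filter == "median" and self.median_size % 2 == 0:
            raise ValueError(
                f"median window must be odd, got {self.median_size}"
            )


def preprocess(raw: ImageGrid, config: PreprocessConfig | None = None) -> ImageGrid:
    """Background-subtract, smooth, and renormalize an image.

    With every switch off this is the identity. Otherwise the estimated
    background (morphological rolling ball, or a low-percentile constant)
    is subtracted and clipped at zero, the optional filter is applied,
    and the result is rescaled to span [0, 1].
    """
    config = config or PreprocessConfig()
    x = raw.pixels.copy()
    touched = False

    if config.background == "rolling_ball":
        x = np.clip(x - rolling_ball(x, radius=config.rolling_ball_radius), 0, None)
        touched = True
    elif config.background == "percentile":
        x = np.clip(x - np.percentile(x, config.percentile), 0, None)
        touched = True

    if config.filter == "gaussian":
        x = ndimage.gaussian_filter(x, config.gaussian_sigma)
        touched = True
    elif config.filter == "median":
        x = ndimage.median_filter(x, size=config.median_size)
        touched = True

    if touched and x.max() > 0:
        x = x / x.max()
    return raw.with_pixels(np.clip(x, 0.0, 1.0))


@dataclass
class PostprocessConfig:
    """Segmentation and contrast-enhancement switches."""

    segmentation: bool = True
    min_object_area: int = 10
    enhancement: bool = True
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)


def postprocess(
    denoised: ImageGrid, config: PostprocessConfig | None = None
) -> tuple[np.ndarray, ImageGrid]:
    """Segment bright regions (Otsu + small-object removal) and stretch contrast.

    A constant image yields an empty mask with a warning rather than a
    failure. Returns ``(mask, enhanced_image)``.
    """
    config = config or PostprocessConfig()
    x = denoised.pixels
    mask = np.zeros(x.shape, dtype=bool)
    if config.segmentation:
        if np.ptp(x) < 1e-12:
            warnings.warn(
                "constant image: segmentation yields an empty mask",
                UserWarning,
                stacklevel=2,
            )
        else:
            # For bright minority foreground on a dark background Otsu can
            # land inside the background's upper tail; flooring the
            # threshold at the image mean keeps it between the two modes.
            mask = x > max(threshold_otsu(x), x.mean())
            mask = morphology.remove_small_objects(
                mask, max_size=config.min_object_area - 1
            )
    enhanced = denoised
    if config.enhancement:
        lo, hi = np.percentile(x, config.stretch_percentiles)
        if hi > lo:
            enhanced = denoised.with_pixels(
                np.clip((x - lo) / (hi - lo), 0.0, 1.0)
            )
    return mask, enhanced


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs; fully determines its outputs."""

    preset: str = "rayleigh_785"       # synthetic modality preset
    size: int = 64
    n_bodies: int = 3
    body_radius_px: tuple[float, float] | None = None  # None -> size-scaled
    noise_sigma: float | None = None   # None -> the preset's default sigma
    blur_sigma_px: float | None = None # optional observation blur
    methods: tuple[str, ...] = METHOD_ORDER
    denoiser_configs: dict[str, DenoiserConfig] = field(default_factory=dict)
    reference_mode: str = "clean_truth"
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    postprocessing: PostprocessConfig = field(default_factory=PostprocessConfig)
    fast: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.reference_mode not in ("noisy_input", "clean_truth"):
            raise ValueError(f"bad reference_mode {self.reference_mode!r}")
        if self.size < 8:
            raise ValueError("size must be >= 8")

    def config_for(self, method: str) -> DenoiserConfig:
        if method in self.denoiser_configs:
            return self.denoiser_configs[method]
        return (
            DenoiserConfig.fast(method)
            if self.fast
            else DenoiserConfig.default(method)
        )

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class BenchmarkReport:
    """Rows (one per method, canonical order), baseline, traces, provenance."""

    rows: list[MetricReport]
    errors: dict[str, str]
    baseline: MetricReport
    traces: dict[str, TrainingTrace]
    denoised: dict[str, ImageGrid]
    noisy: ImageGrid
    clean: ImageGrid
    config_hash: str
    master_seed: int

    def to_frame(self) -> pd.DataFrame:
        records = [r.as_dict() for r in self.rows]
        return pd.DataFrame.from_records(
            records,
            columns=[
                "model",
                "psnr_db",
                "ssim",
                "rmse",
                "frc",
                "frc_threshold_freq",
                "reference_mode",
            ],
        )

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "baseline": self.baseline.as_dict(),
            "rows": [r.as_dict() for r in self.rows],
            "errors": dict(sorted(self.errors.items())),
        }


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run the full comparative protocol on one synthetic scene."""
    preset = modality_preset(config.preset)
    radii = config.body_radius_px or (config.size / 10, config.size / 6)
    clean, _labels = generate_phantom(
        config.size, config.size, n_bodies=config.n_bodies,
        body_radius_px=radii, seed=config.master_seed,
    )

    observed = clean
    if config.blur_sigma_px:
        psf = gaussian_psf(config.blur_sigma_px, 9)
        from .phantom import apply_psf

        observed = apply_psf(clean, psf)

    noise = preset.noise
    if config.noise_sigma is not None:
        noise = NoiseModel("gaussian", gaussian_sigma=config.noise_sigma)
    seed_rng = substream(config.master_seed, "noise1")
    s1, s2 = (int(s) for s in seed_rng.integers(0, 2**31 - 1, size=2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pair = make_noisy_pair(observed, noise, s1, s2)

    pre = config.preprocessing
    pre_pair = dataclasses.replace(
        pair, y1=preprocess(pair.y1, pre), y2=preprocess(pair.y2, pre)
    )
    noisy = pre_pair.y1

    baseline = evaluate_all(
        noisy, noisy, clean, config.reference_mode, method="noisy_input"
    )

    rows: list[MetricReport] = []
    errors: dict[str, str] = {}
    traces: dict[str, TrainingTrace] = {}
    denoised: dict[str, ImageGrid] = {}
    for method in METHOD_ORDER:
        if method not in config.methods:
            continue
        cfg = config.config_for(method)
        psf = (
            gaussian_psf(config.blur_sigma_px, 9)
            if (method == "zs_deconvnet" and config.blur_sigma_px)
            else None
        )
        try:
            out, trace, _model = train(
                method, pre_pair, cfg, seed=config.master_seed, psf=psf
            )
        except Exception as exc:  # failure isolation: record, keep going
            errors[method] = f"{type(exc).__name__}: {exc}"
            continue
        traces[method] = trace
        denoised[method] = out
        rows.append(
            evaluate_all(noisy, out, clean, config.reference_mode, method=method)
        )

    return BenchmarkReport(
        rows=rows,
        errors=errors,
        baseline=baseline,
        traces=traces,
        denoised=denoised,
        noisy=noisy,
        clean=clean,
        config_hash=config.config_hash(),
        master_seed=config.master_seed,
    )


def export_loss_curves(
    traces: dict[str, TrainingTrace],
    first_k: int = 25,
    png_path=None,
    csv_path=None,
) -> pd.DataFrame:
    """Overlay per-method loss-vs-epoch curves (first ``first_k`` epochs).

    The plot truncates each curve to ``first_k`` points for readability
    (shorter traces are drawn in full); the CSV always holds the complete
    traces, one (model, epoch, loss) row per recorded epoch.
    """
    if not traces:
        raise ValueError("no traces to export")
    records = [
        {"model": name, "epoch": e + 1, "loss": loss}
        for name, trace in traces.items()
        for e, loss in enumerate(trace.losses)
    ]
    df = pd.DataFrame.from_records(records, columns=["model", "epoch", "loss"])
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, trace in traces.items():
            k = min(first_k, len(trace.losses))
            ax.plot(range(1, k + 1), trace.losses[:k], label=name)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss (MSE)")
        ax.set_title(f"Loss vs. epoch (first {first_k} epochs)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return df
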