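"""TIFF image I/O, run configuration, and manifests.

Images travel as single- or multi-page grayscale TIFF, 16-bit by default
(float32 available for lossless round trips); integer data are rescaled
by the dtype ceiling to [0, 1] on read. A JSON sidecar next to each
written image records modality metadata and provenance. All writes are
atomic (temp file + rename) so interrupted runs never leave truncated
artifacts.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import os
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .denoise import DenoiserConfig
from .nn import NetworkSpec
from .phantom import ImageGrid, ImageStack
from .pipeline import BenchmarkConfig, PostprocessConfig, PreprocessConfig

__all__ = [
    "read_image",
    "write_image",
    "load_config",
    "dump_config",
    "RunManifest",
    "atomic_write_bytes",
    "atomic_write_text",
]

_VERSION = "0.1.0"


def atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as f:
            f.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _scale_to_unit(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{path}: RGB(A) input not supported; convert to single-channel "
            "grayscale first (e.g. average the channels)"
        )
    if np.issubdtype(arr.dtype, np.integer):
        ceiling = np.iinfo(arr.dtype).max
        return arr.astype(np.float64) / ceiling
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError(
            f"{path}: float pixels must lie in [0, 1]; found "
            f"min={arr.min():.6g}, max={arr.max():.6g}"
        )
    return arr


def read_image(path) -> ImageGrid | ImageStack:
    """Read a grayscale TIFF (or PNG fixture) as an image or slice stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        arr = tifffile.imread(path)

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    tag = meta.get("modality_tag", "synthetic")
    pitch = float(meta.get("pixel_size_um", 1.0))

    if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        pixels = _scale_to_unit(arr, path)
        slices = [ImageGrid(p, tag, pitch) for p in pixels]
        return ImageStack(slices, step_um=float(meta.get("step_um", 10.0)))
    pixels = _scale_to_unit(arr, path)
    return ImageGrid(pixels, tag, pitch)


def write_image(
    image: ImageGrid | ImageStack,
    path,
    bit_depth: str | int = 16,
    metadata: dict | None = None,
) -> Path:
    """Write an image or stack as lossless TIFF with a JSON sidecar.

    ``bit_depth`` is 8, 16, or "float32"; float32 is written without
    quantization. Writing 8-bit data that needs finer quantization than
    1/255 emits a warning.
    """
    path = Path(path)
    if isinstance(image, ImageStack):
        planes = np.stack([s.pixels for s in image.slices])
        first = image.slices[0]
        extra_meta = {"step_um": image.step_um, "n_slices": len(image)}
    else:
        planes = image.pixels
        first = image
        extra_meta = {}

    if bit_depth == "float32":
        data = planes.astype(np.float32)
    elif bit_depth in (8, 16):
        ceiling = 255 if bit_depth == 8 else 65535
        quantized = np.round(planes * ceiling)
        if bit_depth == 8 and np.max(np.abs(planes - quantized / ceiling)) > 1.0 / (
            2 * 65535
        ):
            warnings.warn(
                f"writing {path.name} at 8-bit loses precision beyond the "
                "16-bit quantization bound",
                UserWarning,
                stacklevel=2,
            )
        data = quantized.astype(np.uint8 if bit_depth == 8 else np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8, 16 or 'float32', got {bit_depth!r}")

    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, data, photometric="minisblack")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise

    sidecar = {
        "modality_tag": first.modality_tag,
        "pixel_size_um": first.pixel_size_um,
        "bit_depth": bit_depth,
        **extra_meta,
        **(metadata or {}),
    }
    atomic_write_text(_sidecar_path(path), json.dumps(sidecar, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_NESTED = {
    "preprocessing": PreprocessConfig,
    "postprocessing": PostprocessConfig,
}


def _build_dataclass(cls, payload: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {context}{key!r}{suggestion}")
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> BenchmarkConfig:
    """Load a YAML or JSON benchmark configuration.

    Unspecified fields fall back to the documented defaults (including
    the per-method training schedule); unknown keys are rejected with a
    spelling suggestion rather than silently ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    text = path.read_text()
    payload = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a mapping at the top level")

    payload = dict(payload)
    for key, cls in _NESTED.items():
        if key in payload and isinstance(payload[key], dict):
            payload[key] = _build_dataclass(cls, payload[key], f"{key}.")
    if "methods" in payload:
        payload["methods"] = tuple(payload["methods"])
    if "denoiser_configs" in payload:
        built = {}
        for method, sub in dict(payload["denoiser_configs"]).items():
            sub = dict(sub)
            sub.setdefault("method", method)
            if "network" in sub and isinstance(sub["network"], dict):
                sub["network"] = _build_dataclass(
                    NetworkSpec, sub["network"], "network."
                )
            built[method] = _build_dataclass(
                DenoiserConfig, sub, f"denoiser_configs.{method}."
            )
        payload["denoiser_configs"] = built
    return _build_dataclass(BenchmarkConfig, payload, "")


def dump_config(config: BenchmarkConfig) -> dict:
    """Normalized plain-dict form of a config; load(dump(c)) round-trips."""
    from .pipeline import _as_jsonable

    return _as_jsonable(config)


@dataclass
class RunManifest:
    """Provenance of one benchmark run, sufficient for bit-identical re-runs."""

    config_hash: str
    master_seed: int
    artifact_paths: list[str]
    version: str = _VERSION
    timestamp: str = ""

    def write(self, path) -> None:
        atomic_write_text(
            Path(path),
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True),
        )
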