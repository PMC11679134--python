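"""Synthetic spheroid phantoms, PSF blurring, and per-modality noise.

Emulates light-sheet images of multicellular spheroids: bright, smoothly
textured ellipsoidal bodies (cell aggregates, ~300-400 um across in the
real samples) on a dark background, over a field of view of ~635 um on a
side. The forward model is the usual microscope observation model

    Y = h * X + n

with ``X`` the latent clean image, ``h`` a point-spread function and
``n`` additive (Gaussian) and/or signal-dependent (Poisson shot) noise.
All intensities live in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._rng import substream

__all__ = [
    "ImageGrid",
    "ImageStack",
    "PSFKernel",
    "NoiseModel",
    "NoisyPair",
    "ModalityPreset",
    "generate_phantom",
    "gaussian_psf",
    "psf_sigma_from_beam_waist",
    "apply_psf",
    "add_noise",
    "make_noisy_pair",
    "modality_preset",
    "MODALITY_PRESETS",
]

VALID_MODALITY_TAGS = ("rayleigh", "fluorescence", "raman", "synthetic")

# Field-of-view analogue of the instrument, in micrometres.
FIELD_OF_VIEW_UM = 635.0


@dataclass
class ImageGrid:
    """A 2-D grayscale intensity field normalized to [0, 1].

    ``pixel_size_um`` is metadata only (physical pixel pitch); no operation
    in this package converts intensities based on it.
    """

    pixels: np.ndarray
    modality_tag: str = "synthetic"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"image too small: {h}x{w}, need at least 8x8")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError(
                "pixels outside [0, 1]: "
                f"min={self.pixels.min():.6g}, max={self.pixels.max():.6g}"
            )
        self.pixels = np.clip(self.pixels, 0.0, 1.0)
        if self.modality_tag not in VALID_MODALITY_TAGS:
            raise ValueError(
                f"modality_tag {self.modality_tag!r} not in {VALID_MODALITY_TAGS}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        return ImageGrid(pixels, self.modality_tag, self.pixel_size_um)


@dataclass
class ImageStack:
    """An ordered list of 2-D slices along the optical axis.

    Training and evaluation operate slice-wise; ``step_um`` records the
    axial sampling (10 um by default, matching typical light-sheet
    optical-sectioning steps).
    """

    slices: list[ImageGrid]
    step_um: float = 10.0

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        shape = self.slices[0].pixels.shape
        for s in self.slices[1:]:
            if s.pixels.shape != shape:
                raise ValueError("all slices in a stack must share one shape")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class PSFKernel:
    """Normalized, centro-symmetric convolution kernel (the blur ``h``)."""

    weights: np.ndarray
    sigma_px: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("PSF weights must be 2-D")
        kh, kw = self.weights.shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"PSF side lengths must be odd, got {kh}x{kw}")
        if np.any(self.weights < 0):
            raise ValueError("PSF weights must be non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"PSF weights must sum to 1, got {total!r}")
        center = self.weights[kh // 2, kw // 2]
        if center < self.weights.max() - 1e-12:
            raise ValueError("PSF maximum must be at the center")
        if not np.allclose(self.weights, self.weights[::-1, ::-1], atol=1e-12):
            raise ValueError("PSF must be symmetric under 180-degree rotation")


@dataclass
class NoiseModel:
    """Detector-noise description: Gaussian read noise and/or Poisson shot noise.

    ``poisson_photons`` is the expected photon count at intensity 1.0;
    smaller values mean stronger shot noise (variance ~ intensity/photons).
    """

    kind: str = "gaussian"
    gaussian_sigma: float = 0.05
    poisson_photons: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson", "mixed"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.kind in ("poisson", "mixed") and self.poisson_photons <= 0:
            raise ValueError("poisson_photons must be > 0 for Poisson noise")


@dataclass
class NoisyPair:
    """Two noisy observations of one latent clean image (plus the truth)."""

    y1: ImageGrid
    y2: ImageGrid
    clean: ImageGrid

    def __post_init__(self) -> None:
        if not (
            self.y1.pixels.shape == self.y2.pixels.shape == self.clean.pixels.shape
        ):
            raise ValueError("y1, y2 and clean must share one shape")


@dataclass
class ModalityPreset:
    """Acquisition settings of one imaging modality, with a default noise model."""

    name: str
    modality_tag: str
    laser_nm: float
    power_mw: float
    exposure_ms: float
    aotf_nm: float
    noise: NoiseModel = field(default_factory=NoiseModel)


# Acquisition parameter rows for the four modality configurations.
# Weak-signal modalities (fluorescence, Raman) default to stronger noise
# than elastic Rayleigh scattering.
MODALITY_PRESETS: dict[str, ModalityPreset] = {
    "rayleigh_785": ModalityPreset(
        "rayleigh_785", "rayleigh", 785, 1, 100, 775,
        NoiseModel("gaussian", gaussian_sigma=0.05),
    ),
    "rayleigh_660": ModalityPreset(
        "rayleigh_660", "rayleigh", 660, 1, 100, 650,
        NoiseModel("gaussian", gaussian_sigma=0.05),
    ),
    "fluorescence_660": ModalityPreset(
        "fluorescence_660", "fluorescence", 660, 130, 5000, 694,
        NoiseModel("mixed", gaussian_sigma=0.15, poisson_photons=200.0),
    ),
    "raman_660": ModalityPreset(
        "raman_660", "raman", 660, 130, 5000, 817,
        NoiseModel("mixed", gaussian_sigma=0.15, poisson_photons=100.0),
    ),
}


def modality_preset(name: str) -> ModalityPreset:
    """Look up one acquisition preset by name."""
    try:
        return MODALITY_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown modality preset {name!r}; valid names: "
            f"{sorted(MODALITY_PRESETS)}"
        ) from None


def generate_phantom(
    height: int,
    width: int,
    n_bodies: int = 3,
    body_radius_px: tuple[float, float] = (8.0, 18.0),
    texture_scale: float = 0.15,
    seed: int = 0,
    background_level: float = 0.06,
) -> tuple[ImageGrid, np.ndarray]:
    """Generate a clean spheroid-like scene and its integer label mask.

    Bodies are random ellipses with a smooth radial intensity falloff and
    granular internal texture (a smoothed random field), placed so that
    they never touch: the label mask has exactly ``n_bodies`` connected
    components. Returns ``(image, labels)`` with labels 0 = background,
    1..n_bodies = bodies. Deterministic per seed.
    """
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if n_bodies < 0:
        raise ValueError(f"n_bodies must be >= 0, got {n_bodies}")
    r_lo, r_hi = float(body_radius_px[0]), float(body_radius_px[1])
    if n_bodies > 0:
        if r_lo <= 0 or r_hi <= 0:
            raise ValueError("body radii must be positive")
        if r_hi >= min(height, width) / 2:
            raise ValueError(
                f"body_radius_px upper bound {r_hi} too large for a "
                f"{height}x{width} image"
            )

    rng = substream(seed, "phantom")
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)

    # Low, gently varying background.
    bg_field = ndimage.gaussian_filter(rng.normal(size=(height, width)), 8.0)
    img = background_level * (1.0 + 0.15 * bg_field)
    labels = np.zeros((height, width), dtype=np.int32)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, max semi-axis)
    for body in range(1, n_bodies + 1):
        for _ in range(500):
            a = rng.uniform(r_lo, r_hi)          # semi-axes
            b = a * rng.uniform(0.6, 1.0)        # mild eccentricity
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(a + 2, height - a - 2)
            cx = rng.uniform(a + 2, width - a - 2)
            # 3 px clearance keeps bodies disconnected in the label mask.
            if all(
                np.hypot(cy - py, cx - px) > a + pr + 3.0
                for py, px, pr in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place body {body} without overlap; reduce "
                "n_bodies or body_radius_px"
            )
        placed.append((cy, cx, a))

        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r2 = (u / a) ** 2 + (v / b) ** 2
        inside = r2 <= 1.0
        base = rng.uniform(0.65, 0.85)
        profile = base * (1.0 - 0.35 * r2)       # brighter core, dimmer rim
        texture = ndimage.gaussian_filter(
            rng.normal(size=(height, width)), 1.5
        )
        profile = profile * (1.0 + texture_scale * texture)
        img = np.where(inside, profile, img)
        labels[inside] = body

    img = np.clip(img, 0.0, 1.0)
    grid = ImageGrid(
        img, "synthetic", pixel_size_um=FIELD_OF_VIEW_UM / max(height, width)
    )
    return grid, labels


def gaussian_psf(sigma_px: float, size: int) -> PSFKernel:
    """Isotropic Gaussian PSF of odd side ``size``, normalized to sum 1."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"PSF size must be odd and >= 1, got {size}")
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px}")
    half = size // 2
    coords = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(coords**2) / (2.0 * sigma_px**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    return PSFKernel(kernel, sigma_px=float(sigma_px))


def psf_sigma_from_beam_waist(
    waist_um: float = 8.0, pixel_size_um: float = FIELD_OF_VIEW_UM / 128
) -> float:
    """Gaussian sigma (pixels) from a light-sheet beam waist.

    Treats the waist as the FWHM of the blur profile; defaults reflect an
    ~8 um waist over a 635 um field sampled at 128 px.
    """
    fwhm_px = waist_um / pixel_size_um
    return fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def apply_psf(image: ImageGrid, psf: PSFKernel) -> ImageGrid:
    """Blur an image with the PSF (reflective boundaries, clipped to [0,1])."""
    kh, kw = psf.weights.shape
    if kh > image.height or kw > image.width:
        raise ValueError(
            f"kernel {kh}x{kw} larger than image {image.height}x{image.width}"
        )
    out = ndimage.convolve(image.pixels, psf.weights, mode="reflect")
    return image.with_pixels(np.clip(out, 0.0, 1.0))


def _corrupt(pixels: np.ndarray, model: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = pixels
    if model.kind in ("poisson", "mixed"):
        counts = rng.poisson(np.clip(out, 0, None) * model.poisson_photons)
        out = counts / model.poisson_photons
    if model.kind in ("gaussian", "mixed"):
        out = out + rng.normal(0.0, model.gaussian_sigma, size=pixels.shape)
    return np.clip(out, 0.0, 1.0)


def add_noise(image: ImageGrid, model: NoiseModel) -> ImageGrid:
    """Corrupt an image per the noise model; deterministic per ``model.seed``."""
    if model.kind == "gaussian" and model.gaussian_sigma == 0.0:
        return image.with_pixels(image.pixels.copy())
    rng = substream(model.seed, "noise1")
    return image.with_pixels(_corrupt(image.pixels, model, rng))


def make_noisy_pair(
    clean: ImageGrid, model: NoiseModel, seed1: int, seed2: int
) -> NoisyPair:
    """Draw two independent noisy observations of one clean image.

    Equal seeds are allowed (the two observations are then identical) but
    flagged with a warning, since downstream paired training degenerates.
    """
    if seed1 == seed2:
        warnings.warn(
            "make_noisy_pair called with seed1 == seed2: the two "
            "observations are identical, not independent",
            UserWarning,
            stacklevel=2,
        )
    y1 = add_noise(clean, replace(model, seed=seed1))
    y2 = add_noise(clean, replace(model, seed=seed2))
    return NoisyPair(y1=y1, y2=y2, clean=clean)
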