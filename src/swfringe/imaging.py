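"""Render synthetic 2D fringe images from specimen surfaces.

This is the data generator that stands in for the micrographs of the
standing-wave experiments: a fluorescent monolayer on a spherical cap
produces concentric fringes where the surface cuts successive antinodal
planes; a membrane-shell discocyte produces nested membrane contours
from multiplanar excitation.

The imaging model is deliberately simple: per pixel, the relative
intensity of the surface point(s) under that pixel (see
:func:`swfringe.optics.detected_intensity`), an optional lateral
Gaussian blur standing in for the scanning point-spread function, then
Poisson shot noise plus Gaussian read noise.  All antinodes crossing the
specimen contribute with equal weight (no axial point-spread envelope):
the experiments this emulates show simultaneous multiplanar visibility
within the depth of field of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .geometry import HeightMap
from .optics import DetectionMode, OpticsConfig, detected_intensity

__all__ = [
    "NoiseModel",
    "FringeImage",
    "render_surface_intensity",
    "render_monolayer_image",
    "render_membrane_image",
    "simulate_subtraction_pair",
    "foreshortening_factor",
]


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise of the detector.

    ``photon_scale`` is the expected photon count at unit relative
    intensity; ``background`` is a constant offset entering the Poisson
    rate (stray light / autofluorescence); ``read_noise_sd`` is additive
    Gaussian noise in counts.  A ``photon_scale`` of 0 is not allowed;
    use :meth:`noiseless` for deterministic rendering.
    """

    photon_scale: float = 500.0
    read_noise_sd: float = 0.0
    background: float = 0.0
    seed: int = 0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @classmethod
    def noiseless(cls, photon_scale: float = 500.0, background: float = 0.0):
        """Deterministic rendering: expected counts, no sampling."""
        return cls(
            photon_scale=photon_scale, background=background, enabled=False
        )


@dataclass
class FringeImage:
    """2D intensity raster with physical pixel size and provenance.

    ``data`` is float counts (noisy renders are integer-valued Poisson
    draws plus Gaussian read noise, clipped at 0); ``pixel_size`` in
    nm/pixel; ``metadata`` records the optics, specimen, noise and seed
    that produced the image.
    """

    data: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("FringeImage data must be 2D")
        if min(self.data.shape) < 64:
            raise ValueError("raster dimensions must be at least 64x64")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


def foreshortening_factor(surface: HeightMap) -> np.ndarray:
    """Areal foreshortening 1/cos(slope) of a dyed surface, per pixel.

    A membrane carrying dye at uniform areal density appears brighter
    where it is steep relative to the image plane: the projected pixel
    footprint collects light from a surface patch larger by
    ``sqrt(1 + |grad z|^2)``.  NaN-filled (undefined) regions yield 1.
    """
    z = surface.data
    filled = np.where(np.isfinite(z), z, np.nan)
    gy, gx = np.gradient(filled, surface.pixel_size)
    g2 = gx**2 + gy**2
    g2 = np.where(np.isfinite(g2), g2, 0.0)
    return np.sqrt(1.0 + g2)


def _apply_noise(
    expected: np.ndarray, noise: NoiseModel, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    if not noise.enabled:
        return expected
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    out = rng.poisson(expected).astype(float)
    if noise.read_noise_sd > 0:
        out += rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _blur(field_: np.ndarray, blur_sigma: float, pixel_size: float) -> np.ndarray:
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    if blur_sigma == 0:
        return field_
    return ndimage.gaussian_filter(field_, sigma=blur_sigma / pixel_size)


def render_surface_intensity(surface: HeightMap, cfg: OpticsConfig) -> np.ndarray:
    """Noiseless relative intensity of a dyed monolayer surface (NaN -> 0)."""
    z = surface.data
    finite = np.isfinite(z)
    out = np.zeros(z.shape, dtype=float)
    if finite.any():
        out[finite] = detected_intensity(z[finite], cfg)
    return out


def render_monolayer_image(
    surface: HeightMap,
    cfg: OpticsConfig,
    noise: NoiseModel,
    blur_sigma: float = 0.0,
) -> FringeImage:
    """Image of a single dyed surface (e.g. the spherical-cap monolayer).

    Expected pixel value is ``photon_scale * I(z) + background`` with
    ``I`` the mode-dependent standing-wave intensity; lateral Gaussian
    blur (sigma in nm) is applied to the noiseless field before noise.
    The contact point of a cap (z = 0) is dark: the mirror is the first
    node, so its expected value is the background alone.  Deterministic
    for a fixed seed.
    """
    rel = render_surface_intensity(surface, cfg)
    expected = noise.photon_scale * _blur(rel, blur_sigma, surface.pixel_size)
    expected = expected + noise.background
    data = _apply_noise(expected, noise)
    return FringeImage(
        data,
        surface.pixel_size,
        metadata={
            "kind": "monolayer",
            "optics": cfg.to_dict(),
            "noise": {
                "photon_scale": noise.photon_scale,
                "read_noise_sd": noise.read_noise_sd,
                "background": noise.background,
                "seed": noise.seed,
                "enabled": noise.enabled,
            },
            "blur_sigma_nm": blur_sigma,
        },
    )


def render_membrane_image(
    upper: HeightMap,
    lower: HeightMap,
    cfg: OpticsConfig,
    noise: NoiseModel,
    blur_sigma: float = 0.0,
    mirror_present: bool = True,
) -> FringeImage:
    """Image of a two-sheet membrane shell (discocyte) above the mirror.

    Both membrane sheets contribute with equal weight; each sheet's
    signal is the standing-wave intensity at its height times the areal
    foreshortening 1/cos(slope) of the dyed membrane.  With
    ``mirror_present=False`` (control on a plain slide) there is no
    standing wave and the per-sheet intensity is a constant, so only the
    steep rim produces contrast -- the familiar bright cell outline.
    """
    if upper.shape != lower.shape or upper.pixel_size != lower.pixel_size:
        raise ValueError("upper and lower height maps must share the grid")
    mu, ml = upper.mask, lower.mask
    if not np.array_equal(mu, ml):
        raise ValueError("upper and lower membrane masks differ")
    if np.any(upper.data[mu] < lower.data[mu]):
        raise ValueError("upper membrane must lie above the lower membrane")

    rel = np.zeros(upper.shape, dtype=float)
    for sheet in (upper, lower):
        if mirror_present:
            sheet_rel = render_surface_intensity(sheet, cfg)
        else:
            sheet_rel = np.where(sheet.mask, 1.0, 0.0)
        rel += sheet_rel * foreshortening_factor(sheet)

    expected = noise.photon_scale * _blur(rel, blur_sigma, upper.pixel_size)
    expected = expected + noise.background
    data = _apply_noise(expected, noise)
    return FringeImage(
        data,
        upper.pixel_size,
        metadata={
            "kind": "membrane",
            "optics": cfg.to_dict(),
            "mirror_present": mirror_present,
            "blur_sigma_nm": blur_sigma,
            "noise": {
                "photon_scale": noise.photon_scale,
                "read_noise_sd": noise.read_noise_sd,
                "background": noise.background,
                "seed": noise.seed,
                "enabled": noise.enabled,
            },
        },
    )


def simulate_subtraction_pair(
    surface: HeightMap,
    excitation_wavelength: float,
    detection_wavelength: float,
    refractive_index: float,
    noise: NoiseModel,
    detection_bandwidth: float = 5.0,
    blur_sigma: float = 0.0,
) -> Tuple[FringeImage, FringeImage, FringeImage]:
    """Excitation-only and emission-only renders of one surface, and their difference.

    Emulates the notch-filter control: the broadband excitation-only
    pattern ``sin^2`` at the excitation wavelength, the emission
    self-interference pattern at the detection wavelength with the
    excitation standing wave suppressed, and the pixel-wise difference
    (excitation - emission, clipped at 0).  The difference carries the
    same beat envelope as the directly observed moire, with period
    ``moire_period(lambda_ex, lambda_det) / (2n)`` in height.

    The two renders use independent noise streams derived from
    ``noise.seed``.
    """
    if detection_wavelength <= excitation_wavelength:
        raise ValueError("detection_wavelength must exceed excitation_wavelength")
    cfg_ex = OpticsConfig(
        excitation_wavelength=excitation_wavelength,
        refractive_index=refractive_index,
        detection_mode=DetectionMode.BROADBAND_EXCITATION_ONLY,
    )
    cfg_em = OpticsConfig(
        excitation_wavelength=excitation_wavelength,
        detection_center=detection_wavelength,
        detection_bandwidth=detection_bandwidth,
        refractive_index=refractive_index,
        detection_mode=DetectionMode.EMISSION_ONLY,
    )
    seeds = np.random.SeedSequence(noise.seed).spawn(2)
    noise_ex = NoiseModel(
        noise.photon_scale,
        noise.read_noise_sd,
        noise.background,
        seed=int(seeds[0].generate_state(1)[0] % (2**31)),
        enabled=noise.enabled,
    )
    noise_em = NoiseModel(
        noise.photon_scale,
        noise.read_noise_sd,
        noise.background,
        seed=int(seeds[1].generate_state(1)[0] % (2**31)),
        enabled=noise.enabled,
    )
    img_ex = render_monolayer_image(surface, cfg_ex, noise_ex, blur_sigma)
    img_em = render_monolayer_image(surface, cfg_em, noise_em, blur_sigma)
    diff = subtract_images(img_ex, img_em)
    return img_ex, img_em, diff


def subtract_images(a: FringeImage, b: FringeImage) -> FringeImage:
    """Pixel-wise ``a - b`` clipped at 0; metadata records both parents."""
    if a.shape != b.shape:
        raise ValueError("images must have identical dimensions")
    if a.pixel_size != b.pixel_size:
        raise ValueError("images must have identical pixel size")
    data = np.clip(a.data - b.data, 0.0, None)
    return FringeImage(
        data,
        a.pixel_size,
        metadata={
            "kind": "difference",
            "minuend": a.metadata,
            "subtrahend": b.metadata,
        },
    )
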