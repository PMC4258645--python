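"""Closed-form optics of standing-wave excitation above a plane mirror.

A beam reflected at normal incidence from a mirror interferes with itself
and forms a stationary ``sin**2`` axial intensity pattern.  A perfect
mirror imposes a pi phase shift on reflection, so the mirror surface is
the first *node*; antinodes sit at heights ``(2k+1) * lambda / (4n)`` and
are spaced ``lambda / (2n)`` apart (all wavelengths in vacuo, ``n`` the
refractive index of the medium between fluorophore and mirror).

Fluorescence emitted near the mirror also self-interferes (direct and
reflected emission), producing fringes at the *emission* wavelength even
when the excitation standing wave is suppressed.  When both modulations
are present the detected fluorescence carries a moire beat between the
two spatial frequencies, with period ``1/L = 1/lambda_ex - 1/lambda_em``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionMode",
    "OpticsConfig",
    "antinode_spacing",
    "axial_fwhm",
    "moire_period",
    "detected_intensity",
]


class DetectionMode(str, enum.Enum):
    """How the fluorescence signal is spectrally detected.

    ``broadband_excitation_only``
        Wide detection band; only the excitation standing wave modulates
        the signal: ``I(z) = sin^2(2 pi n z / lambda_ex)``.
    ``emission_only``
        The excitation standing wave is suppressed (e.g. a notch mirror
        that reflects only the emission); the signal is the emission
        self-interference averaged over the detection band.
    ``narrowband_moire``
        Both modulations present; narrow detection band makes the moire
        beat between excitation and emission periods visible.
    """

    BROADBAND_EXCITATION_ONLY = "broadband_excitation_only"
    EMISSION_ONLY = "emission_only"
    NARROWBAND_MOIRE = "narrowband_moire"


# number of midpoint quadrature nodes across the detection band
_BAND_QUADRATURE_POINTS = 21


@dataclass(frozen=True)
class OpticsConfig:
    """Excitation/detection settings of the standing-wave experiment.

    Parameters
    ----------
    excitation_wavelength : float
        Excitation wavelength in nm (in vacuo).
    detection_center : float
        Centre of the detection band in nm.  Must exceed the excitation
        wavelength (Stokes shift) in the two emission-sensitive modes.
    detection_bandwidth : float
        Full width of the (flat) detection band in nm; 0 means a single
        spectral line.
    refractive_index : float
        Refractive index of the medium between fluorophore and mirror.
    detection_mode : DetectionMode
    """

    excitation_wavelength: float
    detection_center: float = 0.0
    detection_bandwidth: float = 0.0
    refractive_index: float = 1.0
    detection_mode: DetectionMode = DetectionMode.BROADBAND_EXCITATION_ONLY

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "detection_mode", DetectionMode(self.detection_mode)
        )
        if self.excitation_wavelength <= 0:
            raise ValueError("excitation_wavelength must be positive")
        if self.detection_bandwidth < 0:
            raise ValueError("detection_bandwidth must be non-negative")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.detection_mode in (
            DetectionMode.EMISSION_ONLY,
            DetectionMode.NARROWBAND_MOIRE,
        ):
            if self.detection_center <= self.excitation_wavelength:
                raise ValueError(
                    "detection_center must exceed excitation_wavelength "
                    f"(Stokes shift) in mode {self.detection_mode.value}"
                )
            half = self.detection_bandwidth / 2
            if self.detection_center - half <= 0:
                raise ValueError("detection band extends to non-positive wavelengths")

    def to_dict(self) -> dict:
        return {
            "excitation_nm": self.excitation_wavelength,
            "detection_center_nm": self.detection_center,
            "detection_bandwidth_nm": self.detection_bandwidth,
            "refractive_index": self.refractive_index,
            "mode": self.detection_mode.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        return cls(
            excitation_wavelength=float(d["excitation_nm"]),
            detection_center=float(d.get("detection_center_nm", 0.0)),
            detection_bandwidth=float(d.get("detection_bandwidth_nm", 0.0)),
            refractive_index=float(d["refractive_index"]),
            detection_mode=DetectionMode(
                d.get("mode", DetectionMode.BROADBAND_EXCITATION_ONLY)
            ),
        )


def antinode_spacing(cfg: OpticsConfig) -> float:
    """Axial spacing lambda/(2n) between adjacent antinodes, in nm."""
    return cfg.excitation_wavelength / (2.0 * cfg.refractive_index)


def axial_fwhm(cfg: OpticsConfig) -> float:
    """Full width at half maximum lambda/(4n) of one sin^2 antinodal peak, nm.

    This is the axial resolution of standing-wave excitation: the
    half-maximum points of ``sin^2`` sit a quarter period either side of
    the antinode.
    """
    return cfg.excitation_wavelength / (4.0 * cfg.refractive_index)


def moire_period(excitation_wavelength: float, emission_wavelength: float) -> float:
    """Moire beat period ``L`` from ``1/L = 1/lambda_ex - 1/lambda_em``, nm.

    The beat observed along *height* above the mirror has period
    ``L / (2n)``; this function returns ``L`` itself (a wavelength-domain
    quantity, independent of the medium).

    Raises
    ------
    ValueError
        If the wavelengths are equal (the period diverges) or the
        emission wavelength is not longer than the excitation one.
    """
    if excitation_wavelength <= 0:
        raise ValueError("excitation_wavelength must be positive")
    if emission_wavelength == excitation_wavelength:
        raise ValueError(
            "moire period diverges for equal excitation and emission wavelengths"
        )
    if emission_wavelength < excitation_wavelength:
        raise ValueError(
            "emission_wavelength must exceed excitation_wavelength (Stokes shift)"
        )
    return (
        excitation_wavelength
        * emission_wavelength
        / (emission_wavelength - excitation_wavelength)
    )


def _band_wavelengths(cfg: OpticsConfig) -> np.ndarray:
    """Midpoint quadrature nodes across the flat detection band."""
    if cfg.detection_bandwidth == 0:
        return np.array([cfg.detection_center])
    m = _BAND_QUADRATURE_POINTS
    half = cfg.detection_bandwidth / 2.0
    edges = np.linspace(-half, half, m + 1)
    return cfg.detection_center + 0.5 * (edges[:-1] + edges[1:])


def detected_intensity(z, cfg: OpticsConfig):
    """Relative detected fluorescence intensity at height(s) ``z`` (nm).

    Mode-dependent:

    * ``broadband_excitation_only`` -- excitation standing wave only,
      ``sin^2(2 pi n z / lambda_ex)``.
    * ``emission_only`` -- emission self-interference averaged over a
      flat detection band (no excitation modulation).
    * ``narrowband_moire`` -- product of the excitation factor and the
      band-averaged emission factor; its amplitude envelope along z
      beats with period ``moire_period(...) / (2n)``.

    All values lie in ``[0, 1]`` and vanish at the mirror (``z = 0``),
    the first node of every standing wave.

    Parameters
    ----------
    z : float or ndarray
        Height(s) above the mirror in nm, ``>= 0``.
    cfg : OpticsConfig
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("height z above the mirror must be non-negative")
    n = cfg.refractive_index

    def excitation_factor():
        return np.sin(2.0 * np.pi * n * z[..., None] / cfg.excitation_wavelength) ** 2

    def emission_factor():
        lams = _band_wavelengths(cfg)
        return np.sin(2.0 * np.pi * n * z[..., None] / lams) ** 2

    mode = cfg.detection_mode
    if mode is DetectionMode.BROADBAND_EXCITATION_ONLY:
        out = np.sin(2.0 * np.pi * n * z / cfg.excitation_wavelength) ** 2
    elif mode is DetectionMode.EMISSION_ONLY:
        out = emission_factor().mean(axis=-1)
    else:  # NARROWBAND_MOIRE
        out = (excitation_factor() * emission_factor()).mean(axis=-1)
    if out.ndim == 0:
        return float(out)
    return out
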