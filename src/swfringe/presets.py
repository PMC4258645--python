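"""Reference fixtures reproducing the study conditions of the experiments.

The default spherical-cap fixture mirrors the monolayer-on-lens
experiment in air: 514 nm excitation, n = 1, a lens of R = 30 mm, and a
field of view sized so the cap surface spans exactly 37 antinodes
(height 37 * lambda/2n = 9.509 um at the field edge, a node).  The
discocyte fixture mirrors the red-cell experiments: 488 nm excitation
in aqueous mountant (n = 1.34), a 7.8 um biconcave cell on the mirror.

Images default to 512 x 512 (the experiments used 2048 x 2048; the
fixture keeps the same field geometry at reduced sampling so full
analyses run in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .geometry import (
    MM,
    UM,
    DiscocyteSpecimen,
    HeightMap,
    SphericalCapSpecimen,
    discocyte_surfaces,
    spherical_cap_height,
    spherical_cap_radius,
)
from .imaging import (
    FringeImage,
    NoiseModel,
    render_membrane_image,
    render_monolayer_image,
)
from .optics import DetectionMode, OpticsConfig, antinode_spacing

__all__ = [
    "cap_optics",
    "cap_specimen",
    "cap_surface",
    "cap_fixture",
    "discocyte_optics",
    "discocyte_fixture",
]

DEFAULT_SIZE = 512
DEFAULT_N_ANTINODES = 37
DEFAULT_CAP_R = 30.0 * MM


def cap_optics(
    mode: DetectionMode | str = DetectionMode.BROADBAND_EXCITATION_ONLY,
    detection_center: float = 580.0,
    detection_bandwidth: float = 5.0,
) -> OpticsConfig:
    """514 nm excitation in air; narrowband detection options for moire."""
    mode = DetectionMode(mode)
    if mode is DetectionMode.BROADBAND_EXCITATION_ONLY:
        return OpticsConfig(514.0, refractive_index=1.0, detection_mode=mode)
    return OpticsConfig(
        514.0,
        detection_center=detection_center,
        detection_bandwidth=detection_bandwidth,
        refractive_index=1.0,
        detection_mode=mode,
    )


def cap_specimen(
    cfg: Optional[OpticsConfig] = None,
    radius_of_curvature: float = DEFAULT_CAP_R,
    n_antinodes: int = DEFAULT_N_ANTINODES,
    size: int = DEFAULT_SIZE,
) -> Tuple[SphericalCapSpecimen, float]:
    """Cap specimen and pixel size for a field spanning ``n_antinodes``.

    The field radius is chosen so the cap height at the edge of the
    radial profile (the inscribed circle of the square image) equals
    ``n_antinodes * lambda / (2n)`` -- a node, so exactly
    ``n_antinodes`` antinodes intersect the profiled surface.  Returns
    the specimen (contact point at the image centre) and the pixel size
    in nm.
    """
    cfg = cfg or cap_optics()
    edge_height = n_antinodes * antinode_spacing(cfg)
    spec0 = SphericalCapSpecimen(radius_of_curvature)
    field_radius = spherical_cap_radius(edge_height, spec0)
    # the outermost profiled radius is (size/2 - 0.5) pixels from centre
    pixel_size = field_radius / (size / 2.0 - 0.5)
    center = (size / 2.0) * pixel_size  # physical position of pixel (size-1)/2 + 0.5
    spec = SphericalCapSpecimen(
        radius_of_curvature,
        contact_center=(center, center),
        max_field_radius=field_radius,
    )
    return spec, pixel_size


def cap_surface(
    spec: SphericalCapSpecimen, pixel_size: float, size: int = DEFAULT_SIZE
) -> HeightMap:
    """Height map of the cap over the square pixel grid (corners included)."""
    x = (np.arange(size) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx - spec.contact_center[0], yy - spec.contact_center[1])
    z = spherical_cap_height(r, spec)
    return HeightMap(z, pixel_size)


def cap_fixture(
    mode: DetectionMode | str = DetectionMode.BROADBAND_EXCITATION_ONLY,
    seed: int = 0,
    photon_scale: float = 500.0,
    background: float = 5.0,
    noisy: bool = True,
    size: int = DEFAULT_SIZE,
    n_antinodes: int = DEFAULT_N_ANTINODES,
    radius_of_curvature: float = DEFAULT_CAP_R,
) -> Tuple[FringeImage, HeightMap, SphericalCapSpecimen, OpticsConfig]:
    """Render the reference spherical-cap fringe image.

    Returns ``(image, ground-truth height map, specimen, optics)``.
    ``noisy=False`` renders the expected (noise-free) counts with zero
    background.
    """
    cfg = cap_optics(mode)
    spec, pixel_size = cap_specimen(cfg, radius_of_curvature, n_antinodes, size)
    surface = cap_surface(spec, pixel_size, size)
    if noisy:
        noise = NoiseModel(photon_scale=photon_scale, background=background, seed=seed)
    else:
        noise = NoiseModel.noiseless(photon_scale=photon_scale)
    img = render_monolayer_image(surface, cfg, noise)
    img.metadata["specimen"] = {
        "kind": "spherical_cap",
        "radius_of_curvature_nm": spec.radius_of_curvature,
        "contact_center_nm": list(spec.contact_center),
        "max_field_radius_nm": spec.max_field_radius,
        "n_antinodes": n_antinodes,
    }
    return img, surface, spec, cfg


def discocyte_optics() -> OpticsConfig:
    """488 nm excitation in aqueous mountant (n = 1.34), broadband."""
    return OpticsConfig(488.0, refractive_index=1.34)


def discocyte_fixture(
    seed: int = 0,
    photon_scale: float = 500.0,
    background: float = 5.0,
    noisy: bool = True,
    size: int = 256,
    pixel_size: float = 40.0,
    mirror_present: bool = True,
    spec: Optional[DiscocyteSpecimen] = None,
) -> Tuple[FringeImage, HeightMap, HeightMap, DiscocyteSpecimen, OpticsConfig]:
    """Render the reference discocyte membrane image.

    A 7.8 um biconcave red cell centred in a ~10 um field at 40 nm
    pixels, imaged at 488 nm in n = 1.34 mountant.  Returns
    ``(image, upper, lower, specimen, optics)``.
    """
    cfg = discocyte_optics()
    center = (size / 2.0) * pixel_size
    if spec is None:
        spec = DiscocyteSpecimen(center=(center, center))
    upper, lower = discocyte_surfaces(spec, (size, size), pixel_size)
    if noisy:
        noise = NoiseModel(photon_scale=photon_scale, background=background, seed=seed)
    else:
        noise = NoiseModel.noiseless(photon_scale=photon_scale)
    img = render_membrane_image(
        upper, lower, cfg, noise, mirror_present=mirror_present
    )
    img.metadata["specimen"] = {
        "kind": "discocyte",
        "diameter_nm": spec.diameter,
        "center_thickness_nm": spec.center_thickness,
        "rim_thickness_nm": spec.rim_thickness,
        "standoff_nm": spec.standoff,
        "center_nm": list(spec.center),
        "tilt_rad": list(spec.tilt),
    }
    return img, upper, lower, spec, cfg
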