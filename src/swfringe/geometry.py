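"""Parametric specimen surfaces and the fringe-radius/height geometry.

Two model specimens are provided:

* a spherical cap -- a planoconvex lens of large radius of curvature
  ``R`` resting on the mirror, carrying a fluorescent monolayer.  A
  point at lateral radius ``r`` from the contact point sits at height
  ``L = R - sqrt(R^2 - r^2)`` above the mirror (Pythagoras on the median
  section), so the evenly spaced standing-wave antinodes map to
  concentric bright fringes whose radial spacing shrinks outward;

* a discocyte -- the normal biconcave red-blood-cell shape, a thin
  membrane shell ~7-8 um across, ~1 um thick at the dimple and ~2.5 um
  at the rim, sitting just above the mirror.

Heights are in nm above the mirror; lateral coordinates are physical nm
with the origin at the image corner and values at pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "SphericalCapSpecimen",
    "DiscocyteSpecimen",
    "HeightMap",
    "spherical_cap_height",
    "spherical_cap_radius",
    "fringe_height_separation",
    "biconcave_thickness_coefficients",
    "biconcave_thickness",
    "discocyte_surfaces",
]

MM = 1.0e6  # nm per mm
UM = 1.0e3  # nm per um


@dataclass(frozen=True)
class SphericalCapSpecimen:
    """Spherical cap (planoconvex lens) touching the mirror at one point.

    Parameters
    ----------
    radius_of_curvature : float
        Sphere radius R in nm (lenses used with this geometry have R of
        tens of mm, i.e. ~1e7 nm).
    contact_center : (float, float)
        (x, y) of the contact point in the image plane, nm.
    max_field_radius : float
        Largest lateral radius of interest, nm; must not exceed R.
    """

    radius_of_curvature: float
    contact_center: Tuple[float, float] = (0.0, 0.0)
    max_field_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.radius_of_curvature <= 0:
            raise ValueError("radius_of_curvature must be positive")
        if (
            self.max_field_radius is not None
            and self.max_field_radius > self.radius_of_curvature
        ):
            raise ValueError("max_field_radius must not exceed radius_of_curvature")


@dataclass(frozen=True)
class DiscocyteSpecimen:
    """Biconcave red-blood-cell membrane shell above the mirror.

    Defaults follow the dimensions of a normal mouse discocyte:
    diameter 7.8 um, 1 um thick at the central dimple, 2.5 um at the
    rim.  ``standoff`` is the gap between the mirror and the lowest
    point of the lower membrane (0 for a cell settled on the mirror).
    ``tilt`` is a small-angle (about-x, about-y) pair in radians.
    """

    diameter: float = 7.8 * UM
    center_thickness: float = 1.0 * UM
    rim_thickness: float = 2.5 * UM
    standoff: float = 0.0
    center: Tuple[float, float] = (0.0, 0.0)
    tilt: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 < self.center_thickness < self.rim_thickness):
            raise ValueError("require 0 < center_thickness < rim_thickness")
        if not (4 * UM <= self.diameter <= 12 * UM):
            raise ValueError("diameter outside the plausible red-cell range 4-12 um")
        if self.standoff < 0:
            raise ValueError("standoff must be non-negative")


@dataclass
class HeightMap:
    """Gridded surface height z(x, y) above the mirror.

    ``data`` holds heights in nm (NaN where the surface is undefined,
    e.g. outside a cell footprint); ``pixel_size`` is nm per pixel.
    Pixel centres: physical position of pixel (i, j) is
    ``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)`` (x along
    columns, y along rows), origin at the image corner.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("HeightMap data must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.data[np.isfinite(self.data)] < 0):
            raise ValueError("heights above the mirror must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of defined pixels."""
        return np.isfinite(self.data)

    def pixel_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate grids of the pixel centres, nm."""
        ny, nx = self.data.shape
        x = (np.arange(nx) + 0.5) * self.pixel_size
        y = (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


def spherical_cap_height(r, spec: SphericalCapSpecimen):
    """Height ``R - sqrt(R^2 - r^2)`` of the cap surface at lateral radius r.

    Strictly increasing in r; ~``r^2 / (2R)`` for small r; equals R at
    the sphere equator.  Raises for r outside [0, R].
    """
    r = np.asarray(r, dtype=float)
    R = spec.radius_of_curvature
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    if np.any(r > R):
        raise ValueError("radius exceeds the radius of curvature")
    # algebraically R - sqrt(R^2 - r^2); this form avoids cancellation
    # for r << R (fringe heights are ~1e-4 of R)
    out = r**2 / (R + np.sqrt((R - r) * (R + r)))
    return float(out) if out.ndim == 0 else out


def spherical_cap_radius(z, spec: SphericalCapSpecimen):
    """Inverse of :func:`spherical_cap_height`: lateral radius at height z."""
    z = np.asarray(z, dtype=float)
    R = spec.radius_of_curvature
    if np.any(z < 0) or np.any(z > R):
        raise ValueError("height must lie in [0, R]")
    out = np.sqrt(z * (2.0 * R - z))
    return float(out) if out.ndim == 0 else out


def fringe_height_separation(r1: float, r2: float, spec: SphericalCapSpecimen) -> float:
    """Height difference between two fringes of radii r1 > r2 on the cap.

    Equals ``sqrt(R^2 - r2^2) - sqrt(R^2 - r1^2)``, the separation of
    two successive bright fringes obtained from the two right triangles
    the radii form with the sphere centre.
    """
    if not (r1 > r2 >= 0):
        raise ValueError("require r1 > r2 >= 0")
    return spherical_cap_height(r1, spec) - spherical_cap_height(r2, spec)


def biconcave_thickness_coefficients(
    center_thickness: float,
    rim_thickness: float,
    rim_position: float = 0.85,
) -> Tuple[float, float, float]:
    """Solve (C0, C2, C4) of the biconcave thickness profile.

    The profile family is ``T(rho) = sqrt(1 - rho^2) (C0 + C2 rho^2 +
    C4 rho^4)`` with ``rho = 2 r / diameter`` -- the standard smooth
    quartic-in-rho^2 description of the discocyte.  Only two thickness
    values are constrained (centre and rim maximum), so the remaining
    degree of freedom is closed by fixing the location of the thickness
    maximum at ``rho* = rim_position``; ``T(rho*) = rim_thickness`` and
    ``T'(rho*) = 0`` then give a 2x2 linear system for C2, C4.

    Raises
    ------
    ValueError
        If the resulting profile is not positive on (0, 1) or its
        stationary point at ``rho*`` is not the global maximum
        (incompatible thickness constraints).
    """
    if not (0 < rim_position < 1):
        raise ValueError("rim_position must lie in (0, 1)")
    c0 = center_thickness
    a = rim_position**2
    s = np.sqrt(1.0 - a)
    t = rim_thickness / s  # = C0 + C2 a + C4 a^2
    # T'(rho*) = 0  =>  (1 - a)(2 C2 + 4 C4 a) = C0 + C2 a + C4 a^2 = t
    A = np.array([[a, a**2], [2.0 * (1.0 - a), 4.0 * a * (1.0 - a)]])
    b = np.array([t - c0, t])
    c2, c4 = np.linalg.solve(A, b)

    rho = np.linspace(0.0, 1.0, 2001)
    prof = np.sqrt(1.0 - rho**2) * (c0 + c2 * rho**2 + c4 * rho**4)
    if np.any(prof[:-1] <= 0):
        raise ValueError("incompatible thickness constraints: profile non-positive")
    if abs(prof.max() - rim_thickness) > 1e-6 * rim_thickness:
        raise ValueError(
            "incompatible thickness constraints: rim stationary point is not "
            "the thickness maximum"
        )
    return float(c0), float(c2), float(c4)


def biconcave_thickness(r, spec: DiscocyteSpecimen):
    """Membrane-to-membrane thickness T at lateral radius r (nm), NaN outside."""
    c0, c2, c4 = biconcave_thickness_coefficients(
        spec.center_thickness, spec.rim_thickness
    )
    rho = 2.0 * np.asarray(r, dtype=float) / spec.diameter
    inside = rho <= 1.0
    rho_c = np.where(inside, rho, 0.0)
    t = np.sqrt(1.0 - rho_c**2) * (c0 + c2 * rho_c**2 + c4 * rho_c**4)
    out = np.where(inside, t, np.nan)
    return float(out) if out.ndim == 0 else out


def discocyte_surfaces(
    spec: DiscocyteSpecimen,
    shape: Tuple[int, int],
    pixel_size: float,
) -> Tuple[HeightMap, HeightMap]:
    """Upper and lower membrane height maps of a discocyte on a grid.

    The midplane sits at ``standoff + rim_thickness / 2`` so the lowest
    point of the (untilted) lower membrane touches ``standoff``; upper
    and lower surfaces are ``midplane +/- T/2`` with a small-angle tilt
    ``z += tx * (y - yc) + ty * (x - xc)`` applied to both.  Outside the
    cell footprint both maps are NaN.
    """
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, y)
    xc, yc = spec.center
    r = np.hypot(xx - xc, yy - yc)

    t = biconcave_thickness(r, spec)
    midplane = spec.standoff + spec.rim_thickness / 2.0
    tx, ty = spec.tilt
    tilt_plane = tx * (yy - yc) + ty * (xx - xc)
    upper = midplane + t / 2.0 + tilt_plane
    lower = midplane - t / 2.0 + tilt_plane
    if np.nanmin(lower) < 0:
        raise ValueError("tilt/standoff push the lower membrane below the mirror")
    return HeightMap(upper, pixel_size), HeightMap(lower, pixel_size)
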