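"""Fringe-image measurement chain.

Turns a 2D concentric-fringe image into physical axial quantities:

1. locate the centre of radial symmetry (the specimen/mirror contact
   point, which is dark -- the mirror is the first node);
2. azimuthally average into a radial intensity profile;
3. detect the fringe peaks and refine each to sub-bin precision;
4. map peak radii to heights above the mirror through the spherical-cap
   geometry ``z = R - sqrt(R^2 - r^2)``;
5. estimate the antinodal spacing (vs the theoretical ``lambda/2n``)
   and, for narrowband detection, the moire beat period of the
   peak-amplitude envelope (vs ``L/2n``).

Peak refinement mirrors the original measurement procedure: the profile
is interpolated, negated, and minimised within a bracket around each
detected sample maximum (bounded scalar minimisation of the flipped
function).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import interpolate, optimize, signal

from .errors import CenterNotFoundError, EnvelopeNotFoundError, NoPeaksFoundError
from .geometry import SphericalCapSpecimen, spherical_cap_height
from .imaging import FringeImage, subtract_images  # re-export: image algebra
from .optics import OpticsConfig, antinode_spacing

__all__ = [
    "RadialProfile",
    "FringePeakSet",
    "find_fringe_center",
    "radial_profile",
    "detect_peaks",
    "radii_to_heights",
    "estimate_spacing",
    "estimate_spacing_differences",
    "estimate_envelope_period",
    "subtract_images",
    "analyze_cap_image",
    "CapAnalysisReport",
]


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity versus radial distance.

    ``radii`` are annulus-centre radii in nm (strictly increasing),
    ``intensities`` the mean counts in each annulus, ``bin_width`` the
    annulus width in nm, ``center`` the (x, y) image position used, nm.
    """

    radii: np.ndarray
    intensities: np.ndarray
    bin_width: float
    center: Tuple[float, float]

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.radii.shape != self.intensities.shape or self.radii.ndim != 1:
            raise ValueError("radii and intensities must be equal-length 1D arrays")
        if len(self.radii) and np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class FringePeakSet:
    """Refined fringe peaks: radii, optional heights, amplitudes, indices.

    ``peak_radii`` nm (strictly increasing, sub-bin refined);
    ``peak_heights_z`` nm above the mirror (NaN until assigned);
    ``peak_amplitudes`` interpolated profile value at the refined
    radius; ``antinode_index`` integer antinode numbers (-1 until
    assigned).
    """

    peak_radii: np.ndarray
    peak_amplitudes: np.ndarray
    peak_heights_z: np.ndarray = None  # type: ignore[assignment]
    antinode_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_radii = np.asarray(self.peak_radii, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_heights_z is None:
            self.peak_heights_z = np.full_like(self.peak_radii, np.nan)
        else:
            self.peak_heights_z = np.asarray(self.peak_heights_z, dtype=float)
        if self.antinode_index is None:
            self.antinode_index = np.full(self.peak_radii.shape, -1, dtype=int)
        else:
            self.antinode_index = np.asarray(self.antinode_index, dtype=int)
        if np.any(np.diff(self.peak_radii) <= 0):
            raise ValueError("peak radii must be strictly increasing")
        z = self.peak_heights_z
        if np.all(np.isfinite(z)) and len(z) > 1 and np.any(np.diff(z) <= 0):
            raise ValueError("peak heights must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_radii)

    @property
    def has_heights(self) -> bool:
        return bool(np.all(np.isfinite(self.peak_heights_z)))


# ---------------------------------------------------------------------------
# centre finding


def _symmetry_score(
    data: np.ndarray, cx: float, cy: float, bin_width: float
) -> float:
    """Fraction of image variance explained by the radial binning at (cx, cy).

    For the true centre of a concentric pattern almost all structure is
    radial, so the between-annulus variance approaches the total
    variance; for a wrong centre or a structureless image it is small.
    """
    ny, nx = data.shape
    x = (np.arange(nx) + 0.5)[None, :]
    y = (np.arange(ny) + 0.5)[:, None]
    r = np.hypot(x - cx, y - cy)
    idx = (r / bin_width).astype(np.int64).ravel()
    v = data.ravel()
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=v)
    keep = counts > 0
    means = sums[keep] / counts[keep]
    grand = v.mean()
    between = np.sum(counts[keep] * (means - grand) ** 2)
    total = np.sum((v - grand) ** 2)
    if total == 0:
        return 0.0
    return float(between / total)


def find_fringe_center(
    img: FringeImage,
    score_threshold: float = 0.1,
) -> Tuple[float, float]:
    """Sub-pixel centre of radial symmetry of a concentric fringe pattern.

    Maximises the azimuthal-symmetry score (fraction of image variance
    explained by annular means) by hierarchical grid search: a coarse
    pass on a block-averaged image over all candidate positions, then
    local searches at full resolution with step refined down to 1/8
    pixel.  Returns the centre in pixel coordinates (x, y), where
    (0, 0) is the centre of the corner pixel.

    Raises
    ------
    CenterNotFoundError
        If the best score stays below ``score_threshold`` (no
        radially symmetric structure, e.g. a uniform image).
    """
    data = img.data.astype(float)

    # coarse pass on an 8x block-averaged image
    ds = 8
    ny, nx = data.shape
    small = data[: ny - ny % ds, : nx - nx % ds]
    small = small.reshape(ny // ds, ds, nx // ds, ds).mean(axis=(1, 3))
    sny, snx = small.shape
    best, best_c = -1.0, (snx / 2.0, sny / 2.0)
    for cy in np.arange(0.5, sny, 1.0):
        for cx in np.arange(0.5, snx, 1.0):
            s = _symmetry_score(small, cx, cy, 1.0)
            if s > best:
                best, best_c = s, (cx, cy)

    # refine at full resolution; candidate coordinates are pixel-centre
    # based: small-image coord c maps to full-image ds*c - 0.5 offset
    cx = best_c[0] * ds - 0.5
    cy = best_c[1] * ds - 0.5
    step = float(ds)
    best = _symmetry_score(data, cx + 0.5, cy + 0.5, 1.0)
    while step >= 0.125:
        step /= 2.0
        improved = True
        while improved:
            improved = False
            for dx, dy in ((step, 0), (-step, 0), (0, step), (0, -step),
                           (step, step), (step, -step), (-step, step), (-step, -step)):
                s = _symmetry_score(data, cx + dx + 0.5, cy + dy + 0.5, 1.0)
                if s > best:
                    best, cx, cy, improved = s, cx + dx, cy + dy, True

    if best < score_threshold:
        raise CenterNotFoundError(
            f"no radially symmetric structure found (score {best:.3f} "
            f"< threshold {score_threshold})"
        )
    return float(cx), float(cy)


# ---------------------------------------------------------------------------
# radial profiling


def radial_profile(
    img: FringeImage,
    center: Tuple[float, float],
    bin_width: Optional[float] = None,
    max_radius: Optional[float] = None,
) -> RadialProfile:
    """Azimuthal mean intensity in annular bins around ``center``.

    ``center`` is in pixel coordinates (x, y); ``bin_width`` in nm
    (default: one pixel) must be at least the pixel size.
    ``max_radius`` (nm) defaults to the distance from the centre to the
    nearest image edge, so only complete annuli (no corner fragments)
    enter the profile.  Empty bins are dropped.
    """
    if bin_width is None:
        bin_width = img.pixel_size
    if bin_width < img.pixel_size:
        raise ValueError("bin_width must be at least the pixel size")
    ny, nx = img.shape
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError("center must lie inside the image")
    if max_radius is None:
        max_radius = img.pixel_size * min(cx, cy, nx - 1 - cx, ny - 1 - cy)

    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    r = np.hypot(x - cx, y - cy) * img.pixel_size
    sel = (r <= max_radius).ravel()
    idx = (r.ravel()[sel] / bin_width).astype(np.int64)
    v = img.data.ravel()[sel]
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=v)
    keep = counts > 0
    radii = (np.nonzero(keep)[0] + 0.5) * bin_width
    means = sums[keep] / counts[keep]
    return RadialProfile(radii, means, bin_width, (cx, cy))


def ray_profile(
    img: FringeImage,
    center: Tuple[float, float],
    angle: float = 0.0,
    step: Optional[float] = None,
) -> RadialProfile:
    """Intensity along a single radial ray (no azimuthal averaging).

    Higher-fidelity but noisier alternative to :func:`radial_profile`;
    samples the image by linear interpolation at ``step`` nm intervals
    (default one pixel) along direction ``angle`` (radians) until the
    image edge.
    """
    from scipy.ndimage import map_coordinates

    if step is None:
        step = img.pixel_size
    ny, nx = img.shape
    cx, cy = center
    dx, dy = np.cos(angle), np.sin(angle)
    tmax_x = ((nx - 1 - cx) / dx if dx > 0 else (-cx / dx)) if dx != 0 else np.inf
    tmax_y = ((ny - 1 - cy) / dy if dy > 0 else (-cy / dy)) if dy != 0 else np.inf
    tmax = min(tmax_x, tmax_y) * img.pixel_size
    radii = np.arange(step / 2.0, tmax, step)
    t = radii / img.pixel_size
    coords = np.vstack([cy + t * dy, cx + t * dx])
    vals = map_coordinates(img.data, coords, order=1)
    return RadialProfile(radii, vals, step, (cx, cy))


# ---------------------------------------------------------------------------
# peak detection and refinement


def _refine_maximum(
    x: np.ndarray, y: np.ndarray, i: int, halfwidth: float
) -> Tuple[float, float]:
    """Refine the sample maximum at index i by bounded minimisation of the
    negated cubic-interpolated signal within +-halfwidth of x[i]."""
    lo = max(0, i - 4)
    hi = min(len(x), i + 5)
    if hi - lo < 4:  # cubic needs 4 points; fall back to the sample
        return float(x[i]), float(y[i])
    spline = interpolate.CubicSpline(x[lo:hi], y[lo:hi])
    a = max(x[lo], x[i] - halfwidth)
    b = min(x[hi - 1], x[i] + halfwidth)
    res = optimize.minimize_scalar(
        lambda t: -spline(t), bounds=(a, b), method="bounded",
        options={"xatol": 1e-4 * halfwidth},
    )
    xr = float(res.x)
    return xr, float(spline(xr))


def detect_peaks(
    profile: RadialProfile,
    min_prominence: float = 0.1,
    min_separation: Optional[float] = None,
) -> FringePeakSet:
    """Detect and sub-bin-refine the fringe peaks of a radial profile.

    Local maxima with prominence at least ``min_prominence`` times the
    profile's intensity range and mutual separation at least
    ``min_separation`` nm (default: two bins) are detected, then each
    is refined by bounded scalar minimisation of the negated
    cubic-interpolated profile within one bin either side of the sample
    maximum.  Returns radii and amplitudes; heights are filled later by
    :func:`radii_to_heights`.
    """
    r, v = profile.radii, profile.intensities
    if len(r) < 3:
        raise ValueError("profile must have at least 3 samples")
    if min_separation is None:
        min_separation = 2.0 * profile.bin_width
    rng_v = float(v.max() - v.min())
    if rng_v == 0:
        raise NoPeaksFoundError("profile is constant; no peaks")
    distance = max(1, int(round(min_separation / profile.bin_width)))
    idx, _ = signal.find_peaks(
        v, prominence=min_prominence * rng_v, distance=distance
    )
    if len(idx) == 0:
        raise NoPeaksFoundError("no peaks above the prominence threshold")
    radii = np.empty(len(idx))
    amps = np.empty(len(idx))
    for k, i in enumerate(idx):
        radii[k], amps[k] = _refine_maximum(r, v, i, profile.bin_width)
    order = np.argsort(radii)
    return FringePeakSet(radii[order], amps[order])


def radii_to_heights(
    peaks: FringePeakSet, spec: SphericalCapSpecimen
) -> FringePeakSet:
    """Fill peak heights via the cap geometry and number the antinodes.

    ``z_i = R - sqrt(R^2 - r_i^2)``; antinode indices are assigned
    0, 1, 2, ... in order of increasing height (the innermost fringe is
    taken to cut the first antinode).
    """
    z = spherical_cap_height(peaks.peak_radii, spec)
    return FringePeakSet(
        peaks.peak_radii,
        peaks.peak_amplitudes,
        peak_heights_z=z,
        antinode_index=np.arange(len(peaks)),
    )


# ---------------------------------------------------------------------------
# spacing and envelope estimation


def estimate_spacing(peaks: FringePeakSet) -> Tuple[float, float]:
    """Antinodal spacing and its standard error by linear regression.

    Fits ``z = spacing * index + intercept`` by least squares over the
    numbered peaks and returns (slope, standard error of the slope).
    Regression uses every peak at once and is therefore less sensitive
    to noise in individual peak positions than averaging successive
    differences (see :func:`estimate_spacing_differences`).
    """
    if len(peaks) < 3 or not peaks.has_heights:
        raise ValueError("need at least 3 peaks with heights assigned")
    k = peaks.antinode_index.astype(float)
    z = peaks.peak_heights_z
    n = len(k)
    km, zm = k.mean(), z.mean()
    skk = np.sum((k - km) ** 2)
    slope = np.sum((k - km) * (z - zm)) / skk
    resid = z - (zm + slope * (k - km))
    # standard error of the regression slope
    se = np.sqrt(np.sum(resid**2) / (n - 2) / skk) if n > 2 else 0.0
    return float(slope), float(se)


def estimate_spacing_differences(peaks: FringePeakSet) -> Tuple[float, float]:
    """Antinodal spacing as mean +- sd of successive height differences."""
    if len(peaks) < 3 or not peaks.has_heights:
        raise ValueError("need at least 3 peaks with heights assigned")
    d = np.diff(peaks.peak_heights_z) / np.diff(peaks.antinode_index)
    return float(d.mean()), float(d.std(ddof=1))


def estimate_envelope_period(
    peaks: FringePeakSet,
    min_prominence: float = 0.1,
) -> float:
    """Beat period (in height, nm) of the peak-amplitude envelope.

    Under narrowband detection the fringe peak amplitudes beat along
    height with the moire period ``L / (2n)``.  Interior maxima of the
    amplitude-vs-height sequence with prominence at least
    ``min_prominence`` times the maximum amplitude are detected and
    refined by the same bounded cubic-interpolation procedure as the
    fringe peaks; the period is the mean spacing of the refined maxima.
    The wavelength-domain moire period follows as ``L = period * 2n``.

    Raises
    ------
    EnvelopeNotFoundError
        If fewer than 2 envelope maxima are present (e.g. the
        unmodulated emission-only control).
    """
    if not peaks.has_heights:
        raise ValueError("peaks must have heights assigned")
    z = peaks.peak_heights_z
    a = peaks.peak_amplitudes
    if len(z) < 5:
        raise EnvelopeNotFoundError("too few peaks to carry an envelope")
    idx, _ = signal.find_peaks(a, prominence=min_prominence * float(a.max()))
    if len(idx) < 2:
        raise EnvelopeNotFoundError(
            f"fewer than 2 envelope maxima found ({len(idx)})"
        )
    dz = float(np.median(np.diff(z)))
    zs = np.empty(len(idx))
    for k, i in enumerate(idx):
        zs[k], _ = _refine_maximum(z, a, i, dz)
    return float(np.mean(np.diff(zs)))


# ---------------------------------------------------------------------------
# end-to-end cap analysis


@dataclass
class CapAnalysisReport:
    """Result of the full measurement chain on a cap fringe image."""

    center: Tuple[float, float]
    n_peaks: int
    spacing_nm: float
    spacing_sd_nm: float
    theoretical_spacing_nm: float
    rel_error_pct: float
    envelope_L_nm: Optional[float] = None
    profile: Optional[RadialProfile] = None
    peaks: Optional[FringePeakSet] = None

    def to_dict(self) -> dict:
        d = {
            "center_px": [float(c) for c in self.center],
            "n_peaks": self.n_peaks,
            "spacing_nm": self.spacing_nm,
            "spacing_sd_nm": self.spacing_sd_nm,
            "theoretical_spacing_nm": self.theoretical_spacing_nm,
            "rel_error_pct": self.rel_error_pct,
        }
        if self.envelope_L_nm is not None:
            d["envelope_L_nm"] = self.envelope_L_nm
        return d


def analyze_cap_image(
    img: FringeImage,
    cfg: OpticsConfig,
    spec: SphericalCapSpecimen,
    bin_width: Optional[float] = None,
    min_prominence: float = 0.1,
    min_separation: Optional[float] = None,
    estimate_envelope: bool = False,
) -> CapAnalysisReport:
    """Run the full chain: centre, profile, peaks, heights, spacing (, envelope).

    ``rel_error_pct`` is ``|spacing - lambda/2n| / (lambda/2n) * 100``.
    When ``estimate_envelope`` is set, the moire period is reported as
    ``L = envelope height period * 2n``.
    """
    center = find_fringe_center(img)
    profile = radial_profile(img, center, bin_width=bin_width)
    peaks = detect_peaks(profile, min_prominence, min_separation)
    peaks = radii_to_heights(peaks, spec)
    spacing, sd = estimate_spacing(peaks)
    theory = antinode_spacing(cfg)
    rel = abs(spacing - theory) / theory * 100.0
    envelope_L = None
    if estimate_envelope:
        period = estimate_envelope_period(peaks)
        envelope_L = period * 2.0 * cfg.refractive_index
    return CapAnalysisReport(
        center=center,
        n_peaks=len(peaks),
        spacing_nm=spacing,
        spacing_sd_nm=sd,
        theoretical_spacing_nm=theory,
        rel_error_pct=rel,
        envelope_L_nm=envelope_L,
        profile=profile,
        peaks=peaks,
    )
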