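"""Contour-based 3D surface reconstruction from fringe images.

Each bright fringe marks where the dyed surface crosses a standing-wave
antinode, i.e. an iso-height contour at ``z = (2k+1) lambda / (4n)``.
Reconstruction therefore proceeds by (1) extracting fringe ridge lines
from the image, (2) ordering them by containment and assigning
consecutive antinode indices (hence heights), and (3) interpolating the
contour points onto a regular grid.

The *absolute* antinode index is not identifiable from a single
broadband image -- only index differences are; ``base_index`` selects
the offset and is recorded in the output.  Under narrowband detection
the moire amplitude envelope can rank candidate offsets (the beat phase
varies along height); see :func:`rank_base_indices_by_envelope`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from shapely.geometry import Polygon
from skimage import measure, morphology
from scipy import ndimage

from .errors import AmbiguousTopologyError
from .geometry import HeightMap
from .imaging import FringeImage
from .optics import OpticsConfig

__all__ = [
    "FringeContour",
    "ContourSet",
    "extract_fringe_contours",
    "assign_antinode_indices",
    "choose_nesting_mode",
    "interpolate_surface",
    "reconstruction_rmse",
]


@dataclass
class FringeContour:
    """One fringe ridge: an ordered (x, y) polyline in nm with metadata."""

    points: np.ndarray  # (N, 2) x, y in nm
    ridge_strength: float
    antinode_index: Optional[int] = None
    z: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")

    @property
    def mean_radius(self) -> float:
        c = self.points.mean(axis=0)
        return float(np.hypot(*(self.points - c).T).mean())


@dataclass
class ContourSet:
    """A family of fringe contours from one image."""

    contours: List[FringeContour]
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def __getitem__(self, i):
        return self.contours[i]

    @property
    def assigned(self) -> bool:
        return all(c.z is not None for c in self.contours)


def _trace_component(coords_rc: np.ndarray, pixel_size: float) -> np.ndarray:
    """Order skeleton pixels of one ring into a polyline by angle about
    the component centroid (adequate for the star-convex fringe rings
    this pipeline produces)."""
    xy = np.column_stack([coords_rc[:, 1], coords_rc[:, 0]]).astype(float)
    c = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - c[1], xy[:, 0] - c[0])
    order = np.argsort(ang)
    return (xy[order] + 0.5) * pixel_size


def _refine_ridge_points(poly_nm: np.ndarray, data: np.ndarray,
                         pixel_size: float, reach_px: float = 2.0) -> np.ndarray:
    """Shift each polyline vertex to the intensity maximum along the
    local outward direction (sub-pixel, parabolic fit).

    The skeleton of a thresholded band marks the band *midline*, which
    for radially chirped fringes is biased off the true ridge; sampling
    the image along the outward normal and fitting a parabola around the
    maximum removes that bias.
    """
    c = poly_nm.mean(axis=0)
    d = poly_nm - c
    norms = np.linalg.norm(d, axis=1)
    norms[norms == 0] = 1.0
    u = d / norms[:, None]  # outward unit vectors
    offsets = np.linspace(-reach_px, reach_px, 9)
    # sample positions: (n_points, n_offsets, 2) in pixel-centre coords
    pos = (poly_nm[:, None, :] + u[:, None, :] * offsets[None, :, None]
           * pixel_size) / pixel_size - 0.5
    vals = ndimage.map_coordinates(
        data, [pos[..., 1].ravel(), pos[..., 0].ravel()], order=3, mode="nearest"
    ).reshape(pos.shape[:2])
    i = np.argmax(vals, axis=1)
    i = np.clip(i, 1, len(offsets) - 2)
    rows = np.arange(len(poly_nm))
    a, b, cc = vals[rows, i - 1], vals[rows, i], vals[rows, i + 1]
    denom = a - 2 * b + cc
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (a - cc) / denom, 0.0)
    delta = np.clip(delta, -1.0, 1.0)
    step = offsets[1] - offsets[0]
    shift = (offsets[i] + delta * step) * pixel_size
    return poly_nm + u * shift[:, None]


def extract_fringe_contours(
    img: FringeImage,
    smoothing_sigma: float = 0.0,
    ridge_threshold: float = 0.5,
    keep_open: bool = False,
) -> ContourSet:
    """Extract bright fringe ridge lines as ordered polylines.

    The image is Gaussian-smoothed (sigma in nm), thresholded at
    ``ridge_threshold`` times its maximum, and the bright bands are
    thinned to one-pixel chains by morphological skeletonisation; each
    connected chain becomes one polyline (nm coordinates, pixel-centre
    convention).  Fragments shorter than 10 pixels are dropped, as are
    open (non-closed) chains -- typically fringes clipped by the image
    edge -- unless ``keep_open`` is set.  May return an empty set
    (e.g. for a uniform image, which has no ridge structure after
    thresholding).

    The default threshold of 0.5 picks out the full-width-at-half-
    maximum band of each sin^2 fringe, which keeps adjacent crowded
    fringes near the field edge separate.
    """
    data = img.data.astype(float)
    if smoothing_sigma > 0:
        data = ndimage.gaussian_filter(data, smoothing_sigma / img.pixel_size)
    vmax = data.max()
    span = vmax - data.min()
    if vmax <= 0 or span == 0 or span < 1e-9 * max(vmax, 1.0):
        return ContourSet([], img.pixel_size)
    mask = data >= ridge_threshold * vmax
    skel = morphology.skeletonize(mask)
    labels, nlab = ndimage.label(skel, structure=np.ones((3, 3), dtype=int))
    contours: List[FringeContour] = []
    for lab in range(1, nlab + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < 10:
            continue
        poly = _trace_component(coords, img.pixel_size)
        if not keep_open:
            gaps = np.hypot(*np.diff(np.vstack([poly, poly[:1]]), axis=0).T)
            if gaps.max() > 3.0 * img.pixel_size:  # open chain: one large gap
                continue
        poly = _refine_ridge_points(poly, data, img.pixel_size)
        strength = float(data[coords[:, 0], coords[:, 1]].mean())
        contours.append(FringeContour(poly, strength))
    contours.sort(key=lambda c: -Polygon(c.points).area if len(c.points) >= 3 else 0.0)
    return ContourSet(contours, img.pixel_size, metadata=dict(img.metadata))


def _nested_polygons(contours: Sequence[FringeContour]) -> List[Polygon]:
    polys = []
    for c in contours:
        p = Polygon(c.points)
        if not p.is_valid:
            p = p.buffer(0)
        if p.is_empty:
            raise AmbiguousTopologyError("degenerate contour polygon")
        polys.append(p)
    return polys


def assign_antinode_indices(
    contours: ContourSet,
    cfg: OpticsConfig,
    mode: str = "nested_outward",
    base_index: int = 0,
) -> ContourSet:
    """Assign consecutive antinode indices (and heights) along the nesting.

    Contours must form a strictly nested family (each contained in the
    next larger).  ``nested_outward`` numbers from the innermost contour
    outward (a bowl touching the mirror at its centre, like the cap);
    ``nested_inward`` numbers from the outermost inward (a dome).
    Heights follow ``z = (2 index + 1) lambda_ex / (4 n)``.

    Raises
    ------
    AmbiguousTopologyError
        If any pair of contours crosses (neither contains the other).
    """
    if mode not in ("nested_outward", "nested_inward"):
        raise ValueError("mode must be 'nested_outward' or 'nested_inward'")
    if base_index < 0:
        raise ValueError("base_index must be non-negative")
    cs = sorted(contours.contours, key=lambda c: Polygon(c.points).area, reverse=True)
    polys = _nested_polygons(cs)
    for outer, inner, co in zip(polys[:-1], polys[1:], cs[1:]):
        # strict nesting: each successive (smaller) contour lies inside
        # the previous; a tiny negative buffer forgives 1-px raggedness
        if not outer.buffer(1.5 * contours.pixel_size).contains(inner):
            raise AmbiguousTopologyError(
                "contours are not strictly nested (crossing or disjoint rings)"
            )
    n = len(cs)
    lam = cfg.excitation_wavelength
    ri = cfg.refractive_index
    for depth, c in enumerate(cs):  # depth 0 = outermost
        if mode == "nested_inward":
            idx = base_index + depth
        else:
            idx = base_index + (n - 1 - depth)
        c.antinode_index = idx
        c.z = (2 * idx + 1) * lam / (4.0 * ri)
    out = ContourSet(cs, contours.pixel_size, metadata=dict(contours.metadata))
    out.metadata.update(
        {
            "nesting_mode": mode,
            "base_index": base_index,
            "base_index_note": (
                "absolute antinode index is not identifiable from a single "
                "broadband image; heights are offset by base_index antinodes"
            ),
        }
    )
    return out


def choose_nesting_mode(img: FringeImage, contours: ContourSet) -> str:
    """Heuristic nesting direction from the dark-contact-point cue.

    The mirror surface is a node, so a surface touching the mirror is
    dark at the contact point: if the image centre region inside the
    innermost contour is darker than the mean ridge intensity, the
    innermost contour is the lowest antinode (``nested_outward``);
    otherwise ``nested_inward``.
    """
    if len(contours) == 0:
        raise ValueError("no contours")
    cs = sorted(contours.contours, key=lambda c: Polygon(c.points).area)
    innermost = cs[0]
    cx, cy = innermost.points.mean(axis=0) / img.pixel_size
    iy, ix = int(round(cy)), int(round(cx))
    ny, nx = img.shape
    sl = (slice(max(0, iy - 2), min(ny, iy + 3)), slice(max(0, ix - 2), min(nx, ix + 3)))
    inner_val = float(img.data[sl].mean())
    ridge_val = float(np.mean([c.ridge_strength for c in contours]))
    return "nested_outward" if inner_val < 0.5 * ridge_val else "nested_inward"


def interpolate_surface(
    contours: ContourSet,
    shape: Optional[Tuple[int, int]] = None,
    grid_pixel_size: Optional[float] = None,
) -> HeightMap:
    """Linear scatter interpolation of contour points onto a regular grid.

    Requires at least 2 contours with assigned heights.  The grid
    defaults to the source image grid (from the contour-set metadata is
    not required: ``shape``/``grid_pixel_size`` default to the contour
    bounding box at the contour set's pixel size).  Outside the convex
    hull of the contour points the surface is undefined (NaN).
    """
    assigned = [c for c in contours if c.z is not None]
    if len(assigned) < 2:
        raise ValueError("need at least 2 contours with assigned heights")
    if grid_pixel_size is None:
        grid_pixel_size = contours.pixel_size
    pts = np.vstack([c.points for c in assigned])
    vals = np.concatenate([np.full(len(c.points), c.z) for c in assigned])
    if shape is None:
        nx = int(np.ceil(pts[:, 0].max() / grid_pixel_size)) + 1
        ny = int(np.ceil(pts[:, 1].max() / grid_pixel_size)) + 1
        shape = (ny, nx)
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * grid_pixel_size
    y = (np.arange(ny) + 0.5) * grid_pixel_size
    xx, yy = np.meshgrid(x, y)
    interp = LinearNDInterpolator(pts, vals)
    z = interp(xx, yy)
    zmin, zmax = vals.min(), vals.max()
    z = np.clip(z, zmin, zmax)
    return HeightMap(z, grid_pixel_size)


def reconstruction_rmse(recon: HeightMap, truth: HeightMap) -> float:
    """Root-mean-square height difference over the shared defined mask.

    If the grids differ, the truth is resampled onto the reconstruction
    grid by bilinear interpolation (both use the corner-origin
    pixel-centre convention).
    """
    if recon.shape == truth.shape and recon.pixel_size == truth.pixel_size:
        t = truth.data
    else:
        ny, nx = truth.shape
        xt = (np.arange(nx) + 0.5) * truth.pixel_size
        yt = (np.arange(ny) + 0.5) * truth.pixel_size
        rgi = RegularGridInterpolator(
            (yt, xt), truth.data, bounds_error=False, fill_value=np.nan
        )
        ry, rx = recon.shape
        xr = (np.arange(rx) + 0.5) * recon.pixel_size
        yr = (np.arange(ry) + 0.5) * recon.pixel_size
        xx, yy = np.meshgrid(xr, yr)
        t = rgi(np.stack([yy.ravel(), xx.ravel()], axis=-1)).reshape(recon.shape)
    mask = np.isfinite(recon.data) & np.isfinite(t)
    if not mask.any():
        raise ValueError("reconstruction and truth share no defined pixels")
    d = recon.data[mask] - t[mask]
    return float(np.sqrt(np.mean(d**2)))
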