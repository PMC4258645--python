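"""Contour-based 3D reconstruction of the calibration cap surface.

Every bright fringe is an iso-height contour at an antinode height
(2k+1) * lambda/4n.  Extracting the fringe ridges, numbering them along
their nesting order and interpolating between them recovers the 3D
surface from a single 2D image; with the known synthetic ground truth
the reconstruction error can be scored directly.
"""

from swfringe import (
    antinode_spacing,
    assign_antinode_indices,
    choose_nesting_mode,
    extract_fringe_contours,
    interpolate_surface,
    reconstruction_rmse,
)
from swfringe.presets import cap_fixture

# noiseless 1024x1024 render: 37 fringes over a 1.5 mm field
image, truth, specimen, optics = cap_fixture(noisy=False, size=1024)

contours = extract_fringe_contours(image)
mode = choose_nesting_mode(image, contours)  # dark contact point => outward
contours = assign_antinode_indices(contours, optics, mode=mode, base_index=0)
surface = interpolate_surface(contours, shape=image.shape,
                              grid_pixel_size=image.pixel_size)
rmse = reconstruction_rmse(surface, truth)

print(f"extracted fringe contours: {len(contours)}")
print(f"nesting direction chosen:  {mode}")
print(f"height range assigned:     {min(c.z for c in contours):.1f} - "
      f"{max(c.z for c in contours):.1f} nm")
print(f"reconstruction RMSE vs ground truth: {rmse:.1f} nm")
print(f"(inter-antinode interpolation bound: lambda/8n = "
      f"{antinode_spacing(optics) / 4:.1f} nm)")
# RMSE well below the antinode spacing shows the contour map recovers
# the surface with sub-fringe axial precision between the antinodes.
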