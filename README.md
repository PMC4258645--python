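# swfringe

Simulation and analysis of **standing-wave-excited fluorescence fringes**
formed above a plane mirror, and their use for sub-wavelength axial
metrology and 3D contour mapping of membranes — in particular the
surface of red blood cells.

## The physics

Placing a mirror behind a fluorescent specimen makes the excitation beam
interfere with its own reflection. A perfect mirror imposes a π phase
shift, so the mirror surface is a *node* and the excitation intensity
along height z is

    I_ex(z) = sin²(2π n z / λ_ex)

with antinodes at z_k = (2k+1)·λ/4n, spaced **λ/2n** apart and each of
axial full width at half maximum **λ/4n** (≈ 91 nm for 488 nm in
n = 1.34 mountant — a ~3× improvement over ordinary confocal axial
resolution). A thin dyed surface crossing these planes lights up as a
family of fringes: each fringe is an iso-height contour of the surface.

Fluorescence *emission* near the mirror also self-interferes at its own
(Stokes-shifted) wavelength. Detected through a narrow spectral band
centred at λ_em, the fringes are amplitude-modulated by a **moiré beat**
at the difference frequency

    1/L = 1/λ_ex − 1/λ_em

(L = 4520 nm for 514/580 nm; the beat spacing in height is L/2n). The
same beat appears when the emission-only fringe pattern is subtracted
from the excitation-only pattern.

The package provides, as plain Python modules:

- `swfringe.optics` — the closed-form standing-wave model above
  (antinode spacing, axial FWHM, moiré period, mode-dependent detected
  intensity with flat-band spectral averaging);
- `swfringe.geometry` — specimen surfaces: the spherical-cap
  calibration specimen (height L = R − √(R²−r²) at lateral radius r)
  and a biconcave discocyte membrane shell (7.8 µm diameter, 1 µm
  centre / 2.5 µm rim thickness by default);
- `swfringe.imaging` — a synthetic fringe-image renderer (Poisson shot
  noise + Gaussian read noise, optional lateral blur, membrane
  foreshortening, emission-only / subtraction controls);
- `swfringe.analysis` — the measurement chain: sub-pixel fringe-centre
  finding, azimuthal radial profiling, peak detection with bounded
  cubic refinement, radius→height conversion, spacing regression and
  moiré-envelope period estimation;
- `swfringe.reconstruction` — fringe-contour extraction, antinode
  numbering along the nesting order, and scattered interpolation into a
  3D height map;
- `swfringe.cli` — a thin `swfringe` command
  (`simulate | analyze | reconstruct | evaluate`).

## Worked example

```python
from swfringe import analyze_cap_image
from swfringe.presets import cap_fixture

image, truth, specimen, optics = cap_fixture(seed=0, photon_scale=500.0,
                                             background=5.0)
report = analyze_cap_image(image, optics, specimen)
print(report.n_peaks, report.spacing_nm, report.rel_error_pct)
```

This renders a noisy 512×512 image of a dyed spherical cap (R = 30 mm,
514 nm excitation in air) whose field of view spans 37 antinodes, then
measures the spacing. Output of `examples/02_cap_spacing_measurement.py`:

```
fringe centre found at (255.5, 255.5) (pixel coordinates)
detected peaks: 37
measured antinodal spacing: 256.98 +- 0.02 nm
theoretical lambda/2n:      257.0 nm
relative error:             0.009 %
```

The 37 detected fringes map, through the cap geometry, onto an evenly
spaced ladder of heights; the regression slope (256.98 nm) recovers the
theoretical antinode spacing λ/2n = 257 nm. The other scripts in
`examples/` demonstrate the moiré beat measurement (direct narrowband
detection and the subtraction route, both landing within ~0.5% of
L = 4517 nm), contour-based 3D reconstruction of the cap (RMSE ≈ 9 nm
against ground truth, far below the λ/8n = 64 nm interpolation bound),
and the multiplanar fringes of a discocyte red-cell membrane.

The same pipeline from the shell:

```bash
swfringe simulate --preset cap --seed 0 --out sim/
swfringe analyze --image sim/image.tif --report report.json
swfringe reconstruct --image sim/image.tif --truth sim/truth.tif --out rec/
```

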