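# Methods

## Optical model

The excitation standing wave is modelled as an ideal planar pattern
above a perfect mirror: reflection carries a π phase shift, the mirror
surface is the first node, and the relative excitation intensity at
height z (nm, physical distance along the optical axis) is
sin²(2πnz/λ_ex) with λ_ex the vacuum wavelength and n the refractive
index of the medium between fluorophore and mirror. Antinodes sit at
(2k+1)·λ/4n; their spacing is λ/2n and each sin² peak has FWHM λ/4n.
Planar antinodes are assumed at all numerical apertures; no
NA-dependent axial compression factor is applied. This is a deliberate
model simplification — the scanned focal spot of a real high-NA
objective produces locally curved wavefronts, and the package does not
attempt a vectorial focal-field computation.

Emission self-interference (a dye molecule near a reflector interferes
its direct and reflected emission) is modelled with the same sin² form
at the detected emission wavelength. Three detection modes are exposed:

- `broadband_excitation_only` — excitation modulation only;
- `emission_only` — emission modulation averaged over a flat detection
  band (models suppressing the excitation standing wave with a notch
  reflector);
- `narrowband_moire` — the *product* of the excitation factor and the
  band-averaged emission factor.

Whether the jointly modulated signal is multiplicative or additive in
the two interference factors is not established by the subtraction
experiment the model emulates — only the beat period is. The product
form was chosen because both forms carry the identical envelope period
L/2n, where 1/L = 1/λ_ex − 1/λ_em, and the period is the measured
quantity. The band average uses 21-point midpoint quadrature over a
flat band (no dye emission spectrum is modelled; detection bands here
are ≤ 100 nm and only the band centre enters the analysis). Dipole
orientation effects, quantum-yield modulation and lifetime oscillations
near the mirror are neglected throughout.

Note that a finite detection band makes the beat a narrow frequency
comb rather than a single line: the band-averaged envelope stays
coherent over the first ~10 µm of height for a 5 nm band at 580 nm,
which comfortably covers the fixtures' 9.5 µm height span.

## Specimen surfaces

**Spherical cap.** A sphere of radius R touching the mirror puts a
surface point at lateral radius r at height z = R − √(R² − r²)
(evaluated as r²/(R + √(R²−r²)) to avoid cancellation; fringe heights
are ~10⁻⁴ of R). The default calibration specimen uses R = 30 mm, in
the range of the long-radius planoconvex lenses used for this kind of
calibration.

**Discocyte.** The biconcave red-cell thickness profile is the standard
smooth quartic family T(ρ) = √(1−ρ²)(C₀ + C₂ρ² + C₄ρ⁴), ρ = 2r/D. The
printed cell dimensions constrain only T(0) = 1 µm and max T = 2.5 µm
(D = 7.8 µm), so the remaining degree of freedom is closed by fixing
the thickness maximum at ρ* = 0.85, near the classical value for a
normal discocyte; C₂ and C₄ then follow from a 2×2 linear system. The
solve is rejected when the resulting profile is non-positive or its
rim stationary point is not the global maximum. The membrane is an
infinitesimally thin shell; upper/lower sheets are midplane ± T/2 above
a configurable mirror standoff (default 0 nm — the standoff of a cell
settled on an adhesive-coated mirror is not independently known), with
an optional small-angle tilt.

## Rendering

Pixel value = Poisson(photon_scale · I + background) + N(0, read_noise²),
where I is the relative detected intensity of the surface point(s)
under the pixel, after an optional lateral Gaussian blur of the
noiseless field standing in for the scanning PSF (default off). For
membranes both sheets contribute with equal weight (relative dye uptake
of the two membrane faces is taken as equal), each multiplied by the
areal foreshortening √(1+|∇z|²) of a surface dyed at uniform areal
density — this reproduces the bright cell outline seen without a
mirror. All antinodes crossing the specimen are summed with equal
weight (no axial PSF envelope): multiplanar visibility within the depth
of field is the regime the renderer emulates.

Default fixture raster is 512×512 (1024×1024 for contour
reconstruction, where the outermost fringes must stay separated by
several pixels); the geometry matches the physical experiments'
2048×2048 frames at reduced sampling so that full analyses run in
seconds. Defaults photon_scale 500 and background 5 give the strong
but visibly noisy fringes typical of averaged confocal frames. Noise is
seeded and the seed is recorded in the image metadata; renders are
bit-reproducible.

## Measurement chain

1. **Centre finding** maximises the fraction of image variance
   explained by annular means (between-annulus variance / total
   variance) over candidate centres: hierarchical search — 8× block-
   averaged coarse pass over the whole frame, then full-resolution hill
   climbing down to 1/8-pixel steps. Score below 0.1 raises
   centre-not-found (a uniform or structureless image explains ~none of
   its variance radially).
2. **Radial profile** is the azimuthal mean in annuli of one pixel
   width by default, out to the inscribed circle (corner annuli are
   incomplete and would distort peak counts). A single-ray mode is
   provided for fidelity to a hand-drawn profile; azimuthal averaging
   is the default for noise robustness.
3. **Peak detection** takes local maxima with prominence ≥ 0.1 of the
   profile range, then refines each by bounded scalar minimisation of
   the negated cubic-spline interpolated profile within one bin either
   side — the flipped-function minimisation familiar from this
   measurement done by hand in MATLAB's `fminbnd`. Minimum peak
   separation defaults to two bins; a radius-dependent separation
   (tighter fringe crowding at the field edge) was considered and
   rejected as it needs specimen knowledge the detector does not have —
   the prominence criterion suffices on the supported fixtures.
4. **Radius → height** via the cap geometry; antinode indices 0,1,2,…
   assigned in order of increasing height. **Spacing** is the slope of
   the least-squares regression of height on index (less noise-
   sensitive than averaging successive differences, which is also
   exposed), with the slope's standard error reported.
5. **Envelope period**: interior maxima of peak amplitude vs height,
   with prominence ≥ 0.1 of the *maximum* amplitude (relative to the
   range it would hallucinate maxima on a flat, slowly decaying
   amplitude sequence — the emission-only control must raise
   fewer-than-two-maxima instead), refined by the same bounded cubic
   procedure; the period is the mean spacing of refined maxima and
   L = 2n·period.

## Contour reconstruction

Fringe ridges are extracted by thresholding the (optionally smoothed)
image at 0.5 of its maximum — the FWHM band of a sin² fringe, which
keeps crowded fringes separate — thinning with morphological
skeletonisation, tracing each connected chain into a polyline (angular
ordering about the component centroid; adequate for the star-convex
rings this pipeline targets), and refining every vertex to the
sub-pixel intensity maximum along the local outward direction
(parabolic fit; the skeleton marks the band midline, which is biased
off the true ridge where the fringe chirp is strong). Chains shorter
than 10 pixels, and open chains (fringes clipped by the image edge),
are dropped.

Contours must nest strictly; indices are assigned consecutively along
the nesting order and each contour receives the exact antinode height
(2k+1)·λ/4n. The **absolute** antinode index is not identifiable from a
single broadband image — `base_index` (default 0) sets the offset and
is recorded in the output metadata. The nesting *direction* is chosen
automatically from the dark-contact-point cue (the mirror is a node, so
a surface touching it is dark at the centre); with ground truth the
wrong direction inflates RMSE by two orders of magnitude on the cap
fixture. Surface heights between contours are filled by scattered
linear interpolation (piecewise-linear on the Delaunay triangulation of
the contour points), masked outside the convex hull. Membrane images
containing two sheets are reconstructed as a single surface by default;
separating upper/lower membrane contributions is a declared
simplification.

## What the synthetic data does and does not show

The generator reproduces the geometry, radiometry and noise character
of the calibration and red-cell experiments: chirped concentric fringes
of a spherical surface, narrowband moiré modulation, the emission-only
and subtraction controls, membrane foreshortening, shot + read noise.
It does not model focal-volume effects (pinhole sectioning, curved
high-NA antinodes), dye spectra, mirror imperfections, flat-field or
drift, refractile cell contents, or membrane fluctuations. Passing
recovery tests therefore demonstrates the *measurement chain* is
unbiased and precise under the stated image model, not that real
micrographs meet that model.

## Numerical defaults

| parameter | default | notes |
|---|---|---|
| band quadrature | 21 midpoints | flat detection band |
| profile bin width | 1 pixel | ≥ pixel size enforced |
| peak prominence | 0.1 × range | |
| peak separation | 2 bins | |
| envelope prominence | 0.1 × max amplitude | |
| ridge threshold | 0.5 × image max | FWHM band |
| contour min length | 10 px | |
| centre score threshold | 0.1 | explained-variance fraction |
| refinement tolerance | 1e-4 bin | bounded minimisation xatol |

Degenerate inputs raise typed errors (`CenterNotFoundError`,
`NoPeaksFoundError`, `EnvelopeNotFoundError`, `AmbiguousTopologyError`,
`ConfigError`) which the CLI maps to exit codes 3/3/3/3/2.

## Known limitations

- Peak-count exactness (the 37-fringe fixture) depends on the field
  edge landing on a node; arbitrary crops may gain or lose an edge
  peak.
- Contour extraction needs ≳5 px between adjacent fringes; heavily
  chirped fields should be rendered at higher resolution (the 1024²
  default for reconstruction) or analysed radially instead.
- The nesting-based index assignment assumes a monotone surface under
  the contour family; biconcave membranes violate this near the dimple
  and are only contour-mapped on their monotone annulus.
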