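"""Moire beat between excitation and emission standing waves.

Fluorophores near a mirror also self-interfere at their *emission*
wavelength.  Detected through a narrow (5 nm) band at 580 nm, the
514 nm-excited fringes are amplitude-modulated at the difference
frequency 1/L = 1/514 - 1/580; the same beat appears when the
emission-only pattern (excitation standing wave suppressed) is
subtracted from the excitation-only pattern.  Both routes are measured
here and compared with the theoretical L = 4520 nm.
"""

from swfringe import (
    NoiseModel,
    analyze_cap_image,
    detect_peaks,
    estimate_envelope_period,
    find_fringe_center,
    moire_period,
    radial_profile,
    radii_to_heights,
    simulate_subtraction_pair,
)
from swfringe.presets import cap_fixture

L_theory = moire_period(514.0, 580.0)
print(f"theoretical moire period: L = {L_theory:.0f} nm")

# route 1: directly observed narrowband moire
image, truth, specimen, optics = cap_fixture(
    mode="narrowband_moire", seed=0, photon_scale=500.0, background=5.0
)
report = analyze_cap_image(image, optics, specimen, estimate_envelope=True)
print(f"direct narrowband detection:  L = {report.envelope_L_nm:.0f} nm "
      f"({abs(report.envelope_L_nm - L_theory) / L_theory * 100:.1f}% off theory)")

# route 2: subtraction of the emission-only from the excitation-only image
excitation, emission, difference = simulate_subtraction_pair(
    truth, 514.0, 580.0, 1.0, NoiseModel(photon_scale=500.0, background=5.0, seed=0)
)
center = find_fringe_center(difference)
peaks = radii_to_heights(detect_peaks(radial_profile(difference, center)), specimen)
L_sub = 2.0 * estimate_envelope_period(peaks)
print(f"subtraction-derived pattern:  L = {L_sub:.0f} nm "
      f"({abs(L_sub - L_theory) / L_theory * 100:.1f}% off theory)")
# Both estimates come from the spacing of the peak-amplitude envelope
# maxima along height (the beat spacing in height is L/2n); their
# agreement confirms the modulation sits at the difference frequency.
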