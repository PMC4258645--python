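"""Closed-form quantities of standing-wave fluorescence above a mirror.

Excitation light reflected at normal incidence forms a sin^2 standing
wave with a node at the mirror; fluorescence is excited only near the
antinodes.  This script prints the three numbers that characterise the
method for the two experimental configurations the package models.
"""

from swfringe import OpticsConfig, antinode_spacing, axial_fwhm, moire_period

# monolayer-on-lens calibration experiment: 514 nm argon line, air gap
air = OpticsConfig(excitation_wavelength=514.0, refractive_index=1.0)
print("514 nm excitation in air (n = 1):")
print(f"  antinode spacing lambda/2n = {antinode_spacing(air):.1f} nm")
print(f"  axial FWHM       lambda/4n = {axial_fwhm(air):.1f} nm")

# red-cell experiment: 488 nm in aqueous mountant
cell = OpticsConfig(excitation_wavelength=488.0, refractive_index=1.34)
print("488 nm excitation in aqueous mountant (n = 1.34):")
print(f"  antinode spacing lambda/2n = {antinode_spacing(cell):.1f} nm")
print(f"  axial FWHM       lambda/4n = {axial_fwhm(cell):.1f} nm  (~90 nm axial resolution)")

# moire beat between the excitation standing wave and the emission
# self-interference pattern, for 580 nm detection of 514 nm excitation
L = moire_period(514.0, 580.0)
print(f"moire beat period for 514/580 nm: L = {L:.0f} nm  (1/L = 1/514 - 1/580)")
print(f"  beat spacing in height above the mirror: L/2n = {L / 2:.0f} nm")
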