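"""Physical constants and detector defaults.

The electron rest energy is fixed at exactly 511 keV so that the Compton
energy-transfer arithmetic matches the convention used throughout the
analysis (the annihilation photon energy and the rest energy coincide).
"""

# Electron rest energy m_e c^2 [keV].  Exactly 511 by convention.
MEC2_KEV = 511.0

# Speed of light in vacuum [cm/ns], the value used in the scatter test.
C_CM_PER_NS = 29.98

# Annihilation photon energy [keV].
E_ANNIH_KEV = 511.0

# Prompt de-excitation photon energy of 22Na [keV].
E_PROMPT_KEV = 1274.6

# Classical electron radius squared [cm^2].
RE2_CM2 = 7.940787e-26

# Electron density of EJ-230 polyvinyltoluene [electrons/cm^3]
# (rho = 1.023 g/cm^3, Z/A = 0.5414).
PVT_ELECTRON_DENSITY = 3.335e23

# Default registration threshold on smeared energy deposition [keV].
THRESHOLD_KEV = 70.0

# Default resolutions: time [ns], axial position [cm], and fractional
# energy resolution coefficient (sigma(E)/E = coeff / sqrt(E[MeV])).
SIGMA_T_NS = 0.155
SIGMA_Z_CM = 2.5
ENERGY_RES_COEFF = 0.44

# Published Boltzmann-sigmoid registration-efficiency parameters
# (increasing convention): floor, plateau, midpoint [keV], slope [keV].
BSF_REFERENCE = (0.177, 0.996, 148.7, 22.77)
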