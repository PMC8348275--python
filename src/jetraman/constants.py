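"""Physical constants used throughout the package.

Kept in one place so numerical results are bit-stable across modules.
"""

#: hc/kB in cm·K — converts a wavenumber (cm⁻¹) divided by a temperature (K)
#: into the dimensionless Boltzmann exponent.
HC_OVER_KB = 1.4387770

#: MHz → cm⁻¹ conversion divisor (speed of light in MHz·cm).
MHZ_PER_CM = 29979.2458

#: Rotational constant (cm⁻¹) from a moment of inertia in amu·Å²:  X = INERTIA_TO_CM / I.
INERTIA_TO_CM = 16.8576304

#: Molar gas constant in kJ/(mol·K).
R_KJ_MOL_K = 8.314462618e-3
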