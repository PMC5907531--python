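"""Physical constants and laboratory defaults.

Units follow electrophysiology conventions: time in ms, voltage in mV,
rates in ms^-1, concentrations in mM, current density in pA/pF.
"""

BOLTZMANN_J_PER_K = 1.381e-23
"""Boltzmann constant kB (J/K)."""

PLANCK_J_S = 6.626e-34
"""Planck constant h (J*s)."""

GAS_CONSTANT_J_PER_MOL_K = 8.315
"""Ideal gas constant R (J/mol/K)."""

FARADAY_C_PER_MOL = 96485.0
"""Faraday constant F (C/mol)."""

ROOM_TEMPERATURE_K = 296.15
"""Default bath temperature for voltage-clamp work (23 C)."""

BODY_TEMPERATURE_K = 310.0
"""Physiological temperature used for cell and tissue simulation (37 C)."""

PIPETTE_K_MM = 120.0
"""Internal potassium: 10 mM KCl + 110 mM K-aspartate pipette solution."""

BATH_K_MM = 5.4
"""External potassium of the standard extracellular solution (mM)."""
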