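"""Unit system and physical constants.

The internal unit system is the one conventional for coarse-grained
biomolecular simulation:

========  ==============================
length    Ångström (Å)
energy    kcal·mol⁻¹
time      femtosecond (fs)
mass      atomic mass unit (amu)
========  ==============================

These four choices are not mutually consistent, so energies must be
converted before being used in Newton's equations.  Because
1 amu·Å²·fs⁻² = 10⁷ J·mol⁻¹ exactly (1 amu·N_A = 1 g·mol⁻¹), the
conversion factor is

    1 kcal·mol⁻¹ = 4184 / 10⁷ amu·Å²·fs⁻² = 4.184e-4 amu·Å²·fs⁻².

A velocity-Verlet harmonic-oscillator period test pins this constant.
"""

#: kcal·mol⁻¹ expressed in internal kinetic units (amu·Å²·fs⁻²).
KCAL_MOL_TO_INTERNAL = 4.184e-4

#: internal kinetic units (amu·Å²·fs⁻²) expressed in kcal·mol⁻¹.
INTERNAL_TO_KCAL_MOL = 1.0 / KCAL_MOL_TO_INTERNAL

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹.
KB_KCAL_MOL_K = 0.0019872041
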