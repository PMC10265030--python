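"""Unit conversion constants — the single source of truth for the package.

All public functions take and return the field-conventional units stated in
their docstrings (mN, μm, GPa, mm³, mg); conversions funnel through the
constants below so that a unit audit has one place to look.
"""

#: E [GPa] · T³ [μm³]  →  flexural rigidity [mN·mm]
#: 1 GPa = 1e6 mN/mm², 1 μm³ = 1e-9 mm³  ⇒  1 GPa·μm³ = 1e-3 mN·mm
GPA_UM3_TO_MN_MM = 1e-3

#: μm → mm
UM_TO_MM = 1e-3

#: mass [mg] · g [m/s²] → weight [mN]: 1 mg·m/s² = 1e-6 N = 1e-3 mN
MG_MS2_TO_MN = 1e-3

#: stiffness [μN/nm] → [N/m]
UN_PER_NM_TO_N_PER_M = 1e3

#: area [nm²] → [m²]
NM2_TO_M2 = 1e-18

#: Pa → GPa
PA_TO_GPA = 1e-9

#: μN → N
UN_TO_N = 1e-6

STANDARD_GRAVITY = 9.81  # m/s²


def weight_mn(mass_mg: float, g: float = STANDARD_GRAVITY) -> float:
    """Gravitational force in mN on a mass given in mg."""
    return mass_mg * g * MG_MS2_TO_MN
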