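"""Unit conventions and physical constants.

Internal units follow the GROMACS/Martini convention throughout the
package: length nm, time ps, mass amu (g/mol), energy kJ/mol,
temperature K.  In these units velocity is nm/ps, acceleration nm/ps^2,
and mass density amu/nm^3.  Derived viscosity amu/(nm ps) is converted
to mPa*s for reporting.
"""

#: Boltzmann constant, kJ/(mol K).
KB = 0.008314462618

#: One amu/nm^3 expressed in kg/m^3.
AMU_PER_NM3_TO_KG_PER_M3 = 1.66053906892

#: One amu/(nm ps) expressed in mPa*s.
AMU_PER_NM_PS_TO_MPAS = 1.66053906892e-3


def density_si_to_internal(rho_kg_m3: float) -> float:
    """kg/m^3 -> amu/nm^3."""
    return rho_kg_m3 / AMU_PER_NM3_TO_KG_PER_M3


def viscosity_internal_to_mpas(eta_internal: float) -> float:
    """amu/(nm ps) -> mPa*s."""
    return eta_internal * AMU_PER_NM_PS_TO_MPAS
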