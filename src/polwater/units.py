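"""Unit system and physical constants.

The package works in the conventional molecular-dynamics unit system:
lengths in nm, time in ps, mass in amu, charge in elementary charges (e),
energy in kJ/mol.  Derived quantities follow: velocity nm/ps, force
kJ mol^-1 nm^-1, pressure converted to bar for reporting.
"""

# Electric conversion factor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
F_ELEC = 138.935485

# Vacuum permittivity in e^2 (kJ/mol)^-1 nm^-1
EPS0 = 1.0 / (4.0 * 3.141592653589793 * F_ELEC)

# Boltzmann constant in kJ mol^-1 K^-1
KB = 0.00831446

# 1 e*nm in Debye
DEBYE_PER_E_NM = 48.0321

# 1 amu in kg
AMU_KG = 1.66054e-27

# 1 kJ mol^-1 nm^-3 in bar
BAR_PER_KJ_NM3 = 16.6054

# 1 bar*nm in mN/m  (1 bar = 1e5 N/m^2; x 1e-9 m = 1e-4 N/m)
MN_PER_M_PER_BAR_NM = 0.1

# Force per unit charge in a 1 V/nm field, kJ mol^-1 nm^-1 e^-1
FIELD_CONV = 96.4853

# 1 nm^2/ps in cm^2/s
CM2_S_PER_NM2_PS = 1.0e-2


def amu_per_nm3_to_kg_m3(rho):
    """Convert a number density*mass in amu/nm^3 to kg/m^3."""
    return rho * AMU_KG * 1e27


def kg_m3_to_amu_per_nm3(rho):
    return rho / (AMU_KG * 1e27)
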