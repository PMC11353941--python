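"""Physical constants (CODATA 2018) and the unit conversions used package-wide.

Working units
-------------
Molecular lengths are in angstrom (Å), per-molecule volumes in Å³, molar
volumes in cm³ mol⁻¹, temperatures in K.  Molar energies are reported in
kJ mol⁻¹ and molar entropies in J K⁻¹ mol⁻¹; per-molecule energies (the
mixture module) are in J.  Attraction parameters are carried in molar form,
kJ cm³ mol⁻², and converted to per-molecule J Å³ where the partition
function needs them (``a_molar = N_Av² · a_molecular``).

Every conversion between these systems lives here so that the
thermodynamic formulas elsewhere stay dimensionless-by-construction:
packing products such as ρ₁b₁ are formed as N_Av·b[Å³]/(v₁[cm³ mol⁻¹]·10²⁴).
"""

from __future__ import annotations

import math

# -- constants ---------------------------------------------------------------

R = 8.314462618
"""Molar gas constant, J mol⁻¹ K⁻¹."""

N_AV = 6.02214076e23
"""Avogadro constant, mol⁻¹."""

K_B = R / N_AV
"""Boltzmann constant, J K⁻¹."""

H_PLANCK = 6.62607015e-34
"""Planck constant, J s."""

ATM_PA = 101325.0
"""One standard atmosphere, Pa."""

T_ROOM = 298.15
"""25 °C, the reference temperature of the built-in solvent table, K."""

# Å³ per molecule  <->  cm³ per mole:  1 cm³ = 1e24 Å³
_A3_PER_CM3 = 1.0e24


# -- conversions -------------------------------------------------------------

def number_density(v1_cm3_mol: float) -> float:
    """Liquid number density ρ₁ in Å⁻³ from the molar volume in cm³ mol⁻¹."""
    return N_AV / (v1_cm3_mol * _A3_PER_CM3)


def molar_volume_from_density(rho_A3: float) -> float:
    """Molar volume in cm³ mol⁻¹ from a number density in Å⁻³."""
    return N_AV / (rho_A3 * _A3_PER_CM3)


def molecule_volume_A3(v1_cm3_mol: float) -> float:
    """Per-molecule volume in Å³ from the molar volume in cm³ mol⁻¹."""
    return v1_cm3_mol * _A3_PER_CM3 / N_AV


def b_molar_cm3(b_A3: float) -> float:
    """Molar repulsive volume parameter in cm³ mol⁻¹ from per-molecule Å³."""
    return N_AV * b_A3 / _A3_PER_CM3


def a_molecular_from_molar(a_molar: float) -> float:
    """Per-molecule attraction parameter in J Å³ from kJ cm³ mol⁻².

    a_molar = N_Av² · a_molecular up to the J/kJ and Å³/cm³ factors.
    """
    return a_molar * 1.0e3 * _A3_PER_CM3 / N_AV**2


def a_molar_from_molecular(a_molecular: float) -> float:
    """Molar attraction parameter in kJ cm³ mol⁻² from per-molecule J Å³."""
    return a_molecular * N_AV**2 / (1.0e3 * _A3_PER_CM3)


def thermal_wavelength_A(mass_kg: float, T: float) -> float:
    """Thermal de Broglie wavelength Λ = h/√(2πmkT), in Å."""
    if mass_kg <= 0.0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    if T <= 0.0:
        raise ValueError(f"temperature must be positive, got {T}")
    return H_PLANCK / math.sqrt(2.0 * math.pi * mass_kg * K_B * T) * 1.0e10


def ideal_gas_molar_volume(T: float, P_atm: float = 1.0) -> float:
    """Ideal-gas molar volume RT/P in cm³ mol⁻¹ at T (K) and P (atm)."""
    if T <= 0.0:
        raise ValueError(f"temperature must be positive, got {T}")
    if P_atm <= 0.0:
        raise ValueError(f"pressure must be positive, got {P_atm}")
    return R * T / (P_atm * ATM_PA) * 1.0e6
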