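"""Closed-form solvation thermodynamics of a van der Waals liquid.

The model treats a liquid as a van der Waals fluid: each molecule owns a
repulsive volume ``b`` (derived from an effective hard-sphere diameter σ via
the random-close-packing convention ``b = (πσ³/6)/0.64``) and, optionally, an
attraction parameter ``a``.  Solvation in the Ben-Naim sense — moving a solute
from a fixed position in the ideal gas to a fixed position in the liquid —
then splits exactly into two sub-processes:

* **cavity creation**: the reversible work to open a solute-sized cavity,
  ``ΔG_c = −RT·ln(1−ρ₁b₁) + RT·ρ₁b₂/(1−ρ₁b₁)``, driven purely by excluded
  volume (ρ₁ is the liquid number density);
* **switching on attraction**: ``ΔG_a = −2√(a₁a₂)/v₁`` with a geometric-mean
  solute–solvent cross term.

Each sub-process carries its own enthalpy/entropy split.  The single carrier
of temperature dependence is the isobaric expansion coefficient α_P, taken
constant, so the molar volume follows ``v₁(T) = v₁(T_ref)·exp(α_P(T−T_ref))``
and every analytic derivative below is exact under that model.  The cavity
entropy further decomposes into the always-negative excluded-volume part
``ΔS_x = −ΔG_c/T`` and the structural-reorganization part
``ΔS_nx = ΔH_c/T``, whose enthalpy and entropy contributions cancel in ΔG —
the enthalpy–entropy compensation characteristic of a system responding to a
small perturbation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .constants import R, number_density
from .errors import DomainError, OverpackedLiquidError

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesSpec",
    "SolventState",
    "Conditions",
    "CavityThermo",
    "AttractionThermo",
    "SolvationThermo",
    "hard_sphere_b",
    "molar_volume_at_T",
    "cavity_thermodynamics",
    "attraction_thermodynamics",
    "solvation_free_energy",
    "solvation_dG_from_densities",
    "density_ratio_from_dG",
    "liberation_free_energy",
    "kinetic_pressure",
    "temperature_scan",
]

RANDOM_CLOSE_PACKING = 0.64
_B_SIGMA_TOL = 0.1  # Å³ slack allowed between a stated b and (πσ³/6)/0.64


def hard_sphere_b(sigma: float) -> float:
    """Repulsive volume parameter b (Å³) from a hard-sphere diameter σ (Å).

    ``b = (πσ³/6)/0.64``: the molecular volume inflated by the random
    close packing factor, since randomly packed spheres fill only 64 % of
    space.  For σ = 4 Å (xenon) this gives 52.4 Å³.
    """
    if sigma < 0.0:
        raise DomainError(f"hard-sphere diameter must be >= 0, got {sigma}")
    return (math.pi * sigma**3 / 6.0) / RANDOM_CLOSE_PACKING


@dataclass(frozen=True)
class SpeciesSpec:
    """Size, attraction and mass parameters of one chemical species.

    Parameters
    ----------
    name
        Label for reports.
    sigma
        Effective hard-sphere diameter, Å.
    b
        Repulsive volume parameter per molecule, Å³.  Filled from ``sigma``
        via :func:`hard_sphere_b` when omitted; when both are given they must
        agree to 0.1 Å³.
    a_attr
        Attraction parameter in molar units, kJ cm³ mol⁻² (``None`` =
        unknown; the attraction channel is then reported as absent).
    mass
        Molecular mass in kg, needed only for the thermal de Broglie
        wavelength in absolute chemical potentials.
    """

    name: str = ""
    sigma: float | None = None
    b: float | None = None
    a_attr: float | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0.0:
            raise DomainError(f"{self.name or 'species'}: sigma must be >= 0, got {self.sigma}")
        if self.b is None and self.sigma is not None:
            object.__setattr__(self, "b", hard_sphere_b(self.sigma))
        if self.b is not None and self.b < 0.0:
            raise DomainError(f"{self.name or 'species'}: b must be >= 0, got {self.b}")
        if self.a_attr is not None and self.a_attr < 0.0:
            raise DomainError(f"{self.name or 'species'}: a_attr must be >= 0, got {self.a_attr}")
        if self.mass is not None and self.mass <= 0.0:
            raise DomainError(f"{self.name or 'species'}: mass must be > 0, got {self.mass}")
        if self.sigma is not None and self.b is not None:
            expected = hard_sphere_b(self.sigma)
            if abs(self.b - expected) > _B_SIGMA_TOL:
                raise DomainError(
                    f"{self.name or 'species'}: b={self.b} Å³ inconsistent with "
                    f"(πσ³/6)/0.64={expected:.3f} Å³ for sigma={self.sigma} Å"
                )


@dataclass(frozen=True)
class SolventState:
    """A liquid at reference conditions.

    Holds the experimental molar volume ``v1`` (cm³ mol⁻¹) at ``T_ref`` (K)
    and the isobaric thermal expansion coefficient ``alpha_P`` (K⁻¹, treated
    as temperature-independent).  Derived quantities: the number density
    ``rho1`` (Å⁻³) and packing fraction ``xi1 = rho1·b1`` at ``T_ref``.
    """

    species: SpeciesSpec
    v1: float
    alpha_P: float
    T_ref: float = 298.15

    def __post_init__(self) -> None:
        if self.v1 <= 0.0:
            raise DomainError(f"{self.species.name}: molar volume must be > 0, got {self.v1}")
        if self.T_ref <= 0.0:
            raise DomainError(f"{self.species.name}: T_ref must be > 0, got {self.T_ref}")
        if self.species.b is None:
            raise DomainError(f"{self.species.name}: solvent species needs b (or sigma)")
        if self.alpha_P < 0.0:
            # physically real (water below 4 °C); formulas remain valid
            logger.warning(
                "%s: negative alpha_P = %g K⁻¹ accepted (liquid contracts on heating)",
                self.species.name,
                self.alpha_P,
            )
        if not 0.0 <= self.xi1 < 1.0:
            raise OverpackedLiquidError(
                f"{self.species.name}: packing fraction ρ1·b1 = {self.xi1:.4f} "
                f"not in [0, 1); free volume must be positive"
            )

    @property
    def rho1(self) -> float:
        """Number density at ``T_ref``, Å⁻³."""
        return number_density(self.v1)

    @property
    def xi1(self) -> float:
        """Packing fraction ρ₁·b₁ at ``T_ref``."""
        return self.rho1 * self.species.b

    def v1_at(self, T: float) -> float:
        """Molar volume at T under the constant-α_P exponential model."""
        return molar_volume_at_T(self.v1, self.alpha_P, self.T_ref, T)

    def rho1_at(self, T: float) -> float:
        """Number density at T, Å⁻³."""
        return number_density(self.v1_at(T))


@dataclass(frozen=True)
class Conditions:
    """Temperature (K) and pressure (atm).  P is metadata only: no formula
    in this model uses it numerically."""

    T: float = 298.15
    P_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0.0:
            raise DomainError(f"temperature must be > 0, got {self.T}")


@dataclass(frozen=True)
class CavityThermo:
    """Thermodynamics of cavity creation, kJ mol⁻¹ / J K⁻¹ mol⁻¹.

    ``dS_x = −dG_c/T`` is the excluded-volume entropy (always ≤ 0);
    ``dS_nx = dH_c/T`` is the structural-reorganization entropy, which
    cancels against dH_c in the free energy.
    """

    dG_c: float
    dH_c: float
    dS_c: float
    dS_x: float
    dS_nx: float
    T: float


@dataclass(frozen=True)
class AttractionThermo:
    """Thermodynamics of switching on solute–solvent attraction."""

    dG_a: float
    dH_a: float
    dS_a: float
    T: float


@dataclass(frozen=True)
class SolvationThermo:
    """Assembled Ben-Naim solvation result: ``dG_star = dG_c + dG_a``."""

    dG_star: float
    cavity: CavityThermo
    attraction: AttractionThermo
    attraction_present: bool = True


def molar_volume_at_T(v1_ref: float, alpha_P: float, T_ref: float, T: float) -> float:
    """Molar volume at T from a constant isobaric expansion coefficient.

    Exact solution of d ln v/dT = α_P:  ``v(T) = v_ref·exp(α_P·(T−T_ref))``.
    """
    if v1_ref <= 0.0:
        raise DomainError(f"reference molar volume must be > 0, got {v1_ref}")
    if T <= 0.0 or T_ref <= 0.0:
        raise DomainError(f"temperatures must be > 0, got T={T}, T_ref={T_ref}")
    return v1_ref * math.exp(alpha_P * (T - T_ref))


def cavity_thermodynamics(solvent: SolventState, b2: float, T: float) -> CavityThermo:
    """Work, enthalpy and entropy of creating a cavity of volume parameter b2.

    Molar working formulas, with ρ₁ evaluated at T through the exponential
    volume model::

        ΔG_c = −RT·ln(1−ρ₁b₁) + RT·ρ₁b₂/(1−ρ₁b₁)
        ΔH_c = RT²·α_P·ρ₁/(1−ρ₁b₁)·[b₁ + b₂/(1−ρ₁b₁)]
        ΔS_c = R·ln(1−ρ₁b₁) − R·ρ₁b₂/(1−ρ₁b₁) + ΔH_c/T

    ΔS_c is the exact −∂ΔG_c/∂T and ΔH_c the exact −T²·∂(ΔG_c/T)/∂T of
    these expressions.  Inputs: b2 ≥ 0 in Å³, T in K; outputs in kJ mol⁻¹
    and J K⁻¹ mol⁻¹.
    """
    if b2 < 0.0:
        raise DomainError(f"solute volume parameter b2 must be >= 0, got {b2}")
    if T <= 0.0:
        raise DomainError(f"temperature must be > 0, got {T}")
    b1 = solvent.species.b
    rho1 = solvent.rho1_at(T)
    xi1 = rho1 * b1
    if xi1 >= 1.0:
        raise OverpackedLiquidError(
            f"{solvent.species.name}: ρ1·b1 = {xi1:.4f} >= 1 at T = {T} K; "
            f"the liquid has no free volume"
        )
    free = 1.0 - xi1
    dG_c = (-R * T * math.log(free) + R * T * rho1 * b2 / free) / 1.0e3
    dH_c = (R * T**2 * solvent.alpha_P * rho1 / free * (b1 + b2 / free)) / 1.0e3
    dS_c = R * math.log(free) - R * rho1 * b2 / free + dH_c * 1.0e3 / T
    dS_x = -dG_c * 1.0e3 / T
    dS_nx = dH_c * 1.0e3 / T
    return CavityThermo(dG_c=dG_c, dH_c=dH_c, dS_c=dS_c, dS_x=dS_x, dS_nx=dS_nx, T=T)


def attraction_thermodynamics(
    a1: float, a2: float, v1: float, alpha_P: float, T: float
) -> AttractionThermo:
    """Thermodynamics of switching on the solute–solvent attractive potential.

    With a geometric-mean cross term and ``v1`` the solvent molar volume at
    T (cm³ mol⁻¹), in molar attraction units (kJ cm³ mol⁻²)::

        ΔG_a = −2√(a₁a₂)/v₁
        ΔS_a = −2√(a₁a₂)·α_P/v₁
        ΔH_a = ΔG_a·(1 + α_P·T) = ΔG_a + T·ΔS_a
    """
    if a1 < 0.0 or a2 < 0.0:
        raise DomainError(f"attraction parameters must be >= 0, got a1={a1}, a2={a2}")
    if v1 <= 0.0:
        raise DomainError(f"molar volume must be > 0, got {v1}")
    if T <= 0.0:
        raise DomainError(f"temperature must be > 0, got {T}")
    cross = math.sqrt(a1 * a2)
    dG_a = -2.0 * cross / v1
    dS_a = -2.0 * cross * alpha_P / v1 * 1.0e3
    dH_a = dG_a * (1.0 + alpha_P * T)
    return AttractionThermo(dG_a=dG_a, dH_a=dH_a, dS_a=dS_a, T=T)


def solvation_free_energy(
    solvent: SolventState, solute: SpeciesSpec, T: float
) -> SolvationThermo:
    """Ben-Naim solvation thermodynamics of ``solute`` in ``solvent`` at T.

    Assembles the cavity and attraction sub-processes; ``dG_star`` is their
    sum.  If either species lacks an attraction parameter the attraction
    channel is zero-filled and ``attraction_present`` is False.
    """
    if solute.b is None:
        raise DomainError(f"solute {solute.name or '?'}: b (or sigma) is required")
    cavity = cavity_thermodynamics(solvent, solute.b, T)
    a1 = solvent.species.a_attr
    a2 = solute.a_attr
    present = a1 is not None and a2 is not None
    if present:
        attraction = attraction_thermodynamics(a1, a2, solvent.v1_at(T), solvent.alpha_P, T)
    else:
        logger.warning(
            "attraction parameter missing for %s/%s: attraction channel zero-filled",
            solvent.species.name,
            solute.name or "solute",
        )
        attraction = AttractionThermo(dG_a=0.0, dH_a=0.0, dS_a=0.0, T=T)
    return SolvationThermo(
        dG_star=cavity.dG_c + attraction.dG_a,
        cavity=cavity,
        attraction=attraction,
        attraction_present=present,
    )


def solvation_dG_from_densities(rho2_gas: float, rho2_liq: float, T: float) -> float:
    """ΔG• (kJ mol⁻¹) from the equilibrium solute number densities.

    ``ΔG• = RT·ln(ρ2_gas/ρ2_liq)``: the Ben-Naim solvation free energy is
    directly the log density ratio between the coexisting phases, which is
    how it is extracted from experiment.  Any common density unit works.
    """
    if rho2_gas <= 0.0 or rho2_liq <= 0.0:
        raise DomainError(f"densities must be > 0, got {rho2_gas}, {rho2_liq}")
    if T <= 0.0:
        raise DomainError(f"temperature must be > 0, got {T}")
    return R * T * math.log(rho2_gas / rho2_liq) / 1.0e3


def density_ratio_from_dG(dG_star: float, T: float) -> float:
    """Inverse of :func:`solvation_dG_from_densities`: ρ2_gas/ρ2_liq."""
    if T <= 0.0:
        raise DomainError(f"temperature must be > 0, got {T}")
    return math.exp(dG_star * 1.0e3 / (R * T))


def liberation_free_energy(Vm_from: float, Vm_to: float, T: float) -> float:
    """Molar-volume (liberation) free energy, RT·ln(Vm_from/Vm_to), kJ mol⁻¹.

    This is the contribution that the Ben-Naim solvation convention removes:
    e.g. ideal gas at 1 atm and 298.15 K → water (18.07 cm³ mol⁻¹) gives
    17.87 kJ mol⁻¹.  Use :func:`vdwsolv.constants.ideal_gas_molar_volume`
    for gas-phase endpoints.
    """
    if Vm_from <= 0.0 or Vm_to <= 0.0:
        raise DomainError(f"molar volumes must be > 0, got {Vm_from}, {Vm_to}")
    if T <= 0.0:
        raise DomainError(f"temperature must be > 0, got {T}")
    return R * T * math.log(Vm_from / Vm_to) / 1.0e3


def kinetic_pressure(v1: float, b1_molar: float, T: float) -> float:
    """Kinetic part of the van der Waals pressure, RT/(v1−b1), in Pa.

    ``v1`` and ``b1_molar`` in cm³ mol⁻¹.  Multiplying by the solute's molar
    volume parameter reproduces the pressure–volume term of the cavity work
    exactly, which is the interpretation of that term: the work of pushing
    the free volume aside at the enormous kinetic pressure of a dense liquid
    (thousands of atm).
    """
    if T <= 0.0:
        raise DomainError(f"temperature must be > 0, got {T}")
    if v1 <= b1_molar:
        raise OverpackedLiquidError(
            f"molar volume {v1} cm³/mol does not exceed molar b {b1_molar} cm³/mol"
        )
    # J mol⁻¹ / (cm³ mol⁻¹) = J cm⁻³ = MPa → Pa
    return R * T / (v1 - b1_molar) * 1.0e6


def temperature_scan(
    solvent: SolventState, solute: SpeciesSpec, T_grid
) -> pd.DataFrame:
    """Solvation thermodynamics over a temperature grid, one row per T.

    Returns a DataFrame with columns T, dG_c, dH_c, dS_c, dS_x, dS_nx,
    dG_a, dH_a, dS_a, dG_star (kJ mol⁻¹ / J K⁻¹ mol⁻¹ as elsewhere).
    """
    rows = []
    for T in T_grid:
        try:
            res = solvation_free_energy(solvent, solute, float(T))
        except OverpackedLiquidError as exc:
            raise OverpackedLiquidError(
                f"{solvent.species.name} is overpacked at T = {T} K: {exc}"
            ) from exc
        rows.append(
            {
                "T": float(T),
                "dG_c": res.cavity.dG_c,
                "dH_c": res.cavity.dH_c,
                "dS_c": res.cavity.dS_c,
                "dS_x": res.cavity.dS_x,
                "dS_nx": res.cavity.dS_nx,
                "dG_a": res.attraction.dG_a,
                "dH_a": res.attraction.dH_a,
                "dS_a": res.attraction.dS_a,
                "dG_star": res.dG_star,
            }
        )
    return pd.DataFrame(rows)
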