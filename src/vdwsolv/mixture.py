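"""Finite-composition binary van der Waals solution.

The canonical partition function of a binary mixture of monoatomic van der
Waals particles factorises into ideal translational motion in the free
volume ``V − (b₁N₁ + b₂N₂)`` plus a constant attractive background energy
``−(√a₁N₁ + √a₂N₂)²/V``.  The Helmholtz free energy follows directly, and
its analytic composition derivative gives the chemical potential of the
solute,

    μ₂ = kT·ln(ρ₂Λ₂³) + μ₂•,

whose non-translational part μ₂• (the Ben-Naim standard chemical potential,
i.e. the coupling work of a particle fixed in the solution) depends on the
full composition.  In the infinite-dilution limit μ₂• reduces to the
closed-form solvation free energy of :mod:`vdwsolv.core`; at finite
composition it does not, which is the point of carrying the mixture
explicitly.

Particle numbers are treated as continuous with Stirling's approximation
(ln N! ≈ N·ln N − N), which is what makes the ∂A/∂N₂ derivative
well-defined.  Units here are per-molecule: volumes in Å³, energies in J;
attraction parameters are converted from the molar kJ cm³ mol⁻² convention
of :class:`vdwsolv.core.SpeciesSpec` internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .constants import K_B, a_molecular_from_molar, thermal_wavelength_A
from .core import SpeciesSpec
from .errors import DomainError, OverpackedLiquidError

__all__ = [
    "MixtureState",
    "HelmholtzParts",
    "Mu2Result",
    "helmholtz_free_energy",
    "pressure",
    "chemical_potential_2",
    "chemical_potential_1",
    "numeric_mu2",
    "dilute_solution_state",
]


def _require(species: SpeciesSpec, what: str) -> None:
    if species.b is None:
        raise DomainError(f"{species.name or what}: per-molecule b required")
    if species.a_attr is None:
        raise DomainError(f"{species.name or what}: attraction parameter required")


@dataclass(frozen=True)
class MixtureState:
    """A binary van der Waals solution at (N₁, N₂, V, T).

    Particle counts are continuous nonnegative reals; ``V`` is in Å³ and
    must exceed the occupied volume ``b₁N₁ + b₂N₂``.  Both species need
    ``b`` and ``a_attr``; masses are needed only for absolute free energies
    and total chemical potentials.
    """

    species1: SpeciesSpec
    species2: SpeciesSpec
    N1: float
    N2: float
    V: float
    T: float

    def __post_init__(self) -> None:
        _require(self.species1, "species1")
        _require(self.species2, "species2")
        if self.N1 < 0.0 or self.N2 < 0.0 or (self.N1 == 0.0 and self.N2 == 0.0):
            raise DomainError(f"need N1, N2 >= 0 and not both zero, got {self.N1}, {self.N2}")
        if self.T <= 0.0:
            raise DomainError(f"temperature must be > 0, got {self.T}")
        if self.free_volume <= 0.0:
            raise OverpackedLiquidError(
                f"V = {self.V} Å³ does not exceed occupied volume "
                f"b1·N1 + b2·N2 = {self.V - self.free_volume} Å³"
            )

    @property
    def free_volume(self) -> float:
        return self.V - self.species1.b * self.N1 - self.species2.b * self.N2

    @property
    def _sqrt_a_sum(self) -> float:
        a1 = a_molecular_from_molar(self.species1.a_attr)
        a2 = a_molecular_from_molar(self.species2.a_attr)
        return math.sqrt(a1) * self.N1 + math.sqrt(a2) * self.N2


@dataclass(frozen=True)
class HelmholtzParts:
    """Helmholtz free energy split: mass-independent excess vs ideal
    translational part (J).  ``ideal`` and ``total`` are None when a mass
    is missing."""

    excess: float
    ideal: float | None
    total: float | None


@dataclass(frozen=True)
class Mu2Result:
    """Chemical potential of the solute (J per molecule).  ``total`` is
    None when it was not computable (N₂ = 0 or missing mass)."""

    star: float
    total: float | None


def helmholtz_free_energy(state: MixtureState) -> HelmholtzParts:
    """A = −kT·ln Q, split into ideal-translational and excess parts.

    The excess part, ``−kT·(N₁+N₂)·ln(V_free/V) − (√a₁N₁+√a₂N₂)²/V``, is
    mass-independent; the second term is exactly the attractive potential
    energy.  The ideal part, ``kT·Σᵢ Nᵢ(ln(NᵢΛᵢ³/V) − 1)`` with Stirling's
    approximation, needs masses for the thermal wavelengths Λᵢ.
    """
    kT = K_B * state.T
    n_tot = state.N1 + state.N2
    excess = -kT * n_tot * math.log(state.free_volume / state.V)
    excess -= state._sqrt_a_sum**2 / state.V

    ideal: float | None = None
    if state.species1.mass is not None and state.species2.mass is not None:
        ideal = 0.0
        for sp, N in ((state.species1, state.N1), (state.species2, state.N2)):
            if N > 0.0:
                lam = thermal_wavelength_A(sp.mass, state.T)
                ideal += kT * N * (math.log(N * lam**3 / state.V) - 1.0)
    total = None if ideal is None else ideal + excess
    return HelmholtzParts(excess=excess, ideal=ideal, total=total)


def pressure(state: MixtureState) -> float:
    """Van der Waals equation-of-state pressure −∂A/∂V, in J Å⁻³.

    ``P = (N₁+N₂)kT/V_free − (√a₁N₁+√a₂N₂)²/V²``.
    """
    kT = K_B * state.T
    return (state.N1 + state.N2) * kT / state.free_volume - state._sqrt_a_sum**2 / state.V**2


def chemical_potential_2(state: MixtureState) -> Mu2Result:
    """Analytic chemical potential of component 2, per molecule (J).

    The Ben-Naim standard part is

        μ₂• = −kT·ln(V_free/V) + kT·(N₁+N₂)·b₂/V_free − 2√a₂·(√a₁N₁+√a₂N₂)/V

    and the total adds the translational term kT·ln(ρ₂Λ₂³), defined only
    for N₂ > 0 and a known solute mass.
    """
    kT = K_B * state.T
    b2 = state.species2.b
    a2 = a_molecular_from_molar(state.species2.a_attr)
    star = (
        -kT * math.log(state.free_volume / state.V)
        + kT * (state.N1 + state.N2) * b2 / state.free_volume
        - 2.0 * math.sqrt(a2) * state._sqrt_a_sum / state.V
    )
    total: float | None = None
    if state.N2 > 0.0 and state.species2.mass is not None:
        lam = thermal_wavelength_A(state.species2.mass, state.T)
        total = kT * math.log(state.N2 / state.V * lam**3) + star
    return Mu2Result(star=star, total=total)


def chemical_potential_1(state: MixtureState) -> Mu2Result:
    """Chemical potential of component 1, by 1↔2 label symmetry."""
    swapped = MixtureState(
        species1=state.species2,
        species2=state.species1,
        N1=state.N2,
        N2=state.N1,
        V=state.V,
        T=state.T,
    )
    return chemical_potential_2(swapped)


def numeric_mu2(state: MixtureState, delta: float | None = None) -> float:
    """Central-difference μ₂ = ∂A/∂N₂ at fixed T, V, N₁ (J per molecule).

    ``delta`` defaults to 10⁻⁶·(N₁+N₂); it must satisfy 0 < delta < N₂.
    Requires masses (the derivative is taken on the total free energy).
    """
    if delta is None:
        delta = 1.0e-6 * (state.N1 + state.N2)
    if delta <= 0.0:
        raise DomainError(f"step must be positive, got {delta}")
    if state.N2 - delta <= 0.0:
        raise DomainError(f"step {delta} too large for N2 = {state.N2}")
    a_plus = helmholtz_free_energy(replace(state, N2=state.N2 + delta)).total
    a_minus = helmholtz_free_energy(replace(state, N2=state.N2 - delta)).total
    if a_plus is None or a_minus is None:
        raise DomainError("numeric_mu2 needs masses on both species")
    return (a_plus - a_minus) / (2.0 * delta)


def dilute_solution_state(
    solvent_species: SpeciesSpec,
    solute_species: SpeciesSpec,
    v1_molecular: float,
    T: float,
    x2: float = 1.0e-9,
    N_total: float = 1.0e6,
) -> MixtureState:
    """Build a MixtureState at solute mole fraction ``x2``.

    ``v1_molecular`` is the solvent per-molecule volume in Å³; the system
    volume is set to ``N₁·v1_molecular``, the convention under which the
    infinite-dilution limit of μ₂• reproduces the closed-form solvation
    free energy.
    """
    if not 0.0 <= x2 < 1.0:
        raise DomainError(f"mole fraction must be in [0, 1), got {x2}")
    N2 = x2 * N_total
    N1 = N_total - N2
    return MixtureState(
        species1=solvent_species,
        species2=solute_species,
        N1=N1,
        N2=N2,
        V=N1 * v1_molecular,
        T=T,
    )
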