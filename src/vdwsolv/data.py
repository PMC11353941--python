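"""Built-in solvent dataset, delimited-file I/O, and a synthetic fixture
generator for property tests.

The built-in table holds the experimental molar volumes, isobaric expansion
coefficients and effective hard-sphere diameters (at 25 °C, 1 atm) of the
eight liquids commonly used to contrast water with organic solvents:
water, methanol, ethanol, carbon tetrachloride, n-hexane, n-decane,
cyclohexane and benzene.  ``REFERENCE_CAVITY`` carries the corresponding
published cavity-thermodynamics values for a 4 Å solute, used by the
comparison harness in :mod:`vdwsolv.report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import N_AV
from .core import SolventState, SpeciesSpec, hard_sphere_b
from .errors import DomainError

__all__ = [
    "SolventRecord",
    "builtin_solvents",
    "get_solvent",
    "solvent_state",
    "read_solvent_table",
    "write_solvent_table",
    "fixture_generator",
    "REFERENCE_CAVITY",
]

CSV_COLUMNS = ["name", "sigma_A", "v1_cm3_mol", "alpha_P_per_K"]
CSV_OPTIONAL = ["a_attr"]


@dataclass(frozen=True)
class SolventRecord:
    """One liquid's experimental properties at 25 °C and 1 atm.

    ``alpha_P_e3`` is the expansion coefficient in 10⁻³ K⁻¹ as customarily
    tabulated; ``b1_printed`` the tabulated repulsive volume parameter (Å³),
    which must agree with ``(πσ³/6)/0.64`` to 0.1 Å³.
    """

    name: str
    sigma: float
    v1: float
    alpha_P_e3: float
    b1_printed: float
    reference: str = "builtin-table"
    a_attr: float | None = None
    # exact K⁻¹ value from file input, kept so write→read is bit-lossless
    alpha_P_exact: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0.0:
            raise DomainError(f"{self.name}: sigma must be > 0, got {self.sigma}")
        if self.v1 <= 0.0:
            raise DomainError(f"{self.name}: v1 must be > 0, got {self.v1}")
        if abs(hard_sphere_b(self.sigma) - self.b1_printed) > 0.1:
            raise DomainError(
                f"{self.name}: b1 = {self.b1_printed} Å³ inconsistent with "
                f"(πσ³/6)/0.64 = {hard_sphere_b(self.sigma):.2f} Å³"
            )

    @property
    def alpha_P(self) -> float:
        """Expansion coefficient in K⁻¹."""
        if self.alpha_P_exact is not None:
            return self.alpha_P_exact
        return self.alpha_P_e3 * 1.0e-3


# name, sigma (Å), v1 (cm³/mol), alpha_P (1e-3 K⁻¹), b1 (Å³)
_BUILTIN = (
    ("water", 2.80, 18.07, 0.257, 18.0),
    ("methanol", 3.83, 40.73, 1.189, 46.0),
    ("ethanol", 4.44, 58.68, 1.089, 71.6),
    ("CCl4", 5.37, 97.09, 1.226, 126.7),
    ("n-hexane", 5.92, 131.62, 1.390, 169.7),
    ("n-decane", 7.08, 195.94, 1.020, 290.3),
    ("c-hexane", 5.63, 108.75, 1.214, 146.0),
    ("benzene", 5.26, 89.40, 1.240, 119.1),
)

# Published cavity thermodynamics for a 4 Å diameter solute at 298.15 K in
# each of the eight liquids: dG_c, dH_c (kJ/mol); dS_c, dS_x, dH_c/T (J/K/mol).
REFERENCE_CAVITY = {
    "water": {"dG_c": 13.0, "dH_c": 2.3, "dS_c": -35.9, "dS_x": -43.6, "dS_nx": 7.7},
    "methanol": {"dG_c": 8.8, "dH_c": 8.5, "dS_c": -1.0, "dS_x": -29.5, "dS_nx": 28.5},
    "ethanol": {"dG_c": 8.3, "dH_c": 8.4, "dS_c": 0.4, "dS_x": -27.8, "dS_nx": 28.2},
    "CCl4": {"dG_c": 7.6, "dH_c": 9.7, "dS_c": 7.0, "dS_x": -25.5, "dS_nx": 32.5},
    "n-hexane": {"dG_c": 6.5, "dH_c": 8.8, "dS_c": 7.7, "dS_x": -21.8, "dS_nx": 29.5},
    "n-decane": {"dG_c": 9.2, "dH_c": 16.5, "dS_c": 24.4, "dS_x": -30.9, "dS_nx": 55.3},
    "c-hexane": {"dG_c": 7.9, "dH_c": 10.9, "dS_c": 10.1, "dS_x": -26.5, "dS_nx": 36.6},
    "benzene": {"dG_c": 8.5, "dH_c": 12.0, "dS_c": 11.7, "dS_x": -28.5, "dS_nx": 40.2},
}


def builtin_solvents() -> list[SolventRecord]:
    """The eight built-in liquids with their tabulated properties."""
    return [
        SolventRecord(name=n, sigma=s, v1=v, alpha_P_e3=a, b1_printed=b)
        for n, s, v, a, b in _BUILTIN
    ]


def get_solvent(name: str) -> SolventRecord:
    """Look up a built-in solvent by (case-insensitive) name."""
    for rec in builtin_solvents():
        if rec.name.lower() == name.lower():
            return rec
    known = ", ".join(n for n, *_ in _BUILTIN)
    raise KeyError(f"unknown solvent {name!r}; built-in liquids: {known}")


def solvent_state(record: SolventRecord, T_ref: float = 298.15) -> SolventState:
    """A :class:`SolventState` from a record (b from σ at full precision)."""
    species = SpeciesSpec(name=record.name, sigma=record.sigma, a_attr=record.a_attr)
    return SolventState(species=species, v1=record.v1, alpha_P=record.alpha_P, T_ref=T_ref)


def read_solvent_table(path) -> list[SolventRecord]:
    """Read a delimited solvent table.

    Expected header: ``name,sigma_A,v1_cm3_mol,alpha_P_per_K`` with an
    optional ``a_attr`` column (kJ cm³ mol⁻²).  ``b1`` is recomputed from
    sigma.  Malformed headers or cells raise a parse error naming the row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing required column(s) {missing}; header must "
                          f"contain {CSV_COLUMNS}")
    records = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            sigma = float(row["sigma_A"])
            v1 = float(row["v1_cm3_mol"])
            alpha = float(row["alpha_P_per_K"])
            a_attr = None
            if "a_attr" in df.columns and not pd.isna(row["a_attr"]):
                a_attr = float(row["a_attr"])
        except (TypeError, ValueError) as exc:
            raise DomainError(f"{path}: non-numeric cell in row {rowno}: {exc}") from exc
        if not all(math.isfinite(x) for x in (sigma, v1, alpha)):
            raise DomainError(f"{path}: non-finite value in row {rowno}")
        try:
            records.append(
                SolventRecord(
                    name=str(row["name"]),
                    sigma=sigma,
                    v1=v1,
                    alpha_P_e3=alpha * 1.0e3,
                    b1_printed=round(hard_sphere_b(sigma), 1),
                    reference=str(path),
                    a_attr=a_attr,
                    alpha_P_exact=alpha,
                )
            )
        except DomainError as exc:
            raise DomainError(f"{path}: invalid row {rowno}: {exc}") from exc
    return records


def write_solvent_table(records: list[SolventRecord], path) -> None:
    """Write records as CSV at full precision (lossless round-trip)."""
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "sigma_A": [repr(r.sigma) for r in records],
            "v1_cm3_mol": [repr(r.v1) for r in records],
            "alpha_P_per_K": [repr(r.alpha_P) for r in records],
            "a_attr": ["" if r.a_attr is None else repr(r.a_attr) for r in records],
        }
    )
    df.to_csv(path, index=False)


def fixture_generator(
    seed: int, n: int, with_mass: bool = True
) -> list[tuple[SolventState, SpeciesSpec]]:
    """Deterministic synthetic (solvent, solute) pairs for property tests.

    Draws σ ∈ [2, 8] Å, packing fraction ξ₁ ∈ [0.3, 0.95] (v₁ derived),
    α_P ∈ [0, 2·10⁻³] K⁻¹ and a_attr ∈ [0, 10⁶] kJ cm³ mol⁻² for both
    species; masses span light gases to small organics.  Every pair
    satisfies the type invariants by construction.
    """
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        sigma1 = rng.uniform(2.0, 8.0)
        b1 = hard_sphere_b(sigma1)
        xi1 = rng.uniform(0.3, 0.95)
        # v1 chosen so that rho1*b1 == xi1
        v1 = N_AV * b1 / (xi1 * 1.0e24)
        alpha = rng.uniform(0.0, 2.0e-3)
        a1 = rng.uniform(0.0, 1.0e6)
        sigma2 = rng.uniform(2.0, 8.0)
        a2 = rng.uniform(0.0, 1.0e6)
        m1 = rng.uniform(3.0e-26, 3.0e-25) if with_mass else None
        m2 = rng.uniform(3.0e-26, 3.0e-25) if with_mass else None
        solvent = SolventState(
            species=SpeciesSpec(name="synthetic-solvent", sigma=sigma1, a_attr=a1, mass=m1),
            v1=v1,
            alpha_P=alpha,
        )
        solute = SpeciesSpec(name="synthetic-solute", sigma=sigma2, a_attr=a2, mass=m2)
        pairs.append((solvent, solute))
    return pairs
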