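"""Unit tests for the closed-form solvation thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdwsolv import (
    DomainError,
    OverpackedLiquidError,
    SolventState,
    SpeciesSpec,
    attraction_thermodynamics,
    cavity_thermodynamics,
    density_ratio_from_dG,
    get_solvent,
    hard_sphere_b,
    ideal_gas_molar_volume,
    kinetic_pressure,
    liberation_free_energy,
    molar_volume_at_T,
    solvation_dG_from_densities,
    solvation_free_energy,
    solvent_state,
    temperature_scan,
)
from vdwsolv.constants import ATM_PA, N_AV, R, b_molar_cm3


class TestHardSphereB:
    @pytest.mark.parametrize(
        "sigma, expected_1dp",
        [(4.0, 52.4), (2.80, 18.0), (0.0, 0.0)],
    )
    def test_random_close_packing_convention(self, sigma, expected_1dp):
        assert round(hard_sphere_b(sigma), 1) == pytest.approx(expected_1dp)

    def test_negative_diameter_rejected(self):
        with pytest.raises(DomainError):
            hard_sphere_b(-1.0)


class TestMolarVolumeAtT:
    def test_identity_at_reference(self):
        assert molar_volume_at_T(18.07, 0.5e-3, 298.15, 298.15) == 18.07

    def test_zero_expansivity(self):
        assert molar_volume_at_T(100.0, 0.0, 298.15, 350.0) == 100.0

    def test_exponential_closed_form(self):
        # 100·exp(1e-3 · 10) evaluated independently
        assert molar_volume_at_T(100.0, 1.0e-3, 298.15, 308.15) == pytest.approx(
            101.00501670841679, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            molar_volume_at_T(-1.0, 0.0, 298.15, 300.0)
        with pytest.raises(DomainError):
            molar_volume_at_T(10.0, 0.0, 298.15, -5.0)


class TestCavity:
    def test_water_xenon_reference_row(self, water):
        cav = cavity_thermodynamics(water, hard_sphere_b(4.0), 298.15)
        assert cav.dG_c == pytest.approx(13.0, abs=0.2)
        assert cav.dH_c == pytest.approx(2.3, abs=0.2)
        assert cav.dS_c == pytest.approx(-35.9, abs=1.2)

    def test_methanol_reference_row(self):
        cav = cavity_thermodynamics(
            solvent_state(get_solvent("methanol")), hard_sphere_b(4.0), 298.15
        )
        assert cav.dG_c == pytest.approx(8.8, abs=0.2)
        assert cav.dH_c == pytest.approx(8.5, abs=0.2)

    def test_point_particles_cost_nothing(self):
        solvent = SolventState(
            species=SpeciesSpec(name="ideal", sigma=0.0), v1=20.0, alpha_P=1e-3
        )
        cav = cavity_thermodynamics(solvent, 0.0, 298.15)
        assert cav.dG_c == cav.dH_c == cav.dS_c == 0.0

    def test_overpacked_error_names_packing_product(self):
        # xi just below 1 at T_ref; cooling increases the density past packing
        b1 = hard_sphere_b(8.0)
        v1 = N_AV * b1 / (0.99 * 1e24)
        solvent = SolventState(
            species=SpeciesSpec(name="dense", sigma=8.0), v1=v1, alpha_P=2.0e-3
        )
        with pytest.raises(OverpackedLiquidError, match=r"ρ1·b1"):
            cavity_thermodynamics(solvent, 10.0, 270.0)

    def test_negative_b2_rejected(self, water):
        with pytest.raises(DomainError):
            cavity_thermodynamics(water, -5.0, 298.15)


class TestAttraction:
    def test_no_solute_attraction(self):
        res = attraction_thermodynamics(5.0e5, 0.0, 50.0, 1e-3, 298.15)
        assert res.dG_a == res.dH_a == res.dS_a == 0.0

    def test_direct_substitution_zero_expansivity(self):
        # sqrt(a1·a2) = 1000 kJ cm³/mol², v1 = 100 cm³/mol
        res = attraction_thermodynamics(1.0e6, 1.0, 100.0, 0.0, 298.15)
        assert res.dG_a == pytest.approx(-20.0, rel=1e-12)
        assert res.dH_a == pytest.approx(-20.0, rel=1e-12)
        assert res.dS_a == 0.0

    def test_gibbs_helmholtz_identity_vs_symbolic(self):
        """dH_a − T·dS_a = dG_a, cross-checked against an independent
        symbolic differentiation of ΔG_a(T) = −2√(a1a2)/v1(T)."""
        import sympy as sp

        a1s, a2s, vr, al, Tr, Ts = sp.symbols(
            "a1 a2 v_ref alpha T_ref T", positive=True
        )
        dG = -2 * sp.sqrt(a1s * a2s) / (vr * sp.exp(al * (Ts - Tr)))
        dS = -sp.diff(dG, Ts)
        dH = sp.simplify(dG + Ts * dS)
        subs = {a1s: 4.0e5, a2s: 2.5e5, vr: 75.0, al: 1.1e-3, Tr: 298.15, Ts: 320.0}
        v_at_T = float(vr.subs(subs) * sp.exp(al * (Ts - Tr)).subs(subs))
        res = attraction_thermodynamics(4.0e5, 2.5e5, v_at_T, 1.1e-3, 320.0)
        assert res.dG_a == pytest.approx(float(dG.subs(subs)), rel=1e-12)
        assert res.dS_a == pytest.approx(float(dS.subs(subs)) * 1e3, rel=1e-12)
        assert res.dH_a == pytest.approx(float(dH.subs(subs)), rel=1e-12)
        assert res.dH_a - 320.0 * res.dS_a / 1e3 - res.dG_a == pytest.approx(0.0, abs=1e-12)

    def test_negative_parameter_rejected(self):
        with pytest.raises(DomainError):
            attraction_thermodynamics(-1.0, 1.0, 50.0, 0.0, 298.15)


class TestSolvation:
    def test_water_xenon_without_attraction(self, water, xenon):
        res = solvation_free_energy(water, xenon, 298.15)
        assert not res.attraction_present
        assert res.attraction.dG_a == 0.0
        assert res.dG_star == res.cavity.dG_c == pytest.approx(13.0, abs=0.2)

    def test_self_solvation_attraction(self):
        a1 = 3.0e5
        sp = SpeciesSpec(name="self", sigma=4.0, a_attr=a1)
        solvent = SolventState(species=sp, v1=80.0, alpha_P=1e-3)
        res = solvation_free_energy(solvent, sp, 298.15)
        assert res.attraction.dG_a == pytest.approx(-2.0 * a1 / 80.0, rel=1e-12)

    def test_additivity(self, generated_pairs):
        for solvent, solute in generated_pairs[:50]:
            res = solvation_free_energy(solvent, solute, 310.0)
            assert res.dG_star == pytest.approx(
                res.cavity.dG_c + res.attraction.dG_a, rel=1e-12
            )

    def test_per_molecule_form_matches_molar(self, generated_pairs):
        """Per-molecule coupling work −kT·ln((v1−b1)/v1) + kT·b2/(v1−b1)
        − 2√(a1a2)/v1 agrees with the molar assembly after unit conversion."""
        from vdwsolv.constants import (
            K_B,
            a_molecular_from_molar,
            molecule_volume_A3,
        )

        T = 298.15
        for solvent, solute in generated_pairs[:50]:
            kT = K_B * T
            v1 = molecule_volume_A3(solvent.v1_at(T))
            b1, b2 = solvent.species.b, solute.b
            a1 = a_molecular_from_molar(solvent.species.a_attr)
            a2 = a_molecular_from_molar(solute.a_attr)
            per_molecule = (
                -kT * math.log((v1 - b1) / v1)
                + kT * b2 / (v1 - b1)
                - 2.0 * math.sqrt(a1 * a2) / v1
            )
            molar = solvation_free_energy(solvent, solute, T).dG_star
            assert molar == pytest.approx(per_molecule * N_AV / 1e3, rel=1e-10)


class TestDensityRatio:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        rho_g=st.floats(min_value=1e-6, max_value=1e3),
        rho_l=st.floats(min_value=1e-6, max_value=1e3),
        T=st.floats(min_value=150.0, max_value=600.0),
    )
    def test_round_trip_is_inverse_pair(self, rho_g, rho_l, T):
        dG = solvation_dG_from_densities(rho_g, rho_l, T)
        assert density_ratio_from_dG(dG, T) == pytest.approx(rho_g / rho_l, rel=1e-9)

    def test_equal_densities(self):
        assert solvation_dG_from_densities(3.0, 3.0, 298.15) == 0.0

    def test_ratio_e_gives_RT(self):
        assert solvation_dG_from_densities(math.e, 1.0, 298.15) == pytest.approx(
            R * 298.15 / 1e3, rel=1e-12
        )

    def test_round_trip(self):
        dG = solvation_dG_from_densities(0.7, 2.1, 310.0)
        assert density_ratio_from_dG(dG, 310.0) == pytest.approx(0.7 / 2.1, rel=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(DomainError):
            solvation_dG_from_densities(0.0, 1.0, 298.15)


class TestLiberation:
    def test_ideal_gas_to_water(self):
        vm_gas = ideal_gas_molar_volume(298.15, 1.0)
        assert liberation_free_energy(vm_gas, 18.07, 298.15) == pytest.approx(
            17.87, abs=0.01
        )

    def test_hexane_to_water(self):
        assert liberation_free_energy(131.62, 18.07, 298.15) == pytest.approx(
            4.92, abs=0.01
        )

    def test_no_volume_change(self):
        assert liberation_free_energy(55.0, 55.0, 298.15) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            liberation_free_energy(-1.0, 18.07, 298.15)


class TestKineticPressure:
    def test_matches_cavity_pressure_volume_term(self, water):
        """P_kin · b2 reproduces the second cavity-work term exactly."""
        T = 298.15
        b1_molar = b_molar_cm3(water.species.b)
        b2_molar = b_molar_cm3(hard_sphere_b(4.0))
        p = kinetic_pressure(water.v1, b1_molar, T)  # Pa
        work = p * b2_molar * 1e-6 / 1e3  # Pa·cm³/mol → kJ/mol
        expected = R * T * b2_molar / (water.v1 - b1_molar) / 1e3
        assert work == pytest.approx(expected, rel=1e-12)

    def test_ideal_gas_limit(self):
        assert kinetic_pressure(100.0, 0.0, 298.15) == pytest.approx(
            R * 298.15 / 100.0 * 1e6, rel=1e-12
        )

    def test_water_kinetic_pressure_is_thousands_of_atm(self, water):
        p = kinetic_pressure(water.v1, b_molar_cm3(water.species.b), 298.15)
        assert p / ATM_PA > 1000.0

    def test_overpacked_rejected(self):
        with pytest.raises(OverpackedLiquidError):
            kinetic_pressure(10.0, 12.0, 298.15)


class TestTemperatureScan:
    def test_single_point_equals_direct_call(self, water, xenon):
        df = temperature_scan(water, xenon, [298.15])
        direct = solvation_free_energy(water, xenon, 298.15)
        assert df.loc[0, "dG_c"] == direct.cavity.dG_c
        assert df.loc[0, "dS_a"] == direct.attraction.dS_a

    def test_zero_expansivity_means_zero_cavity_enthalpy(self):
        solvent = SolventState(
            species=SpeciesSpec(name="rigid", sigma=4.0), v1=120.0, alpha_P=0.0
        )
        df = temperature_scan(solvent, SpeciesSpec(sigma=3.0), [280.0, 300.0, 350.0])
        assert (df["dH_c"] == 0.0).all()

    def test_water_cavity_entropy_monotonic_in_T(self, water, xenon):
        grid = np.arange(278.0, 368.01, 5.0)
        df = temperature_scan(water, xenon, grid)
        assert (np.diff(df["dS_c"].to_numpy()) > 0).all()

    def test_entropy_matches_finite_difference_of_free_energy(self, water, xenon):
        grid = np.arange(290.0, 310.01, 0.1)
        df = temperature_scan(water, xenon, grid)
        for col_G, col_S in (("dG_c", "dS_c"), ("dG_star", "dS_c")):
            g = df[col_G].to_numpy() * 1e3
            s = df[col_S].to_numpy()
            fd = -(g[2:] - g[:-2]) / (2 * 0.1)
            np.testing.assert_allclose(fd, s[1:-1], rtol=1e-4)

    def test_overpacked_grid_point_names_temperature(self):
        b1 = hard_sphere_b(8.0)
        v1 = N_AV * b1 / (0.99 * 1e24)
        solvent = SolventState(
            species=SpeciesSpec(name="dense", sigma=8.0), v1=v1, alpha_P=2.0e-3
        )
        with pytest.raises(OverpackedLiquidError, match="270"):
            temperature_scan(solvent, SpeciesSpec(sigma=3.0), [320.0, 270.0])


class TestSpeciesValidation:
    def test_b_autoderived_from_sigma(self):
        sp = SpeciesSpec(sigma=4.0)
        assert sp.b == pytest.approx(hard_sphere_b(4.0))

    def test_inconsistent_b_sigma_rejected(self):
        with pytest.raises(DomainError):
            SpeciesSpec(sigma=4.0, b=60.0)

    def test_negative_alpha_accepted_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="vdwsolv.core"):
            SolventState(
                species=SpeciesSpec(name="cold-water", sigma=2.80),
                v1=18.02,
                alpha_P=-0.07e-3,
                T_ref=275.15,
            )
        assert any("negative alpha_P" in m for m in caplog.messages)
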