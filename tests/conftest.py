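import numpy as np
import pytest

from vdwsolv import SolventState, SpeciesSpec, get_solvent, solvent_state
from vdwsolv.mixture import MixtureState


@pytest.fixture(scope="session")
def water():
    return solvent_state(get_solvent("water"))


@pytest.fixture(scope="session")
def xenon():
    return SpeciesSpec(name="xenon", sigma=4.0, mass=2.18e-25)


@pytest.fixture(scope="session")
def generated_pairs():
    """1000 deterministic synthetic (solvent, solute) pairs."""
    from vdwsolv import fixture_generator

    return fixture_generator(seed=20240822, n=1000)


def random_mixture_states(seed: int, n: int) -> list[MixtureState]:
    """Valid finite-composition states with masses, for derivative oracles."""
    rng = np.random.default_rng(seed)
    from vdwsolv import fixture_generator

    states = []
    for solvent, solute in fixture_generator(seed=seed, n=n):
        x2 = rng.uniform(0.05, 0.5)
        N = 1.0e5
        N2 = x2 * N
        N1 = N - N2
        occupied = solvent.species.b * N1 + solute.b * N2
        V = occupied / rng.uniform(0.3, 0.9)
        states.append(
            MixtureState(
                species1=solvent.species,
                species2=solute,
                N1=N1,
                N2=N2,
                V=V,
                T=rng.uniform(250.0, 400.0),
            )
        )
    return states
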