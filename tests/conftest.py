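import numpy as np
import pytest

import mucoflow as mf


def solve(scenario, **kwargs):
    return mf.solve_gauss_seidel(scenario.fields, scenario.grid, mf.SolverOptions(**kwargs))


@pytest.fixture(scope="session")
def antrum():
    """Borderline scenario and its converged solution."""
    sc = mf.scenario_antrum_borderline()
    return sc, solve(sc)


@pytest.fixture(scope="session")
def antrum_uniform_omega():
    """Borderline scenario with corpus omega lowered to the antral level."""
    sc = mf.scenario_antrum_borderline({"omega_corpus": 1.0})
    return sc, solve(sc)


@pytest.fixture(scope="session")
def cardia():
    sc = mf.scenario_cardia()
    return sc, solve(sc)


@pytest.fixture(scope="session")
def linear_ulcer():
    sc = mf.scenario_linear_ulcer()
    return sc, solve(sc)


@pytest.fixture(scope="session")
def watershed_solutions():
    """The demand ramp: omega -> (scenario, solution)."""
    out = {}
    for omega in (1.0, 10.0, 100.0):
        sc = mf.scenario_watershed(omega)
        out[omega] = (sc, solve(sc))
    return out


@pytest.fixture(scope="session")
def necrosis_pre():
    sc = mf.scenario_necrosis("pre")
    return sc, solve(sc)


@pytest.fixture(scope="session")
def necrosis_post():
    sc = mf.scenario_necrosis("post")
    return sc, solve(sc)


@pytest.fixture(scope="session")
def random_instances():
    """50 seeded random instances (grids up to 20x20) solved both ways."""
    instances = []
    for seed in range(50):
        rng = np.random.default_rng(10_000 + seed)
        nx, ny = int(rng.integers(2, 21)), int(rng.integers(2, 21))
        sc = mf.random_fixture(seed, nx, ny)
        gs = solve(sc)
        direct = mf.solve_direct(mf.assemble_system(sc.fields, sc.grid))
        instances.append((sc, gs, direct))
    return instances
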