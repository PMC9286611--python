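import numpy as np
import pytest

from scrhybrid import MCMCConfig, ModelSpec, SimulationScenario, StateSpace, simulate


@pytest.fixture(scope="session")
def small_scenario():
    """A light scenario for fast end-to-end fits in unit tests."""
    return SimulationScenario(
        N=20,
        state_space=StateSpace(0.0, 10000.0, 0.0, 10000.0),
        camera_nx=5, camera_ny=5,
        trap_nx=3, trap_ny=3,
        cell_nx=5, cell_ny=5,
        n_occasions=5,
        n_fixes=30,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    bundle, truth = simulate(small_scenario, seed=7)
    return bundle, truth


@pytest.fixture(scope="session")
def small_hybrid_draws(small_bundle):
    """One short hybrid fit shared by diagnostics-oriented tests."""
    from scrhybrid import fit

    bundle, truth = small_bundle
    spec = ModelSpec("hybrid", M=60, use_telemetry=True)
    return fit(spec, bundle, MCMCConfig(n_chains=2, n_iter=1500, n_burn=500, seed=3))
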