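"""Shared fixtures: mean-field tables and a small equilibrated run."""

import numpy as np
import pytest

import memcons as mc


@pytest.fixture(scope="session")
def params001():
    return mc.StabilityParams(f=0.01)


@pytest.fixture(scope="session")
def basin(params001):
    """Basin-size table at the standard sparseness f = 0.01."""
    return mc.build_basin_table(params001)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale consolidation setting that equilibrates in seconds."""
    return mc.SimConfig(N=800, f=0.01, tau=20.0, lam=0.25, b=0.3,
                        T=3000.0, n_realizations=3, seed=42)


@pytest.fixture(scope="session")
def small_run(small_cfg, basin):
    return mc.run_simulation(small_cfg, basin)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
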