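"""Shared fixtures.

The saddle-node sweep of the stochastic network is by far the most
expensive computation in the suite, so it is run once per session and
shared by every test that inspects behaviour around the critical
synthesis scale.
"""

import numpy as np
import pytest

from bifurscan import build_network, sweep

SWEEP_SEED = 42
M1_GRID = np.arange(2.0, 4.001, 0.25)


@pytest.fixture(scope="session")
def saddle_sweep():
    """m1 sweep of the 102-gene network at the study conditions.

    k_D = 1, m2 = 3, 100 cells, noise 1/s = 0.05, dt = 0.01, 2e4 Euler
    steps per grid value (scaled-down equilibration; the relaxation
    time is ~1/k_D = 1 time unit, far below the 200 time units
    integrated).
    """
    params = build_network(
        n_g=102, seed=SWEEP_SEED, n_c=100, m2=3.0, k_D=1.0,
        s=20.0, dt=0.01, n_steps=20_000,
    )
    return params, sweep(params, "m1", M1_GRID)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
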