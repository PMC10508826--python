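import numpy as np
import pytest

from spibmetad import (LangevinConfig, make_potential, run_baoab)


@pytest.fixture(scope="session")
def double_well():
    return make_potential("double_well_1d", barrier=5.0)


@pytest.fixture(scope="session")
def two_state_trajectory(double_well):
    """Langevin trajectory on a 5 kBT double well with ground-truth state
    sequence (left/right basin) — the standard substrate for SPIB tests."""
    tr = run_baoab(double_well,
                   LangevinConfig(dt=0.02, n_steps=40000, seed=3, friction=1.0),
                   x0=[-1.0], record_every=10)
    x = tr["positions"][:, 0]
    truth = np.where(x < 0, "L", "R")
    return x, truth


@pytest.fixture(scope="session")
def spib_input(two_state_trajectory):
    """CV matrix: 3 informative channels (linear images of x) + 7 noise."""
    x, truth = two_state_trajectory
    rng = np.random.default_rng(0)
    informative = [x,
                   2 * x + 0.1 * rng.standard_normal(x.size),
                   -x + 0.1 * rng.standard_normal(x.size)]
    noise = [rng.standard_normal(x.size) for _ in range(7)]
    X = np.column_stack(informative + noise)
    return X, truth
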