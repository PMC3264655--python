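import numpy as np
import pytest
from hypothesis import settings

import recursig as rs

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """n=120, 150 genes, 6 planted signal genes — quick but informative."""
    cfg = rs.SimulationConfig(n_samples=120, n_genes=150, n_signal=6,
                              beta_signal=0.8, seed=7)
    return rs.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def censored_outcome():
    """A fixed censored outcome vector for metric tests."""
    rng = np.random.default_rng(99)
    n = 60
    T = rng.exponential(40.0, n)
    C = rng.exponential(60.0, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return time, event
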