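import dataclasses

import numpy as np
import pytest

from nucexpel.simulate import SimulationConfig, simulate_movie


@pytest.fixture(scope="session")
def noiseless_baseline():
    """Noiseless, drift-free field of 20 healthy nuclei: fidelity reference."""
    cfg = SimulationConfig(
        n_cells=20,
        fraction_apoptotic=0.0,
        fraction_expelling=0.0,
        noise_enabled=False,
        drift_sd=0.0,
        area_jitter_sd=1e-9,
        seed=3,
    )
    movie, truth = simulate_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def small_wt_movie():
    """One noisy positive-condition field with ground truth."""
    cfg = SimulationConfig(n_cells=30, fraction_expelling=0.85, seed=11)
    movie, truth = simulate_movie(cfg)
    return cfg, movie, truth


def make_config(**kw) -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
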