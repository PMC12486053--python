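import numpy as np
import pytest

from braid import TrainingConfig, generate_random_system, simulate


LINEAR_ASSIGN = {k: "linear" for k in ("A", "K", "Cy", "Cz")}
NONLIN_CZ_ASSIGN = {"A": "linear", "K": "linear", "Cy": "linear", "Cz": "nonlinear"}


@pytest.fixture(scope="session")
def linear_system():
    """Small fully linear ground-truth system."""
    return generate_random_system(3, 6, 2, 2, nonlinearity="none", seed=7)


@pytest.fixture(scope="session")
def linear_dataset(linear_system):
    return simulate(linear_system, T=3000, seed=17)


@pytest.fixture(scope="session")
def sinus_system():
    return generate_random_system(4, 10, 2, 2, nonlinearity="sinusoidal_cz", seed=11)


@pytest.fixture(scope="session")
def sinus_dataset(sinus_system):
    return simulate(sinus_system, T=4000, seed=23)


def quick_config(**kw):
    """Short training budget for unit tests (not the study-scale fits)."""
    base = dict(epochs=60, patience=10, lr_drops=1, seed=0,
                nonlinearity=dict(LINEAR_ASSIGN))
    base.update(kw)
    return TrainingConfig(**base)


def make_rng(seed=0):
    return np.random.default_rng(seed)
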