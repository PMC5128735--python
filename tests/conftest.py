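import numpy as np
import pytest

from markovfit import random_model, stiffness_penalty
from markovfit.fixtures import ground_truth_model, nav_protocols, synth_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def na3():
    return ground_truth_model("na3")


@pytest.fixture(scope="session")
def na_reduced():
    return nav_protocols(reduced=True)


@pytest.fixture(scope="session")
def na_full():
    return nav_protocols(reduced=False)


@pytest.fixture(scope="session")
def noisy_na_dataset(na3, na_reduced):
    """Reduced-suite synthetic targets with 1% feature noise (fixed seed)."""
    return synth_dataset(na3, na_reduced, 0.01, np.random.default_rng(12345))


def tame_random_model(n_states, p_extra, basis, rng, max_stiffness=500.0, tries=2000):
    """Random reversible model resampled until numerically tame (largest
    |eigenvalue| of Q over the stiffness grid below ``max_stiffness`` 1/ms),
    so adaptive ODE reference integration stays affordable."""
    for _ in range(tries):
        m = random_model(n_states, p_extra, basis, rng)
        s = stiffness_penalty(m)
        if np.isfinite(s) and s <= max_stiffness:
            return m
    raise RuntimeError("could not draw a tame random model")


@pytest.fixture
def tame_model_factory():
    return tame_random_model
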