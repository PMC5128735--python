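"""Shared hand-built oracles for the test suite."""

import numpy as np

from markovfit import MarkovModel, RateMatrix, VoltageBasisSpec


def two_state_decay_Q(rate: float) -> RateMatrix:
    """Irreversible 2-state decay: state 1 empties at ``rate``, no return.
    Closed form: x1(t) = exp(-rate*t)."""
    Q = np.array([[-rate, 0.0], [rate, 0.0]])
    return RateMatrix(Q=Q, voltage=0.0)


def voltage_independent_model() -> MarkovModel:
    """3-state chain whose rates carry no voltage dependence; every sweep of
    any protocol produces the identical conductance trajectory."""
    alpha = np.array([[0.0, 0.0], [0.7, 0.0], [-0.3, 0.0]])
    beta = np.array([[0.5, 0.0], [-0.2, 0.0]])
    return MarkovModel(
        n_states=3, edges=[(1, 2), (2, 3)],
        conductance=np.array([0.0, 1.0, 0.0]),
        alpha=alpha, beta=beta, basis=VoltageBasisSpec("linear"),
    )
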