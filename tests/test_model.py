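"""Graph generation, generator assembly, steady states, validation."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovfit import (
    DegenerateModelError,
    MarkovModel,
    VoltageBasisSpec,
    build_Q,
    random_connected_graph,
    random_model,
    steady_state,
    validate_model,
)


def two_state_model(r12, r21):
    """Voltage-independent 2-state model with the given rates."""
    k = r12 * r21
    ratio = r12 / r21  # = s2/s1 under detailed balance
    return MarkovModel(
        n_states=2, edges=[(1, 2)],
        conductance=np.array([0.0, 1.0]),
        alpha=np.array([[0.0, 0.0], [np.log(ratio), 0.0]]),
        beta=np.array([[np.log(k), 0.0]]),
        basis=VoltageBasisSpec("linear"),
    )


def chain_model(n, conducting=1):
    """Linear chain with all rates 1 (alpha = beta = 0)."""
    cond = np.zeros(n)
    cond[conducting] = 1.0
    return MarkovModel(
        n_states=n, edges=[(i, i + 1) for i in range(1, n)],
        conductance=cond,
        alpha=np.zeros((n, 2)), beta=np.zeros((n - 1, 2)),
        basis=VoltageBasisSpec("linear"),
    )


class TestRandomConnectedGraph:
    def test_two_states_gives_single_edge(self, rng):
        assert random_connected_graph(2, 0.0, rng) == [(1, 2)]

    def test_tree_has_n_minus_one_edges(self, rng):
        edges = random_connected_graph(5, 0.0, rng)
        assert len(edges) == 4
        g = nx.Graph(edges)
        assert nx.is_connected(g) and g.number_of_nodes() == 5

    def test_rejects_single_state(self, rng):
        with pytest.raises(ValueError):
            random_connected_graph(1, 0.0, rng)

    def test_always_connected_many_draws(self):
        rng = np.random.default_rng(7)
        for trial in range(10_000):
            n = 2 + trial % 7
            edges = random_connected_graph(n, 0.3, rng)
            assert len(edges) >= n - 1
            g = nx.Graph(edges)
            g.add_nodes_from(range(1, n + 1))
            assert nx.is_connected(g)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(2, 12), p=st.floats(0.0, 1.0), seed=st.integers(0, 2**31 - 1))
    def test_connectivity_property(self, n, p, seed):
        edges = random_connected_graph(n, p, np.random.default_rng(seed))
        g = nx.Graph(edges)
        g.add_nodes_from(range(1, n + 1))
        assert nx.is_connected(g)
        assert len(edges) <= n * (n - 1) // 2


class TestRandomModel:
    def test_minimal_model_structure(self, rng):
        m = random_model(2, 0.0, VoltageBasisSpec("linear"), rng)
        assert m.n_edges == 1
        assert np.sum(m.conductance > 0) == 1
        assert np.all(m.alpha[0] == 0.0)

    def test_seed_determinism(self):
        basis = VoltageBasisSpec("sigmoid")
        a = random_model(5, 0.4, basis, np.random.default_rng(11))
        b = random_model(5, 0.4, basis, np.random.default_rng(11))
        assert a.edges == b.edges
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.conductance, b.conductance)

    def test_samples_pass_validation(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            m = random_model(4, 0.3, VoltageBasisSpec("linear"), rng)
            assert validate_model(m).passed


class TestBuildQ:
    def test_two_state_assembly(self):
        Q = build_Q(two_state_model(2.0, 3.0), 0.0).Q
        np.testing.assert_allclose(Q, [[-2.0, 3.0], [2.0, -3.0]], atol=1e-12)

    def test_three_state_chain_diagonal(self):
        Q = build_Q(chain_model(3), 17.0).Q
        np.testing.assert_allclose(np.diag(Q), [-1.0, -2.0, -1.0], atol=1e-12)

    @pytest.mark.parametrize("v", [-120.0, -60.0, 0.0, 60.0])
    def test_generator_invariants_random_models(self, v):
        rng = np.random.default_rng(int(abs(v)) + 5)
        for _ in range(25):
            m = random_model(2 + int(rng.integers(5)), 0.3, VoltageBasisSpec("linear"), rng)
            Q = build_Q(m, v).Q
            scale = max(1.0, np.abs(Q).max())
            assert np.max(np.abs(Q.sum(axis=0))) <= 1e-12 * scale
            off = Q[~np.eye(len(Q), dtype=bool)]
            assert np.all(off >= 0)
            assert np.all(np.diag(Q) <= 0)


class TestSteadyState:
    def test_two_state_hand_solution(self):
        x = steady_state(build_Q(two_state_model(2.0, 3.0), 0.0))
        np.testing.assert_allclose(x, [0.6, 0.4], atol=1e-12)

    def test_symmetric_ring_uniform(self):
        n = 5
        edges = [(i, i + 1) for i in range(1, n)] + [(1, n)]
        m = MarkovModel(n, edges, np.eye(n)[0], np.zeros((n, 2)),
                        np.zeros((n, 2)), VoltageBasisSpec("linear"))
        x = steady_state(build_Q(m, -30.0))
        np.testing.assert_allclose(x, np.full(n, 1 / n), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(ln_r12=st.floats(-6, 6), ln_r21=st.floats(-6, 6))
    def test_two_state_closed_form_property(self, ln_r12, ln_r21):
        r12, r21 = np.exp(ln_r12), np.exp(ln_r21)
        x = steady_state(build_Q(two_state_model(r12, r21), 0.0))
        expected = np.array([r21, r12]) / (r12 + r21)
        np.testing.assert_allclose(x, expected, atol=1e-12)

    @pytest.mark.parametrize("v", [-120.0, -60.0, 0.0, 60.0])
    def test_residual_on_random_models(self, v):
        rng = np.random.default_rng(99)
        for _ in range(25):
            m = random_model(3 + int(rng.integers(4)), 0.3,
                             VoltageBasisSpec("sigmoid"), rng)
            Q = build_Q(m, v).Q
            x = steady_state(Q)
            assert np.max(np.abs(Q @ x)) <= 1e-10 * max(1.0, np.abs(Q).max())
            assert abs(x.sum() - 1.0) <= 1e-12
            assert x.min() >= 0.0

    def test_disconnected_generator_rejected(self):
        Q = np.zeros((4, 4))  # two disjoint 2-state blocks
        Q[0, 1], Q[1, 0] = 1.0, 1.0
        Q[2, 3], Q[3, 2] = 2.0, 2.0
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        with pytest.raises(DegenerateModelError):
            steady_state(Q)


class TestValidateModel:
    def test_valid_model_has_no_violations(self, na3):
        assert validate_model(na3).violations == []

    def test_reports_missing_conducting_state(self):
        m = chain_model(3)
        m.conductance[:] = 0.0
        report = validate_model(m)
        assert any("no conducting state" in v for v in report.violations)

    def test_reports_parameter_length_mismatch(self):
        m = chain_model(3)
        m.beta = np.zeros((5, 2))
        report = validate_model(m)
        assert any("parameter length mismatch" in v for v in report.violations)
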