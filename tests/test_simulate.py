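"""Matrix-exponential propagation, feature extraction, cost evaluation."""

import numpy as np
import pytest

from markovfit import (
    Dataset,
    FeatureSpec,
    FeatureUndefinedError,
    MarkovModel,
    Protocol,
    ProtocolStep,
    ProtocolError,
    VoltageBasisSpec,
    build_Q,
    cost,
    fall_time,
    half_max_crossing,
    propagate,
    propagate_ode,
    rise_time,
    run_protocol,
    sample_trace,
    steady_state,
    stiffness_penalty,
)
from markovfit.simulate import validate_protocol

from .helpers import two_state_decay_Q, voltage_independent_model


class TestPropagate:
    def test_stationarity(self, rng):
        from markovfit import random_model

        m = random_model(4, 0.3, VoltageBasisSpec("linear"), rng)
        Q = build_Q(m, -80.0)
        x0 = steady_state(Q)
        np.testing.assert_allclose(propagate(Q, x0, 37.0), x0, atol=1e-10)

    def test_two_state_decay_closed_form(self):
        Q = two_state_decay_Q(rate=2.0)
        x = propagate(Q, np.array([1.0, 0.0]), 0.5)
        assert x[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_zero_duration_is_identity(self):
        Q = two_state_decay_Q(2.0)
        x0 = np.array([0.3, 0.7])
        np.testing.assert_array_equal(propagate(Q, x0, 0.0), x0)


class TestSampleTrace:
    def test_endpoint_matches_one_shot_propagate(self, rng):
        from markovfit import random_model

        for _ in range(10):
            m = random_model(3 + int(rng.integers(3)), 0.3, VoltageBasisSpec("linear"), rng)
            try:
                Q = build_Q(m, -50.0)
            except Exception:
                continue
            x0 = steady_state(build_Q(m, -100.0))
            tr = sample_trace(Q, x0, 0.05, 40)
            np.testing.assert_allclose(tr[:, -1], propagate(Q, x0, 2.0), atol=1e-12)

    def test_conservation_along_trace(self, na3):
        Q = build_Q(na3, -20.0)
        x0 = steady_state(build_Q(na3, -120.0))
        tr = sample_trace(Q, x0, 0.01, 500)
        np.testing.assert_allclose(tr.sum(axis=0), 1.0, atol=1e-9)
        assert tr.min() >= -1e-12

    def test_two_state_decay_samples(self):
        Q = two_state_decay_Q(2.0)
        tr = sample_trace(Q, np.array([1.0, 0.0]), 0.1, 10)
        expected = np.exp(-0.2 * np.arange(11))
        np.testing.assert_allclose(tr[0], expected, atol=1e-12)


class TestOdeBackend:
    def test_agrees_with_expm(self, tame_model_factory):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m = tame_model_factory(3 + int(rng.integers(4)), 0.3,
                                   VoltageBasisSpec("linear"), rng)
            Q = build_Q(m, float(rng.uniform(-100, 20)))
            x0 = steady_state(build_Q(m, -100.0))
            a = propagate(Q, x0, 5.0)
            b = propagate_ode(Q, x0, 5.0)
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_two_state_decay(self):
        Q = two_state_decay_Q(2.0)
        x = propagate_ode(Q, np.array([1.0, 0.0]), 0.5)
        assert x[0] == pytest.approx(np.exp(-1.0), abs=1e-6)


class TestRiseFallTimes:
    def test_mono_exponential_rise(self):
        t = np.arange(0, 10, 0.01)
        g = 1.0 - np.exp(-t)  # tau = 1 ms
        assert rise_time(g, 0.01) == pytest.approx(np.log(9.0), rel=0.01)

    def test_mono_exponential_fall(self):
        t = np.arange(0, 10, 0.01)
        g = np.exp(-t)
        assert fall_time(g, 0.01) == pytest.approx(np.log(4.5), rel=0.01)

    def test_non_crossing_traces_are_undefined(self):
        decaying = np.exp(-np.arange(0, 5, 0.01))
        with pytest.raises(FeatureUndefinedError):
            rise_time(decaying, 0.01)
        rising = 1.0 - np.exp(-np.arange(0, 5, 0.01))
        with pytest.raises(FeatureUndefinedError):
            fall_time(rising, 0.01)


class TestRunProtocol:
    def test_voltage_independent_model_gives_flat_gv(self, na_reduced):
        m = voltage_independent_model()
        res = run_protocol(m, na_reduced["na_activation"])
        np.testing.assert_allclose(res.y, 1.0, atol=1e-9)

    def test_recovery_ratio_approaches_one_at_long_intervals(self, na3):
        proto = Protocol(
            name="rec_long", holding_potential=-120.0,
            steps=(ProtocolStep(-20.0, 20.0, record=True, dt=0.1),
                   ProtocolStep(-120.0, "sweep"),
                   ProtocolStep(-20.0, 8.0, record=True, dt=0.1)),
            sweep_name="duration", sweep_values=(5000.0,),
            feature=FeatureSpec("peak_ratio", step=1, ref_step=0),
            reversal_potential=50.0,
        )
        res = run_protocol(na3, proto)
        assert res.y[0] == pytest.approx(1.0, abs=1e-3)

    def test_backends_agree_on_features(self, na3, na_reduced):
        for name in ("na_activation", "na_recovery"):
            a = run_protocol(na3, na_reduced[name], backend="expm")
            b = run_protocol(na3, na_reduced[name], backend="ode")
            np.testing.assert_allclose(a.y, b.y, atol=1e-5)


class TestStiffnessPenalty:
    def test_two_state_eigenvalue(self):
        from .test_model import two_state_model

        assert stiffness_penalty(two_state_model(2.0, 3.0)) == pytest.approx(5.0, rel=1e-9)

    def test_scales_linearly_with_rates(self):
        from .test_model import two_state_model

        base = stiffness_penalty(two_state_model(2.0, 3.0))
        scaled = stiffness_penalty(two_state_model(2.0 * 7, 3.0 * 7))
        assert scaled == pytest.approx(7 * base, rel=1e-9)

    def test_single_state_is_zero(self):
        m = MarkovModel(1, [], np.array([1.0]), np.zeros((1, 2)),
                        np.zeros((0, 2)), VoltageBasisSpec("linear"))
        assert stiffness_penalty(m) == 0.0


class TestCost:
    def test_zero_on_noiseless_self_fit(self, na3, na_reduced):
        from markovfit.fixtures import synth_dataset

        ds = synth_dataset(na3, na_reduced, 0.0, np.random.default_rng(0))
        assert cost(na3, na_reduced, ds, penalty_weight=0.0) == pytest.approx(0.0, abs=1e-16)

    def test_single_row_squared_difference(self, na3, na_reduced):
        res = run_protocol(na3, na_reduced["na_activation"])
        d = 0.37
        ds = Dataset.from_rows([("na_activation", float(res.x[3]), float(res.y[3]) + d, 1.0)])
        c = cost(na3, na_reduced, ds, penalty_weight=0.0)
        assert c == pytest.approx(d * d, rel=1e-10)

    def test_matches_brute_force_row_sum(self, na3, na_reduced, noisy_na_dataset):
        c = cost(na3, na_reduced, noisy_na_dataset, penalty_weight=0.0)
        sims = {name: run_protocol(na3, p) for name, p in na_reduced.items()}
        total = 0.0
        for _, row in noisy_na_dataset.df.iterrows():
            res = sims[row["protocol"]]
            k = int(np.argmin(np.abs(res.x - row["x"])))
            total += row["weight"] * (res.y[k] - row["y"]) ** 2
        assert c == pytest.approx(total, rel=1e-12)

    def test_unweighted_penalty_variant(self, na3, na_reduced, noisy_na_dataset):
        c0 = cost(na3, na_reduced, noisy_na_dataset, penalty_weight=0.0)
        c1 = cost(na3, na_reduced, noisy_na_dataset, penalty_weight=1e-4)
        assert c1 == pytest.approx(c0 + 1e-4 * stiffness_penalty(na3), rel=1e-10)


class TestProtocolValidation:
    def test_sweep_at_reversal_potential_rejected(self):
        proto = Protocol(
            name="bad", holding_potential=-100.0,
            steps=(ProtocolStep("sweep", 10.0, record=True, dt=0.05),),
            sweep_name="voltage", sweep_values=(-20.0, 50.0),
            feature=FeatureSpec("peak_conductance_over_driving_force"),
            reversal_potential=50.0,
        )
        with pytest.raises(ProtocolError, match="reversal"):
            validate_protocol(proto)

    def test_peak_ratio_requires_reference_step(self):
        proto = Protocol(
            name="bad2", holding_potential=-100.0,
            steps=(ProtocolStep("sweep", 10.0, record=True, dt=0.05),),
            sweep_name="voltage", sweep_values=(-20.0,),
            feature=FeatureSpec("peak_ratio"),
            reversal_potential=50.0,
        )
        with pytest.raises(ProtocolError, match="peak_ratio"):
            validate_protocol(proto)


def test_half_max_crossing_interpolates():
    x = np.array([-60.0, -40.0, -20.0])
    y = np.array([0.2, 0.4, 0.8])
    assert half_max_crossing(x, y) == pytest.approx(-35.0)
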