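"""Packaged protocol library, ground-truth models, and synthetic datasets.

The Na⁺ and K⁺ protocol suites encode the standard voltage-clamp
characterizations (voltage-dependent activation, steady-state inactivation,
recovery from inactivation, rise/fall times, deactivation, conductance
traces) with the printed step voltages, increments and conditioning
durations.  Because no experimental recordings are tabulated anywhere,
deterministic ground-truth models plus a synthetic-dataset generator stand
in for real data: every fitting stage is testable end to end against a
known answer.

Each suite also ships a "reduced" variant (every other sweep value, shorter
conditioning, coarser sampling) for fast parameter-recovery runs; the full
variants match the printed protocol values.
"""

from __future__ import annotations

import numpy as np

from .model import MarkovModel, VoltageBasisSpec
from .simulate import (
    SWEEP,
    Dataset,
    FeatureSpec,
    Protocol,
    ProtocolStep,
    run_protocol,
)

__all__ = ["nav_protocols", "kcnq1_protocols", "ground_truth_model",
           "synth_dataset", "E_NA", "E_K"]

E_NA = 50.0   # mV, Na⁺ reversal potential used throughout the fixtures
E_K = -90.0   # mV, K⁺ reversal potential


def _p(name, hold, steps, sweep_name, sweep_values, feature, e_rev) -> Protocol:
    return Protocol(
        name=name, holding_potential=hold, steps=tuple(steps),
        sweep_name=sweep_name, sweep_values=tuple(sweep_values),
        feature=feature, reversal_potential=e_rev,
    )


def nav_protocols(reduced: bool = False) -> dict[str, Protocol]:
    """The five Na⁺ protocols (activation G-V, steady-state inactivation,
    recovery, rise/fall time, conductance trace).

    Full variant: activation sweeps -120..20 mV in 10 mV steps from a
    -100 mV resting potential; SSI holds at -120 mV with 200 ms conditioning
    then a -20 mV test pulse; recovery conditions at -20 mV for 200 ms and
    recovers at -120 mV for 1-1000 ms; the trace records normalized
    conductance over 5 ms.  Rise/fall times replicate the activation pulses,
    so they are separate Protocol objects sharing the same step sequence
    (simulated only once by the cost function).
    """
    if reduced:
        act_sweep = np.arange(-120.0, 21.0, 20.0)
        act_step = ProtocolStep(SWEEP, 8.0, record=True, dt=0.05)
        ssi_cond, test_dt = 50.0, 0.05
        rec_cond, rec_dt = 20.0, 0.1
        rec_gaps = (1.0, 3.0, 10.0, 30.0, 100.0)
        trace_dt, trace_out = 0.05, 0.25
        test_dur = 8.0
    else:
        act_sweep = np.arange(-120.0, 21.0, 10.0)
        act_step = ProtocolStep(SWEEP, 20.0, record=True, dt=0.005)
        ssi_cond, test_dt = 200.0, 0.005
        rec_cond, rec_dt = 200.0, 0.02
        rec_gaps = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
        trace_dt, trace_out = 0.005, 0.1
        test_dur = 20.0

    protos = {}
    protos["na_activation"] = _p(
        "na_activation", -100.0, [act_step], "voltage", act_sweep,
        FeatureSpec("peak_conductance_over_driving_force", "max_over_sweep"), E_NA)
    protos["na_ssi"] = _p(
        "na_ssi", -120.0,
        [ProtocolStep(SWEEP, ssi_cond), ProtocolStep(-20.0, test_dur, record=True, dt=test_dt)],
        "voltage", act_sweep,
        FeatureSpec("normalized_peak", "max_over_sweep"), E_NA)
    protos["na_recovery"] = _p(
        "na_recovery", -120.0,
        [ProtocolStep(-20.0, rec_cond, record=True, dt=rec_dt),
         ProtocolStep(-120.0, SWEEP),
         ProtocolStep(-20.0, test_dur, record=True, dt=rec_dt)],
        "duration", rec_gaps,
        FeatureSpec("peak_ratio", "none", step=1, ref_step=0), E_NA)
    protos["na_rise"] = _p(
        "na_rise", -100.0, [act_step], "voltage", act_sweep,
        FeatureSpec("rise_time_10_90", "none"), E_NA)
    protos["na_fall"] = _p(
        "na_fall", -100.0, [act_step], "voltage", act_sweep,
        FeatureSpec("fall_time_90_20", "none"), E_NA)
    protos["na_trace"] = _p(
        "na_trace", -100.0, [ProtocolStep(SWEEP, 5.0, record=True, dt=trace_dt)],
        "voltage", (-10.0,),
        FeatureSpec("normalized_trace", "none", trace_dt=trace_out), E_NA)
    return protos


def kcnq1_protocols(reduced: bool = False) -> dict[str, Protocol]:
    """The four K⁺ protocols (activation, deactivation, rise time, traces).

    Activation sweeps -100..60 mV in 20 mV steps from -100 mV; deactivation
    holds at -80 mV, depolarizes to 60 mV for 2 ms, then applies 4 ms
    conditioning pulses from -120 to 0 mV, reading the minimum absolute
    current over the driving force; conductance traces at -20/0/40 mV are
    recorded over 4 ms from a -80 mV resting potential (one single-sweep
    protocol per pulse voltage so dataset keys stay unique).
    """
    if reduced:
        act_sweep = np.arange(-100.0, 61.0, 40.0)
        act_step = ProtocolStep(SWEEP, 6.0, record=True, dt=0.05)
        deact_sweep = np.arange(-120.0, 1.0, 40.0)
        deact_dt = 0.05
        trace_dt, trace_out = 0.05, 0.4
    else:
        act_sweep = np.arange(-100.0, 61.0, 20.0)
        act_step = ProtocolStep(SWEEP, 10.0, record=True, dt=0.01)
        deact_sweep = np.arange(-120.0, 1.0, 20.0)
        deact_dt = 0.01
        trace_dt, trace_out = 0.01, 0.2

    protos = {}
    protos["k_activation"] = _p(
        "k_activation", -100.0, [act_step], "voltage", act_sweep,
        FeatureSpec("peak_conductance_over_driving_force", "max_over_sweep"), E_K)
    protos["k_deactivation"] = _p(
        "k_deactivation", -80.0,
        [ProtocolStep(60.0, 2.0), ProtocolStep(SWEEP, 4.0, record=True, dt=deact_dt)],
        "voltage", deact_sweep,
        FeatureSpec("min_abs_current_over_driving_force", "max_over_sweep"), E_K)
    protos["k_rise"] = _p(
        "k_rise", -100.0, [act_step], "voltage", act_sweep,
        FeatureSpec("rise_time_10_90", "none"), E_K)
    for v in (-20.0, 0.0, 40.0):
        name = f"k_trace_{int(v):+d}mV".replace("+", "p").replace("-", "m")
        protos[name] = _p(
            name, -80.0, [ProtocolStep(SWEEP, 4.0, record=True, dt=trace_dt)],
            "voltage", (v,),
            FeatureSpec("normalized_trace", "none", trace_dt=trace_out), E_K)
    return protos


def _na3() -> MarkovModel:
    # 3-state closed-open-inactivated chain with linear voltage dependence.
    # State 2 conducts.  Tuned to produce a transient Na-like current:
    # fast activation (~0.4 ms at -20 mV), slower inactivation (~1.4 ms),
    # recovery at -120 mV on the tens-of-ms scale.
    basis = VoltageBasisSpec("linear")
    alpha = np.array([
        [0.0, 0.0],
        [4.0, 0.10],    # open state: favored above ~-40 mV
        [10.5, 0.15],   # inactivated: dominates depolarized equilibria
    ])
    beta = np.array([
        [0.2, 0.02],    # edge (1,2): activation kinetics
        [-6.2, 0.0],    # edge (2,3): inactivation kinetics
    ])
    return MarkovModel(
        n_states=3, edges=[(1, 2), (2, 3)],
        conductance=np.array([0.0, 1.0, 0.0]),
        alpha=alpha, beta=beta, basis=basis,
    )


def _k4() -> MarkovModel:
    # 4-state closed-closed-closed-open chain with a bounded sigmoid basis
    # (a = -40 mV, b = 15 mV); monotone delayed-rectifier-like activation.
    basis = VoltageBasisSpec("sigmoid", a=-40.0, b=15.0)
    alpha = np.array([
        [0.0, 0.0],
        [-1.0, 2.5],
        [-2.0, 5.0],
        [-3.0, 7.5],
    ])
    beta = np.full((3, 2), [0.5, 0.0])
    return MarkovModel(
        n_states=4, edges=[(1, 2), (2, 3), (3, 4)],
        conductance=np.array([0.0, 0.0, 0.0, 1.0]),
        alpha=alpha, beta=beta, basis=basis,
    )


_GROUND_TRUTHS = {"na3": _na3, "k4": _k4}


def ground_truth_model(name: str) -> MarkovModel:
    """Deterministic fixed-parameter model by name ("na3", "k4")."""
    try:
        return _GROUND_TRUTHS[name]()
    except KeyError:
        raise ValueError(
            f"unknown ground-truth spec {name!r}; known: {sorted(_GROUND_TRUTHS)}"
        ) from None


def synth_dataset(model: MarkovModel, protocols, noise_sd: float, rng) -> Dataset:
    """Simulate every protocol (expm backend) and add i.i.d. Gaussian noise
    of sd ``noise_sd`` × the protocol's feature scale to each row.  Rows
    whose feature is undefined for the ground truth (e.g. rise time of a
    non-activating sweep) are dropped.  Weights are 1."""
    if isinstance(protocols, dict):
        protocols = list(protocols.values())
    rows = []
    cache: dict = {}
    for proto in protocols:
        res = run_protocol(model, proto, backend="expm", cache=cache)
        finite = np.isfinite(res.y)
        x, y = res.x[finite], res.y[finite]
        scale = float(np.max(np.abs(y))) if len(y) else 1.0
        if scale == 0:
            scale = 1.0
        noise = rng.normal(0.0, noise_sd * scale, size=len(y)) if noise_sd > 0 else 0.0
        for xi, yi in zip(x, y + noise):
            rows.append((proto.name, float(xi), float(yi), 1.0))
    return Dataset.from_rows(rows)
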