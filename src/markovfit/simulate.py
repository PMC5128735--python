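"""Voltage-clamp protocol simulation and cost evaluation.

A voltage-clamp protocol is a sequence of constant-voltage steps, so the
master equation dx/dt = Q(v)x is piecewise linear-time-invariant and each
step is solved exactly by the matrix exponential: x(t) = e^(tQ)x0.  Recorded
steps are sampled on a fixed grid by precomputing H = e^(QΔt) once and
"powering up": y[i] = H·y[i-1].  An adaptive ODE backend is retained as an
independent reference (and for models destined for continuous-voltage use).

Recorded occupancies are converted to normalized conductance
g(t) = G·x(t) and a current proxy I(t) = g(t)·(v - E_rev); derived features
(peak conductance over driving force, normalized peaks, peak ratios,
10-90% rise and 90-20% fall times, normalized traces) feed a weighted
squared-error cost, optionally augmented by a stiffness penalty proportional
to the largest-magnitude eigenvalue of Q over a voltage grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.integrate import solve_ivp

from .errors import (
    FeatureUndefinedError,
    ProtocolError,
    SimulationError,
    StiffnessOverflowError,
)
from .model import MarkovModel, RateMatrix, build_Q, steady_state

__all__ = [
    "ProtocolStep",
    "FeatureSpec",
    "Protocol",
    "Dataset",
    "ProtocolResult",
    "propagate",
    "sample_trace",
    "propagate_ode",
    "sample_trace_ode",
    "run_protocol",
    "rise_time",
    "fall_time",
    "stiffness_penalty",
    "cost",
    "validate_protocol",
    "half_max_crossing",
    "DEFAULT_STIFFNESS_GRID",
]

SWEEP = "sweep"  # placeholder value resolved per sweep iteration

DEFAULT_STIFFNESS_GRID = np.arange(-120.0, 21.0, 10.0)

_SCALAR_KINDS = {
    "peak_conductance_over_driving_force",
    "normalized_peak",
    "peak_ratio",
    "rise_time_10_90",
    "fall_time_90_20",
    "min_abs_current_over_driving_force",
}
_DRIVING_FORCE_KINDS = {
    "peak_conductance_over_driving_force",
    "min_abs_current_over_driving_force",
}


@dataclass(frozen=True)
class ProtocolStep:
    """One constant-voltage step.  ``voltage`` (mV) or ``duration`` (ms) may
    be the string ``"sweep"``, resolved from the protocol's sweep variable.
    ``dt`` is the sampling interval, used only when ``record`` is true."""

    voltage: float | str
    duration: float | str
    record: bool = False
    dt: float = 0.01


@dataclass(frozen=True)
class FeatureSpec:
    """How recorded traces are reduced to fitted observables.

    ``step``/``ref_step`` index into the protocol's *recorded* steps (0-based);
    ``ref_step`` is the conditioning pulse for ``peak_ratio``.  ``trace_dt``
    thins ``normalized_trace`` output to one sample per ``trace_dt`` ms.
    """

    kind: str
    normalization: str = "none"  # none | max_over_sweep | first_sweep
    step: int = 0
    ref_step: int | None = None
    trace_dt: float | None = None


@dataclass(frozen=True)
class Protocol:
    name: str
    holding_potential: float
    steps: tuple[ProtocolStep, ...]
    sweep_name: str  # "voltage" or "duration" (documentation of what sweeps)
    sweep_values: tuple[float, ...]
    feature: FeatureSpec
    reversal_potential: float

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "sweep_values", tuple(float(v) for v in self.sweep_values))

    @property
    def recorded_steps(self) -> list[int]:
        return [k for k, s in enumerate(self.steps) if s.record]

    def simulation_signature(self):
        """Key identifying the raw simulation; protocols sharing it (e.g. a
        G-V sweep and the rise-time measurement on the same pulses) are
        simulated once."""
        return (
            self.holding_potential,
            tuple((s.voltage, s.duration, s.record, s.dt) for s in self.steps),
            self.sweep_values,
        )


def validate_protocol(protocol: Protocol) -> None:
    """Raise :class:`ProtocolError` on structural violations."""
    p = protocol
    if not p.sweep_values:
        raise ProtocolError(f"{p.name}: sweep variable has no values")
    uses_sweep = any(s.voltage == SWEEP or s.duration == SWEEP for s in p.steps)
    if not uses_sweep:
        raise ProtocolError(f"{p.name}: no step references the sweep variable")
    for k, s in enumerate(p.steps):
        if s.duration != SWEEP and float(s.duration) <= 0:
            raise ProtocolError(f"{p.name}: steps[{k}].duration must be positive")
        if s.record and s.dt <= 0:
            raise ProtocolError(f"{p.name}: steps[{k}].dt must be positive when recording")
        if s.duration == SWEEP and any(float(v) <= 0 for v in p.sweep_values):
            raise ProtocolError(f"{p.name}: swept durations must be positive")
    rec = p.recorded_steps
    if not rec:
        raise ProtocolError(f"{p.name}: feature references a recorded step but none exists")
    f = p.feature
    if f.kind not in _SCALAR_KINDS | {"normalized_trace"}:
        raise ProtocolError(f"{p.name}: unknown feature kind {f.kind!r}")
    if f.step >= len(rec):
        raise ProtocolError(f"{p.name}: feature.step {f.step} out of range ({len(rec)} recorded)")
    if f.kind == "peak_ratio":
        if f.ref_step is None or f.ref_step >= len(rec):
            raise ProtocolError(f"{p.name}: peak_ratio requires two recorded steps")
    if f.kind == "normalized_trace" and len(p.sweep_values) != 1:
        raise ProtocolError(f"{p.name}: normalized_trace requires a single sweep value")
    if f.kind in _DRIVING_FORCE_KINDS:
        step = p.steps[rec[f.step]]
        for sv in p.sweep_values:
            v = sv if step.voltage == SWEEP else float(step.voltage)
            if abs(v - p.reversal_potential) < 1.0:
                raise ProtocolError(
                    f"{p.name}: sweep voltage {v} mV within 1 mV of the reversal "
                    f"potential {p.reversal_potential} mV (driving-force singularity)"
                )


@dataclass
class Dataset:
    """Fit targets: rows of (protocol, sweep value x, observed y, weight)."""

    df: pd.DataFrame

    def __post_init__(self):
        required = ["protocol", "x", "y", "weight"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if (self.df["weight"] <= 0).any():
            bad = int(self.df.index[self.df["weight"] <= 0][0])
            raise ValueError(f"dataset row {bad}: weight must be positive")

    @classmethod
    def from_rows(cls, rows) -> "Dataset":
        return cls(pd.DataFrame(rows, columns=["protocol", "x", "y", "weight"]))

    @cached_property
    def groups(self) -> dict:
        out = {}
        for name, g in self.df.groupby("protocol", sort=False):
            out[name] = (
                g["x"].to_numpy(float),
                g["y"].to_numpy(float),
                g["weight"].to_numpy(float),
            )
        return out

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# propagation backends

def _power_trace_py(H: np.ndarray, x0: np.ndarray, n_steps: int) -> np.ndarray:
    out = np.empty((n_steps + 1, H.shape[0]))
    out[0] = x0
    y = x0
    for i in range(1, n_steps + 1):
        y = H @ y
        out[i] = y
    return out.T


try:  # optional JIT of the powering loop; behavior identical to the fallback
    from numba import njit as _njit

    @_njit(cache=False)
    def _power_trace_jit(H, x0, n_steps):  # pragma: no cover - numerics tested via wrapper
        n = H.shape[0]
        out = np.empty((n, n_steps + 1))
        out[:, 0] = x0
        for i in range(1, n_steps + 1):
            for r in range(n):
                acc = 0.0
                for c in range(n):
                    acc += H[r, c] * out[c, i - 1]
                out[r, i] = acc
        return out

    def _power_trace(H, x0, n_steps):
        return _power_trace_jit(np.ascontiguousarray(H), np.ascontiguousarray(x0), n_steps)
except Exception:  # pragma: no cover
    _power_trace = _power_trace_py


def _expm(M: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        H = scipy.linalg.expm(M)
    if not np.all(np.isfinite(H)):
        raise StiffnessOverflowError("matrix exponential overflowed")
    return H


def propagate(Q, x0: np.ndarray, duration: float) -> np.ndarray:
    """x(duration) = e^(duration·Q) x0 for constant voltage."""
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    if duration < 0:
        raise ValueError("duration must be non-negative")
    x0 = np.asarray(x0, dtype=float)
    if duration == 0:
        return x0.copy()
    return _expm(duration * Q) @ x0


def sample_trace(Q, x0: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Occupancy sampled on a fixed grid: columns x0, Hx0, H²x0, ... with
    H = e^(QΔt) precomputed once.  Shape (n_states, n_steps + 1)."""
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    if dt <= 0 or n_steps < 1:
        raise ValueError("need dt > 0 and n_steps >= 1")
    H = _expm(dt * Q)
    out = _power_trace(H, np.asarray(x0, dtype=float), int(n_steps))
    if not np.all(np.isfinite(out)):
        raise StiffnessOverflowError("trace powering produced non-finite occupancy")
    return out


def propagate_ode(Q, x0: np.ndarray, duration: float,
                  rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Reference backend: adaptive integration of dx/dt = Qx (LSODA, which
    switches to an implicit scheme on stiff systems)."""
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    if duration == 0:
        return np.asarray(x0, dtype=float).copy()
    sol = solve_ivp(
        lambda t, x: Q @ x, (0.0, duration), np.asarray(x0, dtype=float),
        method="LSODA", jac=lambda t, x: Q, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed: {sol.message} "
            f"(last step reached t = {sol.t[-1]:.4g} of {duration:.4g} ms)"
        )
    return sol.y[:, -1]


def sample_trace_ode(Q, x0: np.ndarray, dt: float, n_steps: int,
                     rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    t_eval = np.arange(n_steps + 1) * dt
    sol = solve_ivp(
        lambda t, x: Q @ x, (0.0, t_eval[-1]), np.asarray(x0, dtype=float),
        method="LSODA", jac=lambda t, x: Q, t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    return sol.y


# ---------------------------------------------------------------------------
# trace features

def _interp_crossing(trace: np.ndarray, dt: float, level: float,
                     start: int, stop: int, direction: int) -> float:
    """First time in [start, stop) where the trace crosses ``level`` going
    up (direction=+1) or down (-1), linearly interpolated; NaN if never."""
    for i in range(start + 1, stop):
        a, b = trace[i - 1], trace[i]
        if direction > 0 and a < level <= b:
            return (i - 1 + (level - a) / (b - a)) * dt
        if direction < 0 and a > level >= b:
            return (i - 1 + (level - a) / (b - a)) * dt
    return np.nan


def rise_time(trace: np.ndarray, dt: float) -> float:
    """Time for the trace to rise from 10% to 90% of its peak (pre-peak,
    linear interpolation)."""
    trace = np.asarray(trace, dtype=float)
    p = int(np.argmax(trace))
    peak = trace[p]
    if peak <= 0 or trace[0] >= 0.1 * peak:
        raise FeatureUndefinedError("10% threshold never crossed before the peak")
    t10 = _interp_crossing(trace, dt, 0.1 * peak, 0, p + 1, +1)
    t90 = _interp_crossing(trace, dt, 0.9 * peak, 0, p + 1, +1)
    if np.isnan(t10) or np.isnan(t90):
        raise FeatureUndefinedError("rise thresholds never crossed")
    return t90 - t10


def fall_time(trace: np.ndarray, dt: float) -> float:
    """Time for the trace to fall from 90% to 20% of its peak (post-peak)."""
    trace = np.asarray(trace, dtype=float)
    p = int(np.argmax(trace))
    peak = trace[p]
    if peak <= 0:
        raise FeatureUndefinedError("trace has no positive peak")
    t90 = _interp_crossing(trace, dt, 0.9 * peak, p, len(trace), -1)
    t20 = _interp_crossing(trace, dt, 0.2 * peak, p, len(trace), -1)
    if np.isnan(t90) or np.isnan(t20):
        raise FeatureUndefinedError("fall thresholds never crossed after the peak")
    return t20 - t90


# ---------------------------------------------------------------------------
# protocol execution

@dataclass
class RecordedWindow:
    """Occupancy samples of one recorded step of one sweep."""

    voltage: float
    dt: float
    occupancy: np.ndarray  # (n_states, n_samples + 1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[1]) * self.dt

    def conductance(self, G: np.ndarray) -> np.ndarray:
        return G @ self.occupancy


@dataclass
class ProtocolResult:
    protocol: str
    x: np.ndarray  # sweep values (or trace times for normalized_trace)
    y: np.ndarray  # feature values; NaN where undefined
    traces: list | None = None  # per sweep: list of RecordedWindow


def _resolve(value, sweep_value: float) -> float:
    return float(sweep_value) if value == SWEEP else float(value)


def simulate_sweeps(model: MarkovModel, protocol: Protocol, backend: str = "expm",
                    cache: dict | None = None, rtol: float = 1e-8,
                    atol: float = 1e-10) -> list[list[RecordedWindow]]:
    """Raw simulation: per sweep value, the list of recorded windows.

    ``cache`` maps voltage -> (Q, steady_state-or-None) and may be shared
    across protocols for the same model (voltage steps recur across the
    protocol suite).
    """
    if backend not in ("expm", "ode"):
        raise ValueError(f"unknown backend {backend!r}")
    cache = cache if cache is not None else {}

    def get_Q(v: float) -> np.ndarray:
        ent = cache.get(v)
        if ent is None:
            ent = [build_Q(model, v).Q, None]
            cache[v] = ent
        return ent[0]

    def get_ss(v: float) -> np.ndarray:
        ent = cache.get(v)
        if ent is None or ent[1] is None:
            Q = get_Q(v)
            cache[v][1] = steady_state(Q)
        return cache[v][1]

    results = []
    for sv in protocol.sweep_values:
        try:
            x = get_ss(protocol.holding_potential).copy()
            windows = []
            for step in protocol.steps:
                v = _resolve(step.voltage, sv)
                dur = _resolve(step.duration, sv)
                Q = get_Q(v)
                if step.record:
                    n = max(1, int(round(dur / step.dt)))
                    if backend == "expm":
                        occ = sample_trace(Q, x, step.dt, n)
                    else:
                        occ = sample_trace_ode(Q, x, step.dt, n, rtol, atol)
                    windows.append(RecordedWindow(voltage=v, dt=step.dt, occupancy=occ))
                    x = occ[:, -1]
                else:
                    if backend == "expm":
                        x = propagate(Q, x, dur)
                    else:
                        x = propagate_ode(Q, x, dur, rtol, atol)
            results.append(windows)
        except (StiffnessOverflowError, SimulationError) as err:
            raise SimulationError(
                f"protocol {protocol.name!r}, sweep value {sv}: {err}",
                protocol=protocol.name, sweep_value=sv,
            ) from err
    return results


def extract_features(protocol: Protocol, sweeps: list[list[RecordedWindow]],
                     G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduce raw sweeps to the protocol's (x, y) feature table.

    Undefined features (thresholds never crossed) yield NaN so the caller
    can apply its configured penalty instead of aborting.
    """
    f = protocol.feature
    if f.kind == "normalized_trace":
        w = sweeps[0][f.step]
        g = w.conductance(G)
        peak = np.max(np.abs(g))
        y = g / peak if peak > 0 else g
        t = w.times
        stride = 1
        if f.trace_dt is not None:
            stride = max(1, int(round(f.trace_dt / w.dt)))
        return t[::stride].copy(), y[::stride].copy()

    x = np.asarray(protocol.sweep_values, dtype=float)
    y = np.empty_like(x)
    for s, windows in enumerate(sweeps):
        w = windows[f.step]
        g = w.conductance(G)
        drive = w.voltage - protocol.reversal_potential
        current = np.abs(g * drive)
        if f.kind == "peak_conductance_over_driving_force":
            y[s] = np.max(current) / abs(drive)
        elif f.kind == "normalized_peak":
            y[s] = np.max(current)
        elif f.kind == "peak_ratio":
            ref = windows[f.ref_step]
            ref_peak = np.max(np.abs(ref.conductance(G) * (ref.voltage - protocol.reversal_potential)))
            y[s] = np.max(current) / ref_peak if ref_peak > 0 else np.nan
        elif f.kind == "min_abs_current_over_driving_force":
            y[s] = np.min(current) / abs(drive)
        elif f.kind == "rise_time_10_90":
            try:
                y[s] = rise_time(g, w.dt)
            except FeatureUndefinedError:
                y[s] = np.nan
        elif f.kind == "fall_time_90_20":
            try:
                y[s] = fall_time(g, w.dt)
            except FeatureUndefinedError:
                y[s] = np.nan
        else:  # pragma: no cover - guarded by validate_protocol
            raise ProtocolError(f"unknown feature kind {f.kind!r}")

    if f.normalization == "max_over_sweep":
        top = np.nanmax(np.abs(y))
        if top > 0:
            y = y / top
    elif f.normalization == "first_sweep":
        if y[0] != 0 and np.isfinite(y[0]):
            y = y / y[0]
    return x, y


def run_protocol(model: MarkovModel, protocol: Protocol, backend: str = "expm",
                 return_traces: bool = False, cache: dict | None = None) -> ProtocolResult:
    """Simulate every sweep of ``protocol`` and extract its feature table."""
    validate_protocol(protocol)
    sweeps = simulate_sweeps(model, protocol, backend=backend, cache=cache)
    x, y = extract_features(protocol, sweeps, model.conductance)
    return ProtocolResult(
        protocol=protocol.name, x=x, y=y,
        traces=sweeps if return_traces else None,
    )


# ---------------------------------------------------------------------------
# cost

def stiffness_penalty(model: MarkovModel, v_grid=None) -> float:
    """Max over a voltage grid of the largest-magnitude eigenvalue of Q(v)
    (1/ms).  Generator eigenvalues have non-positive real part; the most
    negative one sets how stiff the master equation is.  Returns +inf on
    rate overflow."""
    grid = DEFAULT_STIFFNESS_GRID if v_grid is None else np.asarray(v_grid, dtype=float)
    worst = 0.0
    for v in grid:
        try:
            Q = build_Q(model, v).Q
        except StiffnessOverflowError:
            return np.inf
        if Q.shape[0] == 1:
            continue
        worst = max(worst, float(np.max(np.abs(scipy.linalg.eigvals(Q)))))
    return worst


def cost(model: MarkovModel, protocols, dataset: Dataset,
         penalty_weight: float = 1e-4, backend: str = "expm",
         missing_penalty: float = 100.0, v_grid=None) -> float:
    """Weighted squared error of simulated vs observed features, plus the
    stiffness penalty.  Returns +inf when simulation fails, so the annealer
    rejects the model.

    ``protocols`` is an iterable (or name->Protocol mapping) covering every
    protocol named in the dataset.  Protocols sharing a simulation signature
    (identical step sequences) are simulated once.
    """
    if isinstance(protocols, dict):
        protocols = list(protocols.values())
    by_name = {p.name: p for p in protocols}
    unknown = set(dataset.groups) - set(by_name)
    if unknown:
        raise ValueError(f"dataset references unknown protocols {sorted(unknown)}")

    needed = [by_name[name] for name in dataset.groups]
    total = 0.0
    cache: dict = {}
    sim_cache: dict = {}
    try:
        for proto in needed:
            sig = proto.simulation_signature()
            if sig not in sim_cache:
                sim_cache[sig] = simulate_sweeps(model, proto, backend=backend, cache=cache)
            x_sim, y_sim = extract_features(proto, sim_cache[sig], model.conductance)
            x_obs, y_obs, w = dataset.groups[proto.name]
            idx = np.abs(x_obs[:, None] - x_sim[None, :]).argmin(axis=1)
            matched = np.abs(x_obs - x_sim[idx]) <= 1e-6 * (1.0 + np.abs(x_obs))
            y_hat = y_sim[idx]
            bad = ~matched | ~np.isfinite(y_hat)
            with np.errstate(over="ignore"):  # huge residuals -> inf -> reject
                resid2 = np.where(bad, missing_penalty,
                                  (np.where(bad, y_obs, y_hat) - y_obs) ** 2)
            total += float(np.dot(w, resid2))
    except (SimulationError, StiffnessOverflowError):
        return np.inf
    except Exception as err:  # degenerate generators etc.
        from .errors import DegenerateModelError

        if isinstance(err, DegenerateModelError):
            return np.inf
        raise

    if penalty_weight:
        pen = stiffness_penalty(model, v_grid)
        if not np.isfinite(pen):
            return np.inf
        total += penalty_weight * pen
    return total


def half_max_crossing(x, y, level: float = 0.5) -> float:
    """Interpolated x at which y first crosses ``level`` going up, scanning
    in ascending x (half-activation voltage of a normalized G-V curve).
    NaN if never crossed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    for i in range(1, len(x)):
        a, b = y[i - 1], y[i]
        if a < level <= b:
            return float(x[i - 1] + (level - a) / (b - a) * (x[i] - x[i - 1]))
    return np.nan
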