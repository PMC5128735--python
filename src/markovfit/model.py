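"""Markov model representation for ion-channel gating kinetics.

A channel model is a connected undirected graph whose nodes are discrete
conformational states, a per-state relative conductance vector, and a set of
rate parameters.  Voltage-dependent transition rates are not free: they are
generated from per-state parameters ``alpha`` (which set the equilibrium
occupancies) and per-edge parameters ``beta`` (which set the kinetic speed of
each transition) so that microscopic reversibility holds at every membrane
voltage — see :mod:`markovfit.reversibility`.

Units are fixed throughout the package: time in ms, voltage in mV, rates in
1/ms.  State ids are 1-based in files and documentation; arrays are 0-based
internally.  Edges are stored as sorted unordered pairs in canonical
lexicographic order, and ``beta`` rows are aligned with that order.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .errors import DegenerateModelError

__all__ = [
    "VoltageBasisSpec",
    "MarkovModel",
    "RateMatrix",
    "InitScales",
    "canonical_edges",
    "random_connected_graph",
    "random_model",
    "build_Q",
    "steady_state",
    "validate_model",
]


@dataclass(frozen=True)
class VoltageBasisSpec:
    """Choice of the voltage feature map f(v) used by every rate.

    ``linear``     f(v) = (1, v) — Eyring-type exponential voltage dependence.
    ``polynomial`` f(v) = (1, v, ..., v^order).
    ``sigmoid``    f(v) = (1, sig((v - a)/b)) with the logistic function;
                   bounded, so rates saturate at extreme voltages.

    ``a`` (mV) and ``b`` (mV) are shared across all rates of a model.
    """

    kind: str = "linear"
    order: int = 2
    a: float = -40.0
    b: float = 15.0

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial", "sigmoid"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "polynomial" and self.order < 1:
            raise ValueError("polynomial basis requires order >= 1")
        if self.kind == "sigmoid" and self.b == 0:
            raise ValueError("sigmoid basis requires b != 0")

    @property
    def dimension(self) -> int:
        """Length F of the feature vector."""
        if self.kind == "polynomial":
            return self.order + 1
        return 2


def canonical_edges(edges) -> list[tuple[int, int]]:
    """Sorted list of (min, max) 1-based state pairs; forward = low -> high."""
    out = sorted({(min(i, j), max(i, j)) for i, j in edges})
    for i, j in out:
        if i == j:
            raise ValueError(f"self-loop edge ({i},{j}) not allowed")
    return out


@dataclass
class MarkovModel:
    """Channel model: graph + conductance + reversibility parameters.

    alpha : (n_states, F) array; row i parameterizes the (unnormalized) log
        equilibrium occupancy of state i+1, ln s_i(v) = f(v)·alpha_i.  Row 0
        is pinned to zero (gauge fix: only differences of alpha rows enter
        the rates, so one row is not identifiable).
    beta : (n_edges, F) array in canonical edge order; row e parameterizes
        the log rate product of edge e, ln k_e(v) = f(v)·beta_e.
    conductance : (n_states,) relative conductance in [0, 1] per state.
    """

    n_states: int
    edges: list[tuple[int, int]]
    conductance: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    basis: VoltageBasisSpec = field(default_factory=VoltageBasisSpec)

    def __post_init__(self):
        self.edges = canonical_edges(self.edges)
        self.conductance = np.asarray(self.conductance, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "MarkovModel":
        return MarkovModel(
            n_states=self.n_states,
            edges=list(self.edges),
            conductance=self.conductance.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            basis=self.basis,
        )

    def edge_index(self, i: int, j: int) -> int:
        e = (min(i, j), max(i, j))
        k = bisect_left(self.edges, e)
        if k == len(self.edges) or self.edges[k] != e:
            raise KeyError(f"edge {e} not in model")
        return k


@dataclass(frozen=True)
class RateMatrix:
    """Generator Q (n x n, 1/ms) of the master equation dx/dt = Qx at a fixed
    voltage.  Q[i, j] holds the rate from state j+1 to state i+1; columns sum
    to zero so total occupancy is conserved."""

    Q: np.ndarray
    voltage: float


@dataclass(frozen=True)
class InitScales:
    """Standard deviations for initial parameter draws, per basis component.

    ``offset_sd`` applies to the constant component and to bounded components
    (the sigmoid feature lies in (0, 1)); ``vcoef_sd`` applies to the linear
    voltage coefficient and is shrunk by a factor 120^(p-1) for polynomial
    power p, keeping initial rates numerically sane over the ±120 mV
    physiological range.
    """

    offset_sd: float = 1.0
    vcoef_sd: float = 0.2

    def sds(self, basis: VoltageBasisSpec) -> np.ndarray:
        if basis.kind == "linear":
            return np.array([self.offset_sd, self.vcoef_sd])
        if basis.kind == "sigmoid":
            return np.array([self.offset_sd, self.offset_sd])
        sds = [self.offset_sd]
        for p in range(1, basis.order + 1):
            sds.append(self.vcoef_sd / 120.0 ** (p - 1))
        return np.array(sds)


def random_connected_graph(n_states: int, p_extra: float, rng) -> list[tuple[int, int]]:
    """Random connected graph on ``n_states`` nodes (1-based ids).

    A spanning tree is grown by a random walk over the complete graph: each
    time the walk first enters an unvisited node, the entering edge is added.
    Afterwards every absent node pair is added independently with probability
    ``p_extra``.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if not 0.0 <= p_extra <= 1.0:
        raise ValueError("p_extra must be a probability")
    current = int(rng.integers(n_states))
    visited = {current}
    edges = set()
    while len(visited) < n_states:
        step = int(rng.integers(n_states - 1))
        nxt = step if step < current else step + 1  # uniform over others
        if nxt not in visited:
            visited.add(nxt)
            edges.add((min(current, nxt) + 1, max(current, nxt) + 1))
        current = nxt
    if p_extra > 0:
        for i in range(1, n_states + 1):
            for j in range(i + 1, n_states + 1):
                if (i, j) not in edges and rng.random() < p_extra:
                    edges.add((i, j))
    return canonical_edges(edges)


def draw_parameters(basis: VoltageBasisSpec, shape_rows: int, rng,
                    scales: InitScales | None = None) -> np.ndarray:
    """Draw ``shape_rows`` independent parameter rows from the initial normal
    distributions (used at model initialization and for states/edges created
    by structural perturbations)."""
    scales = scales or InitScales()
    sds = scales.sds(basis)
    return rng.normal(0.0, 1.0, size=(shape_rows, basis.dimension)) * sds


def random_model(n_states: int, p_extra: float, basis: VoltageBasisSpec, rng,
                 scales: InitScales | None = None) -> MarkovModel:
    """Random connected model with one conducting state and normal initial
    parameter draws; alpha of state 1 is zeroed (gauge)."""
    edges = random_connected_graph(n_states, p_extra, rng)
    alpha = draw_parameters(basis, n_states, rng, scales)
    alpha[0, :] = 0.0
    beta = draw_parameters(basis, len(edges), rng, scales)
    conductance = np.zeros(n_states)
    conductance[int(rng.integers(n_states))] = 1.0
    return MarkovModel(n_states, edges, conductance, alpha, beta, basis)


def build_Q(model: MarkovModel, v: float) -> RateMatrix:
    """Assemble the generator Q(v) from the reversibility parameterization.

    Q[i, j] = rate from state j+1 to i+1 for connected pairs, zero otherwise;
    the diagonal is the negative column sum, so every column sums to zero and
    dx/dt = Qx conserves total occupancy.
    """
    from .reversibility import rates_at_voltage

    er = rates_at_voltage(model, v)
    n = model.n_states
    Q = np.zeros((n, n))
    for e, (i, j) in enumerate(model.edges):
        Q[j - 1, i - 1] = er.fwd[e]  # i -> j
        Q[i - 1, j - 1] = er.bwd[e]  # j -> i
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return RateMatrix(Q=Q, voltage=float(v))


def _gth(Q: np.ndarray) -> np.ndarray:
    """Stationary vector by Grassmann-Taksar-Heyman state elimination.

    Uses only the off-diagonal rates and additions, so it is accurate
    componentwise even when rates span many orders of magnitude (where a
    direct solve or eigendecomposition loses the small occupancies to
    cancellation).  Raises on a reducible (disconnected) generator.
    """
    A = Q.T.copy()  # A[i, j] = rate i -> j
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    for k in range(n - 1, 0, -1):
        s = A[k, :k].sum()
        if s <= 0.0:
            raise DegenerateModelError(
                "generator is reducible (disconnected states); no unique steady state"
            )
        A[:k, k] /= s
        A[:k, :k] += np.outer(A[:k, k], A[k, :k])
    x = np.zeros(n)
    x[0] = 1.0
    for k in range(1, n):
        x[k] = x[:k] @ A[:k, k]
    if not np.all(np.isfinite(x)):
        raise DegenerateModelError("could not extract a valid stationary vector")
    return x / x.sum()


def steady_state(Q, tol: float = 1e-10) -> np.ndarray:
    """Stationary occupancy x with Qx = 0, sum(x) = 1, x >= 0; unique for a
    connected graph.  Computed by GTH elimination, which stays accurate even
    for generators whose rates span many orders of magnitude.  Raises
    :class:`DegenerateModelError` for a disconnected generator, whose null
    space is not one-dimensional."""
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] == 1:
        return np.ones(1)
    return _gth(Q)


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.passed


def validate_model(model: MarkovModel) -> ValidationReport:
    """Structural diagnostics; reports violations, never raises."""
    v: list[str] = []
    n, F = model.n_states, model.basis.dimension
    if n < 1:
        v.append("n_states must be positive")
        return ValidationReport(v)
    for i, j in model.edges:
        if not (1 <= i <= n and 1 <= j <= n):
            v.append(f"edge ({i},{j}) references invalid state id")
        if i == j:
            v.append(f"edge ({i},{j}) is a self-loop")
    if n >= 2 and len(model.edges) < n - 1:
        v.append(f"too few edges ({len(model.edges)}) for a connected graph on {n} states")
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    g.add_edges_from(model.edges)
    if n >= 2 and not nx.is_connected(g):
        v.append("graph is not connected")
    if model.conductance.shape != (n,):
        v.append(f"conductance length {model.conductance.shape} != n_states {n}")
    else:
        if not np.all((model.conductance >= 0) & (model.conductance <= 1)):
            v.append("conductance entries must lie in [0, 1]")
        if not np.any(model.conductance > 0):
            v.append("no conducting state")
    if model.alpha.shape != (n, F):
        v.append(f"parameter length mismatch: alpha shape {model.alpha.shape} != ({n}, {F})")
    elif np.any(model.alpha[0] != 0.0):
        v.append("alpha of state 1 must be the zero vector (gauge fix)")
    if model.beta.shape != (len(model.edges), F):
        v.append(
            f"parameter length mismatch: beta shape {model.beta.shape} != "
            f"({len(model.edges)}, {F})"
        )
    return ValidationReport(v)
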