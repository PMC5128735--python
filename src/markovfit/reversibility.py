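"""Microscopic reversibility by construction.

Detailed balance requires r_ij * s_i = r_ji * s_j on every edge at
equilibrium, equivalently that the product of rates around every cycle is
the same in both directions — and this must hold at every membrane voltage.
Instead of constraining the rates directly, the forward/backward rate pair
of each edge is generated from two independent quantities:

    s_i(v) = exp(f(v) · alpha_i)     per-state equilibrium weight
    k_ij(v) = exp(f(v) · beta_ij)    per-edge rate product r_ij * r_ji

which determine the rates uniquely:

    r_ij(v) = sqrt(k_ij(v) * s_j(v) / s_i(v))
    r_ji(v) = sqrt(k_ij(v) * s_i(v) / s_j(v))

Because ln r is a linear map of the free parameters (alpha, beta), every
rate is again of the form exp(theta · f(v)), and detailed balance holds
identically in v.  The closed form above is used in production (O(E) per
voltage); the equivalent stacked 2E x 2E linear system is retained as an
independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit

from .errors import StiffnessOverflowError
from .model import MarkovModel, VoltageBasisSpec, canonical_edges

__all__ = [
    "EdgeRates",
    "ReversibilitySystem",
    "voltage_basis_eval",
    "build_reversibility_system",
    "rates_at_voltage",
    "rates_via_linear_system",
    "edge_thetas",
    "detailed_balance_residual",
]

#: |ln r| beyond which exp() is treated as overflow (float64 overflows ~709).
LN_RATE_LIMIT = 700.0


@dataclass(frozen=True)
class EdgeRates:
    """Per-edge rate pairs at one voltage, in canonical edge order.

    ``fwd[e]`` is the rate low-id -> high-id of edge ``edges[e]``; ``bwd[e]``
    the reverse.  Log-rates are carried alongside since features and cycle
    residuals are naturally computed in log space.
    """

    edges: tuple
    fwd: np.ndarray
    bwd: np.ndarray
    ln_fwd: np.ndarray
    ln_bwd: np.ndarray


@dataclass(frozen=True)
class ReversibilitySystem:
    """Linear-algebra view of the detailed-balance constraints.

    The stacked log-rate vector uses the interleaved column layout
    (fwd_1, bwd_1, fwd_2, bwd_2, ...).  ``D`` (E x 2E) maps it to per-edge
    log-rate differences, ``absD`` to per-edge log-rate sums, and ``IeT``
    (E x n) maps per-state ln s to the per-edge difference ln s_j - ln s_i.
    The stacked [D; absD] matrix is block-diagonal in 2x2 blocks
    [[1, -1], [1, 1]] and hence invertible with determinant 2^E.
    """

    D: np.ndarray
    absD: np.ndarray
    IeT: np.ndarray
    edges: tuple


def voltage_basis_eval(basis: VoltageBasisSpec, v: float) -> np.ndarray:
    """Feature vector f(v) of length ``basis.dimension``."""
    if basis.kind == "linear":
        return np.array([1.0, float(v)])
    if basis.kind == "sigmoid":
        return np.array([1.0, float(expit((v - basis.a) / basis.b))])
    return np.power(float(v), np.arange(basis.order + 1))


def build_reversibility_system(edges, n_states: int | None = None) -> ReversibilitySystem:
    edges = canonical_edges(edges)
    if not edges:
        raise ValueError("need at least one edge")
    E = len(edges)
    if n_states is None:
        n_states = max(j for _, j in edges)
    D = np.zeros((E, 2 * E))
    absD = np.zeros((E, 2 * E))
    IeT = np.zeros((E, n_states))
    for e, (i, j) in enumerate(edges):
        D[e, 2 * e] = 1.0
        D[e, 2 * e + 1] = -1.0
        absD[e, 2 * e] = 1.0
        absD[e, 2 * e + 1] = 1.0
        IeT[e, i - 1] = -1.0
        IeT[e, j - 1] = 1.0
    return ReversibilitySystem(D=D, absD=absD, IeT=IeT, edges=tuple(edges))


def _edge_endpoints(model: MarkovModel):
    idx = np.asarray(model.edges, dtype=int).reshape(-1, 2) - 1
    return idx[:, 0], idx[:, 1]


def rates_at_voltage(model: MarkovModel, v: float) -> EdgeRates:
    """Closed-form per-edge rates at voltage ``v`` (1/ms).

    Raises :class:`StiffnessOverflowError` if any |ln r| exceeds the float64
    exponentiation limit, identifying the offending edge and voltage.
    """
    f = voltage_basis_eval(model.basis, v)
    ln_s = model.alpha @ f
    ln_k = model.beta @ f
    if len(model.edges) == 0:
        empty = np.empty(0)
        return EdgeRates(edges=(), fwd=empty, bwd=empty, ln_fwd=empty, ln_bwd=empty)
    ii, jj = _edge_endpoints(model)
    half_diff = 0.5 * (ln_s[jj] - ln_s[ii])
    half_k = 0.5 * ln_k
    ln_fwd = half_k + half_diff
    ln_bwd = half_k - half_diff
    worst = max(np.max(np.abs(ln_fwd)), np.max(np.abs(ln_bwd)))
    if not np.isfinite(worst) or worst > LN_RATE_LIMIT:
        bad = int(np.argmax(np.maximum(np.abs(ln_fwd), np.abs(ln_bwd))))
        raise StiffnessOverflowError(
            f"rate overflow on edge {model.edges[bad]} at {v} mV "
            f"(|ln r| = {worst:.1f})",
            edge=model.edges[bad],
            voltage=v,
        )
    return EdgeRates(
        edges=tuple(model.edges),
        fwd=np.exp(ln_fwd),
        bwd=np.exp(ln_bwd),
        ln_fwd=ln_fwd,
        ln_bwd=ln_bwd,
    )


def rates_via_linear_system(model: MarkovModel, v: float) -> EdgeRates:
    """Rates obtained by solving the stacked [D; absD] system.

    Mathematically identical to :func:`rates_at_voltage`; kept as an
    independent code path for cross-validation.
    """
    sys_ = build_reversibility_system(model.edges, model.n_states)
    f = voltage_basis_eval(model.basis, v)
    ln_s = model.alpha @ f
    ln_k = model.beta @ f
    rhs = np.concatenate([sys_.IeT @ ln_s, ln_k])
    stacked = np.vstack([sys_.D, sys_.absD])
    ln_r = np.linalg.solve(stacked, rhs)
    ln_fwd = ln_r[0::2]
    ln_bwd = ln_r[1::2]
    return EdgeRates(
        edges=tuple(model.edges),
        fwd=np.exp(ln_fwd),
        bwd=np.exp(ln_bwd),
        ln_fwd=ln_fwd,
        ln_bwd=ln_bwd,
    )


def edge_thetas(model: MarkovModel):
    """Per-edge voltage-constant coefficient vectors (theta_fwd, theta_bwd)
    such that r(v) = exp(theta · f(v)): theta = (beta ± (alpha_j - alpha_i))/2."""
    ii, jj = _edge_endpoints(model)
    d = model.alpha[jj] - model.alpha[ii]
    return 0.5 * (model.beta + d), 0.5 * (model.beta - d)


def detailed_balance_residual(model: MarkovModel, v: float,
                              rates: EdgeRates | None = None) -> float:
    """Max over independent cycles of |sum of (ln r_fwd - ln r_bwd)| around
    the cycle; zero (to roundoff) iff detailed balance holds at ``v``."""
    g = nx.Graph()
    g.add_nodes_from(range(1, model.n_states + 1))
    g.add_edges_from(model.edges)
    cycles = nx.cycle_basis(g)
    if not cycles:
        return 0.0
    er = rates if rates is not None else rates_at_voltage(model, v)
    ln_diff = {}
    for e, (i, j) in enumerate(er.edges):
        ln_diff[(i, j)] = er.ln_fwd[e] - er.ln_bwd[e]
        ln_diff[(j, i)] = er.ln_bwd[e] - er.ln_fwd[e]
    worst = 0.0
    for cyc in cycles:
        total = 0.0
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            total += ln_diff[(a, b)]
        worst = max(worst, abs(total))
    return worst
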