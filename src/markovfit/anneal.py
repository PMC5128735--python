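"""Synchronous multi-chain simulated annealing over model structure and rates.

Several independent Metropolis chains share a single exponential cooling
schedule T(t) = T0·γ^t.  At every iteration each chain proposes a perturbed
model — every proposal applies a sparse Gaussian rate-parameter update, and
with configured probabilities additionally adds/removes a state or an edge
(reconnecting the graph if a removal disconnects it) — evaluates its cost,
and accepts with probability min(1, exp(-(e' - e)/T)).  Chains never
exchange information; the result is the best model seen by any chain.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import (
    InitScales,
    MarkovModel,
    VoltageBasisSpec,
    draw_parameters,
    random_model,
    validate_model,
)
from .simulate import Dataset, cost

__all__ = ["AnnealConfig", "ChainResult", "FitResult", "perturb", "accept",
           "temperature", "anneal"]

STRUCTURAL_MOVES = ("state_add", "state_remove", "edge_add", "edge_remove",
                    "conductance_flip")


@dataclass
class AnnealConfig:
    """Hyper-parameters of the annealer.

    ``T0 = None`` sets the initial temperature to the median initial chain
    cost (scale-free start).  ``sigma`` scales a per-basis-component
    perturbation kernel (:class:`InitScales`), so voltage coefficients move
    on their natural scale; with ``sigma_final`` set, the kernel width decays
    exponentially from ``sigma`` to ``sigma_final`` over the run — a fixed
    schedule mirroring the temperature schedule, so late proposals refine
    rather than re-explore.  ``move_probs`` are per-proposal probabilities of
    each structural move; the rate update always applies.  The conductance
    vector is fixed after initialization unless ``conductance_flip`` is given
    a nonzero probability.
    """

    seed: int
    n_chains: int = 12
    n_iterations: int = 1000
    T0: float | None = None
    gamma: float = 0.9925
    p: float = 0.2
    sigma: float = 0.1
    sigma_final: float | None = 0.01
    move_probs: dict = field(default_factory=lambda: {
        "state_add": 0.02, "state_remove": 0.02,
        "edge_add": 0.02, "edge_remove": 0.02,
        "conductance_flip": 0.0,
    })
    min_states: int = 2
    max_states: int = 10
    init_states: int = 3
    p_extra: float = 0.15
    basis: VoltageBasisSpec = field(default_factory=VoltageBasisSpec)
    scales: InitScales = field(default_factory=InitScales)
    penalty_weight: float = 1e-4
    missing_penalty: float = 100.0
    backend: str = "expm"
    init_candidates: int = 25
    max_init_retries: int = 50

    def __post_init__(self):
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be a probability")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.min_states < 2:
            raise ValueError("min_states must be >= 2")
        for k, v in self.move_probs.items():
            if k not in STRUCTURAL_MOVES:
                raise ValueError(f"unknown structural move {k!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"move probability {k}={v} outside [0, 1]")


def temperature(t: int, config: AnnealConfig, T0: float | None = None) -> float:
    """Exponential schedule T(t) = T0·γ^t."""
    base = T0 if T0 is not None else config.T0
    if base is None:
        raise ValueError("T0 not set")
    return base * config.gamma ** t


def accept(e_old: float, e_new: float, T: float, rng) -> bool:
    """Metropolis rule: always accept downhill; accept uphill with
    probability exp(-(e_new - e_old)/T).  An infinite new cost (failed
    simulation) is always rejected."""
    if not np.isfinite(e_new):
        return False
    if e_new <= e_old:
        return True
    if T <= 0:
        return False
    return rng.random() < np.exp(-(e_new - e_old) / T)


# ---------------------------------------------------------------------------
# perturbation moves

def _reconnect(edges: list, beta_rows: list, n_states: int, basis, rng, scales) -> bool:
    """Join disconnected components with fresh random edges until connected.
    Returns False if no new cross edge exists (only possible on 2 nodes)."""
    g = nx.Graph()
    g.add_nodes_from(range(1, n_states + 1))
    g.add_edges_from(edges)
    while not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        ca, cb = rng.choice(len(comps), size=2, replace=False)
        i = int(comps[ca][rng.integers(len(comps[ca]))])
        j = int(comps[cb][rng.integers(len(comps[cb]))])
        e = (min(i, j), max(i, j))
        if e in edges:
            if n_states == 2:
                return False
            continue
        _insert_edge(edges, beta_rows, e, draw_parameters(basis, 1, rng, scales)[0])
        g.add_edge(i, j)
    return True


def _insert_edge(edges: list, beta_rows: list, e: tuple, beta_row: np.ndarray):
    lo, hi = 0, len(edges)
    while lo < hi:
        mid = (lo + hi) // 2
        if edges[mid] < e:
            lo = mid + 1
        else:
            hi = mid
    edges.insert(lo, e)
    beta_rows.insert(lo, beta_row)


def kernel_sigma(t: int, config: AnnealConfig) -> float:
    """Rate-update width at iteration ``t``: exponential interpolation from
    ``sigma`` to ``sigma_final`` (constant if ``sigma_final`` is None)."""
    if config.sigma_final is None or config.n_iterations <= 1 or config.sigma == 0:
        return config.sigma
    frac = t / (config.n_iterations - 1)
    return config.sigma * (config.sigma_final / config.sigma) ** frac


def perturb(model: MarkovModel, config: AnnealConfig, rng, sigma: float | None = None):
    """One proposal: structural moves (each with its configured probability)
    followed by the always-applied sparse rate update (Bernoulli(p) mask,
    N(0, σ·scale) increments).  The input model is never modified.

    Returns ``(proposal, moves)`` where ``moves`` lists the structural moves
    actually applied.
    """
    m = model.copy()
    basis, scales = m.basis, config.scales
    edges = list(m.edges)
    beta_rows = [row.copy() for row in m.beta] if m.n_edges else []
    alpha = m.alpha.copy()
    conductance = m.conductance.copy()
    n = m.n_states
    moves: list[str] = []

    draws = {mv: rng.random() for mv in STRUCTURAL_MOVES}

    if draws["state_add"] < config.move_probs.get("state_add", 0.0) and n < config.max_states:
        anchor = int(rng.integers(n)) + 1
        n += 1
        alpha = np.vstack([alpha, draw_parameters(basis, 1, rng, scales)])
        conductance = np.append(conductance, 0.0)
        e = (min(anchor, n), max(anchor, n))
        _insert_edge(edges, beta_rows, e, draw_parameters(basis, 1, rng, scales)[0])
        moves.append("state_add")

    if draws["state_remove"] < config.move_probs.get("state_remove", 0.0) and n > config.min_states:
        n_conducting = int(np.sum(conductance > 0))
        candidates = [s for s in range(1, n + 1)
                      if conductance[s - 1] == 0 or n_conducting > 1]
        if candidates:
            victim = int(candidates[rng.integers(len(candidates))])
            keep = [k for k, e in enumerate(edges) if victim not in e]
            edges = [edges[k] for k in keep]
            beta_rows = [beta_rows[k] for k in keep]
            edges = [(i - (i > victim), j - (j > victim)) for i, j in edges]
            alpha = np.delete(alpha, victim - 1, axis=0)
            conductance = np.delete(conductance, victim - 1)
            n -= 1
            if edges:
                pairs = sorted(zip(edges, beta_rows), key=lambda p: p[0])
                edges = [p[0] for p in pairs]
                beta_rows = [p[1] for p in pairs]
            _reconnect(edges, beta_rows, n, basis, rng, scales)
            alpha = alpha - alpha[0]  # restore the gauge after relabeling
            moves.append("state_remove")

    if draws["edge_add"] < config.move_probs.get("edge_add", 0.0):
        present = set(edges)
        absent = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)
                  if (i, j) not in present]
        if absent:
            e = absent[rng.integers(len(absent))]
            _insert_edge(edges, beta_rows, e, draw_parameters(basis, 1, rng, scales)[0])
            moves.append("edge_add")

    if draws["edge_remove"] < config.move_probs.get("edge_remove", 0.0) and edges:
        k = int(rng.integers(len(edges)))
        removed_e, removed_b = edges[k], beta_rows[k]
        del edges[k], beta_rows[k]
        if not edges or not _reconnect(edges, beta_rows, n, basis, rng, scales):
            _insert_edge(edges, beta_rows, removed_e, removed_b)  # irreparable: skip
        else:
            moves.append("edge_remove")

    if draws["conductance_flip"] < config.move_probs.get("conductance_flip", 0.0):
        s = int(rng.integers(n))
        flipped = conductance.copy()
        flipped[s] = 0.0 if flipped[s] > 0 else 1.0
        if np.any(flipped > 0):
            conductance = flipped
            moves.append("conductance_flip")

    # rate update: always applied, gauge row excluded
    width = config.sigma if sigma is None else sigma
    sds = width * scales.sds(basis) / max(scales.offset_sd, 1e-12)
    beta = np.array(beta_rows) if beta_rows else np.zeros((0, basis.dimension))
    for arr, skip_first in ((alpha, True), (beta, False)):
        if arr.size == 0:
            continue
        mask = rng.random(arr.shape) < config.p
        noise = rng.normal(0.0, 1.0, size=arr.shape) * sds
        if skip_first:
            mask[0, :] = False
        arr += mask * noise

    return MarkovModel(n, edges, conductance, alpha, beta, basis), moves


# ---------------------------------------------------------------------------
# the annealer

@dataclass
class ChainResult:
    best_model: MarkovModel
    best_cost: float
    cost_trajectory: np.ndarray      # current cost per iteration
    best_trajectory: np.ndarray      # best-so-far cost per iteration
    proposed: dict
    accepted: dict


@dataclass
class FitResult:
    chains: list[ChainResult]
    config: AnnealConfig
    T0: float

    @property
    def best_chain(self) -> int:
        return int(np.argmin([c.best_cost for c in self.chains]))

    @property
    def best_model(self) -> MarkovModel:
        return self.chains[self.best_chain].best_model

    @property
    def best_cost(self) -> float:
        return self.chains[self.best_chain].best_cost


def anneal(protocols, dataset: Dataset, config: AnnealConfig,
           log_fn=None) -> FitResult:
    """Run synchronous multi-chain annealing against ``dataset``.

    Fully reproducible from ``config.seed``: each chain owns an independent
    child generator, and chains are contract-parallel (no chain reads
    another's state within an iteration).  ``log_fn``, if given, is called
    with one record dict per (iteration, chain) proposal.
    """
    if isinstance(protocols, dict):
        protocols = list(protocols.values())

    def evaluate(m: MarkovModel) -> float:
        return cost(m, protocols, dataset,
                    penalty_weight=config.penalty_weight,
                    backend=config.backend,
                    missing_penalty=config.missing_penalty)

    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(config.n_chains)]

    # each chain starts from the cheapest of several random draws, so the
    # cooling schedule starts at the scale of real data mismatch rather than
    # at the missing-feature penalty plateau of arbitrary random models
    current: list[MarkovModel] = []
    e_cur: list[float] = []
    for rng in rngs:
        e_sel, m_sel = np.inf, None
        draws = 0
        while draws < config.max_init_retries + config.init_candidates:
            m = random_model(config.init_states, config.p_extra, config.basis, rng,
                             config.scales)
            draws += 1
            e = evaluate(m)
            if e < e_sel:
                e_sel, m_sel = e, m
            if np.isfinite(e_sel) and draws >= config.init_candidates:
                break
        if not np.isfinite(e_sel):
            raise RuntimeError(
                "initialization failure: no chain found a finite-cost "
                f"starting model in {draws} draws"
            )
        current.append(m_sel)
        e_cur.append(e_sel)

    T0 = config.T0 if config.T0 is not None else float(np.median(e_cur))
    if T0 <= 0:
        T0 = 1.0

    n_it = config.n_iterations
    best = [m.copy() for m in current]
    e_best = list(e_cur)
    traj = np.empty((config.n_chains, n_it))
    best_traj = np.empty((config.n_chains, n_it))
    proposed = [dict.fromkeys(STRUCTURAL_MOVES + ("rate_update",), 0)
                for _ in range(config.n_chains)]
    accepted = [dict.fromkeys(STRUCTURAL_MOVES + ("rate_update",), 0)
                for _ in range(config.n_chains)]

    for t in range(n_it):
        T = temperature(t, config, T0)
        sig_t = kernel_sigma(t, config)
        for c, rng in enumerate(rngs):
            proposal, moves = perturb(current[c], config, rng, sigma=sig_t)
            e_new = evaluate(proposal)
            ok = accept(e_cur[c], e_new, T, rng)
            for mv in moves + ["rate_update"]:
                proposed[c][mv] += 1
                if ok:
                    accepted[c][mv] += 1
            if ok:
                current[c] = proposal
                e_cur[c] = e_new
                if e_new < e_best[c]:
                    e_best[c] = e_new
                    best[c] = proposal.copy()
            traj[c, t] = e_cur[c]
            best_traj[c, t] = e_best[c]
            if log_fn is not None:
                log_fn({"iteration": t, "chain": c, "temperature": T,
                        "moves": "+".join(moves + ["rate_update"]),
                        "cost": e_new, "accepted": ok})

    chains = [
        ChainResult(best_model=best[c], best_cost=e_best[c],
                    cost_trajectory=traj[c], best_trajectory=best_traj[c],
                    proposed=proposed[c], accepted=accepted[c])
        for c in range(config.n_chains)
    ]
    return FitResult(chains=chains, config=config, T0=T0)
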