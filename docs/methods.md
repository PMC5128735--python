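# Methods

## The model class

A channel is a continuous-time Markov process on `n` discrete conformational
states connected by an undirected graph.  State occupancy `x(t)` evolves by
the master equation

    dx/dt = Q(v) x,

where the generator `Q(v)` holds the voltage-dependent transition rates:
`Q[i][j]` is the rate from state `j` to state `i` for connected pairs, and
each diagonal entry is the negative sum of its column, so total occupancy is
conserved.  (With rates placed at `Q[i][j] = r_ij` — "rate i to j" — the
column sums would not vanish and `dx/dt = Qx` would leak probability; the
convention used here is the unique one that makes the master equation
valid.)  A per-state conductance vector `G` (boolean by default, exactly one
conducting state at initialization) converts occupancy to normalized
conductance `g(t) = G·x(t)` and to a current proxy
`I(t) = g(t)·(v − E_rev)`.

Units are fixed: time in ms, voltage in mV, rates in ms⁻¹.

## Microscopic reversibility by construction

Physical gating cycles satisfy detailed balance: `r_ij s_i = r_ji s_j` on
every edge, at every voltage, where `s` is the equilibrium distribution.
Enforcing this as a constraint during optimization is awkward; instead the
rates are *generated* from unconstrained parameters.  Each state carries a
vector `alpha_i`, each edge a vector `beta_ij`, and a shared voltage basis
`f(v)` defines

    ln s_i(v) = f(v)·alpha_i          (equilibrium weight)
    ln k_ij(v) = f(v)·beta_ij         (rate product r_ij·r_ji)

from which the rates follow in closed form:

    r_ij(v) = sqrt(k_ij(v) · s_j(v)/s_i(v)),
    r_ji(v) = sqrt(k_ij(v) · s_i(v)/s_j(v)).

`k` sets how fast an edge equilibrates; the `s` ratio sets where the
equilibrium lies.  Because `ln r` is linear in `(alpha, beta)`, every rate
is again of the form `exp(theta·f(v))` and detailed balance holds
identically in `v` — cycle residuals are zero to roundoff by construction,
which the tests verify on random cyclic graphs.  The equivalent stacked
`2E×2E` linear system (difference matrix `D`, sum matrix `|D|`, signed
incidence `Ie`) is retained purely as an independent oracle; the closed form
is exact and O(E).

Gauge: only differences `alpha_j − alpha_i` enter the rates, so `alpha` of
state 1 is pinned to the zero vector, removing one non-identifiable degree
of freedom per basis dimension.

### Voltage bases

- `linear`: `f(v) = (1, v)` — Eyring-type exponential voltage dependence.
  Expressive but prone to stiffness: rates grow without bound at extreme
  voltages.
- `polynomial`: `f(v) = (1, v, …, v^order)` — more expressive, more prone
  to overfitting; provided for completeness.
- `sigmoid`: `f(v) = (1, sig((v−a)/b))` — bounded, so every rate saturates;
  `a`, `b` are shared across all rates.  Defaults `a = −40 mV`, `b = 15 mV`
  put the transition in the mid-physiological range; both are configurable
  since no canonical values exist.

Rate overflow (`|ln r| > 700`, the float64 limit) raises a typed error
rather than clipping, because clipping dependent rates would silently break
detailed balance; the stiffness penalty (below) is the sanctioned way to
keep fitted models tame.

## Protocol simulation

Voltage-clamp protocols are sequences of constant-voltage steps, optionally
swept over one variable (a step voltage or a gap duration).  Over each step
the master equation is linear time-invariant, so the solution is exact:
`x(t) = e^(tQ)x0` (scipy's Padé `expm`).  Recorded steps are sampled on a
fixed grid by precomputing `H = e^(QΔt)` once and powering up,
`y[i] = H·y[i−1]` (JIT-compiled when numba is importable; a pure-numpy loop
otherwise — results are identical).  An adaptive ODE backend (LSODA, which
switches to an implicit scheme on stiff systems; `rtol 1e-8`, `atol 1e-10`)
is retained as an independent reference and agrees with the exponential
route to better than 1e-6 in occupancy on tame models.

Steady states initialize every sweep at the holding potential.  They are
computed by GTH (Grassmann–Taksar–Heyman) state elimination rather than a
linear solve or eigendecomposition: random models routinely produce rates
spanning tens of orders of magnitude, where subtraction-based methods lose
the small occupancies entirely, while GTH uses only additions of
nonnegative rates and stays accurate componentwise.

### Features

Recorded occupancy windows reduce to the observables electrophysiologists
fit: peak conductance over driving force (G-V curves), normalized peak
current (steady-state inactivation), peak ratios (recovery from
inactivation, test/conditioning), 10–90% rise and 90–20% fall times
(threshold crossings linearly interpolated between samples), minimum
absolute current over driving force (deactivation), and normalized
conductance traces.  Peaks are taken as the grid maximum of `|I(t)|`; trace
features are thinned to a configurable output spacing.  Sweep voltages
within 1 mV of the reversal potential are rejected at protocol validation
(driving-force singularity).  A feature whose thresholds are never crossed
(e.g. the rise time of a sweep that never activates) is reported as
undefined rather than an error, and contributes a fixed residual
(default 10² per row) to the cost so the annealer can move away from
pathological models without aborting.

## Cost

    cost = Σ_rows w·(simulated − observed)² + λ·max_v |λ_max(Q(v))|

The first term is weighted squared error over all dataset rows (equal
weight per row by default; per-row weights are in the dataset format).
Protocols sharing an identical step sequence (e.g. a G-V sweep and the
rise-time measurement on the same pulses) are simulated once per
evaluation.  The second term penalizes stiffness: the largest-magnitude
eigenvalue of `Q(v)` over a grid (default −120…+20 mV in 10 mV steps, in
ms⁻¹) measures the fastest mode; `λ = penalty_weight` defaults to `1e-4`
per ms⁻¹ (`0` reproduces the unpenalized variant).  Simulation failure
(rate overflow, degenerate generator) yields an infinite cost and certain
rejection.

## Optimization

Synchronous multi-chain simulated annealing searches jointly over model
structure and rate parameters.  All chains share one exponential schedule
`T(t) = T0·γ^t` but never exchange information; perturbation and
Metropolis acceptance (`P = min(1, exp(−Δe/T))`) are per chain.

Every proposal applies a sparse rate update: each parameter entry moves
with probability `p` by a `N(0, σ·scale)` increment, where `scale` is the
per-basis-component width used at initialization (offsets on scale 1,
linear voltage coefficients on scale 0.2), so voltage coefficients move on
their natural scale.  With probability `move_probs[·]` a proposal
additionally applies a structural move: state addition (new non-conducting
state joined by one random edge, fresh parameters), state removal (with
random reconnection of any disconnected components and re-pinning of the
gauge row), edge addition, edge removal (with reconnection; skipped when
irreparable).  The conductance vector is fixed after initialization — no
conductance move is part of the search — but an optional conductance-flip
move (default probability 0) is available for exploration.  Every proposal
is validated in tests: structure, gauge, and detailed-balance residual.

Defaults (all in `AnnealConfig`): 12 chains, `p = 0.2`, `σ = 0.1` decaying
exponentially to `σ_final = 0.01` over the run (a fixed kernel schedule
mirroring the temperature schedule — late proposals refine rather than
re-explore), structural move probabilities 0.02 each, 2–10 states,
`γ = 0.9925`, `T0 =` median initial chain cost.  The structural
probabilities and cooling rate were chosen against the synthetic recovery
study: higher structural churn lets chains balloon to the state cap during
the hot phase and then spend the whole run refining bloated models, and a
slower schedule leaves chains warmer than the noise floor at the end of a
run.  Each chain starts from the cheapest of 25 random draws: arbitrary
random models mostly sit on the missing-feature penalty plateau, and
anchoring `T0` (and the chains) at the scale of genuine data mismatch
spends the schedule on refinement instead of plateau diffusion.  Initial parameters are drawn with offset
components `~N(0, 1)` and voltage coefficients `~N(0, 0.2²)` (shrunk by
`120^(p−1)` for polynomial powers), keeping initial rates finite over
±120 mV; the same distributions supply parameters for states and edges
created by structural moves.

Reproducibility: the run is a pure function of the config seed; each chain
owns an independent child generator, so results equal sequential execution
regardless of any parallelism.

## Synthetic data

No experimental recordings are tabulated anywhere for these channels, so
ground-truth models stand in.  `na3` is a 3-state closed–open–inactivated
chain (linear basis) tuned to transient Na⁺-channel phenomenology: fast
activation (~0.4 ms at −20 mV), slower inactivation (~1.4 ms), recovery at
−120 mV on the tens-of-ms scale, G-V half-activation near −34 mV, SSI
midpoint near −70 mV.  `k4` is a 4-state chain with a bounded sigmoid basis
and delayed-rectifier-like monotone activation.  `synth_dataset` simulates
every protocol with the exponential backend and adds i.i.d. Gaussian noise
of sd `noise_sd ×` (per-protocol feature scale) to each row — noise on
features, not on raw traces, because the cost operates on features and no
noise model is prescribed for the recordings.  Rows whose feature is
undefined for the ground truth are dropped.

What the synthetic conditions do not emulate: correlated (non-stationary)
recording noise, leak and capacitance artifacts, series-resistance error,
temperature effects, and channel run-down.  Passing the recovery tests
therefore shows the estimator recovers a known member of its own model
class from feature-level noise — not that real Nav1.5/KCNQ1 recordings are
reproduced quantitatively.

## Protocol fixtures and problem sizes

Full Na⁺ suite: activation −120…+20 mV in 10 mV steps from −100 mV
(20 ms pulses sampled at 5 µs); SSI with 200 ms conditioning from −120 mV;
recovery with 200 ms conditioning at −20 mV and 1–1000 ms gaps;
rise/fall-time measurements on the activation pulses; a 5 ms normalized
conductance trace at −10 mV.  Full K⁺ suite: activation −100…+60 mV in
20 mV steps, 2 ms + 4 ms deactivation from −80 mV, rise time, traces at
−20/0/+40 mV over 4 ms.  Reversal potentials: E_Na = +50 mV, E_K = −90 mV.
The activation pulse lengths and sampling intervals are package choices
(only the sweep ranges, increments and conditioning durations are
prescribed by the protocol descriptions).

Each suite has a `reduced` variant — every other sweep value, shorter
conditioning (50 ms SSI, 20 ms recovery conditioning), coarser sampling
(50–100 µs) — used for the parameter-recovery studies and anywhere an
annealing run is embedded in a test.  The headline recovery study uses the
reduced Na⁺ suite, 1 % feature noise, 8 chains × 5000 iterations; the
stiffness-penalty comparison uses the recovery protocol alone with
4 chains × 600 iterations × 5 seeds per penalty setting.  Backend-agreement
checks draw random models resampled until their largest eigenvalue over the
stiffness grid is below 500 ms⁻¹ — physiologically plausible rate
magnitudes for which reference ODE integration is meaningful.

## Numerical choices and edge cases

- Canonical edge order: sorted (min, max) pairs; forward = low→high id.
- `H`-powering endpoint equals one-shot `e^(nΔtQ)` to 1e-12 (semigroup
  property, tested); every sampled occupancy conserves Σx = 1 to 1e-9.
- Tie-breaks: peaks take the first grid maximum (`argmax`); half-activation
  voltages interpolate the first upward crossing of 0.5 in ascending x.
- Degenerate inputs: 1-state models have `Q = [0]` and zero stiffness;
  protocols must record at least one step; empty edge sets are rejected by
  the reversibility system; disconnected generators raise.
- Model JSON round-trips parameter arrays bit-exactly (shortest-repr float
  encoding); dataset CSV is read with round-trip float precision.

## Known limitations

- No continuous-voltage (action-potential) simulation, no single-channel
  stochastic trajectories, no state aggregation or identifiability
  analysis, no irreversible (one-way) transitions.
- The annealer offers no replica exchange or adaptive cooling; convergence
  on multimodal structure landscapes depends on chain count and schedule.
- Feature matching joins dataset rows to simulated sweep values by nearest
  x within a relative tolerance of 1e-6; datasets must therefore use the
  same sweep values as the protocol they reference.
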