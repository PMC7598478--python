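"""Multi-agent formalism: states, residences, neighborhoods, rates, bounds.

A model is the tuple ``(G, S, {phi_v}, {psi_v}, S0)``: a contact network,
a finite set of local states, per-agent intensity functions ``phi_v``
(instantaneous firing rate given own state, own residence, and the
neighborhood), successor distributions ``psi_v``, and an initial state map.
For rejection-based simulation each (agent, state) additionally carries a
*rate over-approximation* — a dominating hazard guaranteed to upper-bound
``phi_v`` under every reachable future neighborhood.

This module also houses the naïve race-semantics simulator that defines
the ground-truth dynamics: every step, every agent samples a candidate
delay from its *effective rate* (its intensity extrapolated under a frozen
neighborhood) and the smallest delay fires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intensity import (
    NO_FIRE,
    IntensityFunction,
    sample_inversion,
    sample_thinning,
)
from .network import ContactNetwork

__all__ = [
    "NetworkState",
    "ModelSpec",
    "RateBound",
    "ZeroBound",
    "ConstantBound",
    "IntensityBound",
    "DirectBound",
    "neighborhood",
    "effective_rate",
    "simulate_naive",
    "validate_bound",
    "BoundReport",
    "ModelDefinitionError",
    "BoundInvalidError",
    "PathologicalModelError",
    "Trajectory",
    "TransitionRecord",
    "draw_successor",
]

#: A neighborhood is a list of triplets (neighbor state, neighbor residence,
#: neighbor identifier) — one per neighbor of the focal agent.
Neighborhood = List[Tuple[str, float, int]]


class ModelDefinitionError(ValueError):
    """phi returned a negative rate or psi is not a distribution."""


class BoundInvalidError(RuntimeError):
    """A rate over-approximation was observed below the true rate."""


class PathologicalModelError(RuntimeError):
    """The run exceeded the maximum event budget (diverging event density)."""


# ---------------------------------------------------------------------------
# Network state
# ---------------------------------------------------------------------------

class NetworkState:
    """Per-agent local state and last-change times, plus the global clock.

    Residence times are stored implicitly as ``R(v) = t_global - T(v)``
    where ``T(v)`` is the absolute time of v's last state change; this keeps
    per-event bookkeeping O(1) (no bulk residence updates).
    """

    __slots__ = ("states", "last_change", "t_global")

    def __init__(self, states: Sequence[str], t_global: float = 0.0):
        self.states: List[str] = list(states)
        self.last_change: List[float] = [0.0] * len(self.states)
        self.t_global = float(t_global)

    def residence(self, v: int) -> float:
        return self.t_global - self.last_change[v]


def neighborhood(network: ContactNetwork, state: NetworkState, v: int) -> Neighborhood:
    """The triplet set M(v): (state, residence, id) for each neighbor of v."""
    t = state.t_global
    lc = state.last_change
    s = state.states
    return [(s[w], t - lc[w], w) for w in network.adjacency[v]]


# ---------------------------------------------------------------------------
# Rate over-approximations
# ---------------------------------------------------------------------------

class RateBound:
    """Dominating hazard for one (agent, local state) pair.

    ``rate(residence)`` evaluates the bound at an absolute residence time;
    ``sample_delay(rng, residence, horizon)`` samples a delay from the bound
    hazard *shifted to the current residence* (the conditional law from
    ``residence`` onward), returning :data:`NO_FIRE` for delays beyond the
    horizon.  ``exact`` marks neighbor-independent rates sampled from the
    true law (the event is then never rejected).
    """

    exact: bool = False

    def rate(self, residence: float) -> float:
        raise NotImplementedError

    def sample_delay(self, rng: np.random.Generator, residence: float,
                     horizon: float) -> float:
        raise NotImplementedError


class ZeroBound(RateBound):
    """The agent can never fire in this state."""

    def rate(self, residence: float) -> float:
        return 0.0

    def sample_delay(self, rng, residence, horizon) -> float:
        return NO_FIRE


class ConstantBound(RateBound):
    """Time-independent dominating rate: delays are exponential."""

    __slots__ = ("c",)

    def __init__(self, c: float):
        if c < 0:
            raise ModelDefinitionError("bound rate must be nonnegative")
        self.c = float(c)

    def rate(self, residence: float) -> float:
        return self.c

    def sample_delay(self, rng, residence, horizon) -> float:
        if self.c == 0.0:
            return NO_FIRE
        return rng.exponential(1.0 / self.c)


class IntensityBound(RateBound):
    """Time-varying dominating hazard, sampled by thinning or inversion.

    ``intensity`` is the bound as a function of the focal agent's residence.
    Regeneration from residence ``r`` samples the shifted hazard
    ``t -> intensity(r + t)``; for thinning the dominating constant ``c``
    must upper-bound the hazard on the run horizon (violations raise at
    sample time).
    """

    __slots__ = ("intensity", "method", "c")

    def __init__(self, intensity: IntensityFunction, method: str = "thinning",
                 c: Optional[float] = None):
        if method not in ("thinning", "inversion"):
            raise ValueError("method must be 'thinning' or 'inversion'")
        if method == "thinning" and c is None:
            raise ValueError("thinning requires a dominating constant c")
        self.intensity = intensity
        self.method = method
        self.c = c

    def rate(self, residence: float) -> float:
        return self.intensity(residence)

    def sample_delay(self, rng, residence, horizon) -> float:
        shifted = shift_intensity(self.intensity, residence)
        if self.method == "thinning":
            return sample_thinning(shifted, self.c, rng, horizon)
        delay = sample_inversion(shifted, rng)
        return delay if delay <= horizon else NO_FIRE


class DirectBound(RateBound):
    """Exact sampling of a neighbor-independent rate (never rejected).

    ``sampler(rng, residence)`` draws the remaining delay from the true
    conditional law; ``rate_fn(residence)`` is the true hazard, reported as
    the bound-at-firing so the dominator identity ``mu_hat == mu`` holds.
    """

    exact = True
    __slots__ = ("sampler", "rate_fn")

    def __init__(self, sampler: Callable[[np.random.Generator, float], float],
                 rate_fn: Callable[[float], float]):
        self.sampler = sampler
        self.rate_fn = rate_fn

    def rate(self, residence: float) -> float:
        return self.rate_fn(residence)

    def sample_delay(self, rng, residence, horizon) -> float:
        return self.sampler(rng, residence)


def shift_intensity(intensity: IntensityFunction, r: float) -> IntensityFunction:
    """The hazard conditioned on having survived to residence ``r``.

    Returns ``t -> rate(r + t)`` with cumulative ``Lambda(r+t) - Lambda(r)``;
    closed forms are propagated when available.
    """
    if r == 0.0:
        return intensity
    base = intensity.cumulative_at(r)
    inv = None
    if intensity.inverse_cumulative is not None and math.isfinite(base):
        inv = lambda x: intensity.inverse_cumulative(x + base) - r  # noqa: E731
    cum = None
    if intensity.cumulative is not None:
        cum = lambda t: intensity.cumulative(r + t) - base  # noqa: E731
    return IntensityFunction(
        rate=lambda t: intensity.rate(r + t),
        cumulative=cum,
        inverse_cumulative=inv,
        total_mass=intensity.total_mass - base,
        support=intensity.support - r,
        breakpoints=tuple(p - r for p in intensity.breakpoints if p > r),
        name=f"{intensity.name}|{r:g}",
    )


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """The tuple (G, S, {phi_v}, {psi_v}, S0) plus rate bounds.

    ``phi(v, s, r, m)`` and ``psi(v, s, r, m)`` receive the agent id, its
    local state, its residence time, and the neighborhood triplet list;
    ``psi`` returns a dict mapping successor states to probabilities
    (summing to one within 1e-12).  ``bound(v, s)`` returns the
    :class:`RateBound` for that agent/state.  ``effective_intensity``, when
    provided, returns a closed-form :class:`IntensityFunction` for the
    effective rate of ``(v, s)`` at residence ``r`` under neighborhood ``m``
    (as a function of the delay from *now*); exact engines fall back to
    numeric quadrature of ``phi`` otherwise.  ``direct_samplers`` maps local
    states with neighbor-independent rates to exact delay samplers
    ``(v, r, m, rng) -> delay`` used by the naive/baseline engines (e.g. the
    Laplace–Gillespie mixture of the voter model).
    """

    network: ContactNetwork
    states: Tuple[str, ...]
    phi: Callable[[int, str, float, Neighborhood], float]
    psi: Callable[[int, str, float, Neighborhood], Dict[str, float]]
    initial_state: Sequence[str]
    bound: Callable[[int, str], RateBound]
    effective_intensity: Optional[
        Callable[[int, str, float, Neighborhood], IntensityFunction]] = None
    direct_samplers: Dict[str, Callable] = field(default_factory=dict)
    max_residence: Callable[[str], float] = lambda s: math.inf
    name: str = "model"

    def __post_init__(self):
        if len(self.states) == 0:
            raise ModelDefinitionError("state set must be non-empty")
        if len(set(self.states)) != len(self.states):
            raise ModelDefinitionError("state labels must be unique")
        if len(self.initial_state) != self.network.n:
            raise ModelDefinitionError("initial state map must cover all agents")

    def initial_network_state(self) -> NetworkState:
        return NetworkState(self.initial_state)


def effective_rate(model: ModelSpec, state: NetworkState, v: int,
                   t_delta: float) -> float:
    """phi of agent v extrapolated ``t_delta`` ahead under a frozen neighborhood.

    Both the focal residence and every neighbor residence advance by
    ``t_delta``; no state changes are assumed.
    """
    if t_delta < 0:
        raise ValueError("t_delta must be nonnegative")
    r = state.residence(v)
    t = state.t_global
    lc = state.last_change
    s = state.states
    m = [(s[w], t - lc[w] + t_delta, w) for w in model.network.adjacency[v]]
    val = model.phi(v, s[v], r + t_delta, m)
    if val < 0:
        raise ModelDefinitionError(f"phi returned negative rate {val} for agent {v}")
    return val


def draw_successor(model: ModelSpec, v: int, s: str, r: float,
                   m: Neighborhood, rng: np.random.Generator) -> str:
    """Sample the successor state from psi, asserting normalization."""
    p = model.psi(v, s, r, m)
    total = 0.0
    for state_label, prob in p.items():
        if prob < 0:
            raise ModelDefinitionError(f"psi gave negative probability for {state_label}")
        total += prob
    if abs(total - 1.0) > 1e-12:
        raise ModelDefinitionError(f"psi probabilities sum to {total}, not 1")
    u = rng.random()
    acc = 0.0
    last = s
    for state_label in model.states:
        prob = p.get(state_label, 0.0)
        if prob > 0.0:
            acc += prob
            last = state_label
            if u < acc:
                return state_label
    return last


# ---------------------------------------------------------------------------
# Trajectories (shared by all engines; re-exported by redsim.engines)
# ---------------------------------------------------------------------------

@dataclass
class TransitionRecord:
    time: float
    agent: int
    old_state: str
    new_state: str


@dataclass
class Trajectory:
    """Time-ordered accepted transitions plus instrumentation counters."""

    engine: str
    horizon: float
    initial_state: List[str]
    records: List[TransitionRecord] = field(default_factory=list)
    accepted: int = 0
    rejected: int = 0
    phi_evaluations: int = 0
    neighbor_lookups: int = 0
    neighbor_regenerations: int = 0
    per_event_neighbor_lookups: List[int] = field(default_factory=list)
    final_state: Optional[NetworkState] = None

    @property
    def n_agents(self) -> int:
        return len(self.initial_state)

    def state_fractions(self, states: Sequence[str], t: float) -> Dict[str, float]:
        """Fraction of agents per local state at time ``t`` (replayed from S0)."""
        if t < 0 or t > self.horizon:
            raise ValueError(f"probe time {t} outside [0, {self.horizon}]")
        current = list(self.initial_state)
        for rec in self.records:
            if rec.time > t:
                break
            current[rec.agent] = rec.new_state
        n = len(current)
        return {s: current.count(s) / n for s in states}


# ---------------------------------------------------------------------------
# True-law delay sampling (shared by the naive and baseline engines)
# ---------------------------------------------------------------------------

def sample_true_delay(model: ModelSpec, state: NetworkState, v: int,
                      rng: np.random.Generator, horizon: float,
                      counters: Optional[Trajectory] = None) -> float:
    """Delay from agent v's true effective rate at the current residence.

    Uses, in order of preference: a registered exact sampler for
    neighbor-independent (or mixture-expressible) rates; a closed-form
    effective intensity; generic inversion with numeric quadrature of phi.
    """
    s = state.states[v]
    r = state.residence(v)
    if counters is not None:
        counters.neighbor_lookups += model.network.degree(v)
    direct = model.direct_samplers.get(s)
    if direct is not None:
        m = neighborhood(model.network, state, v)
        return direct(v, r, m, rng)
    if model.effective_intensity is not None:
        m = neighborhood(model.network, state, v)
        eff = model.effective_intensity(v, s, r, m)
        if counters is not None:
            counters.phi_evaluations += 1
        if eff.total_mass == 0.0:
            return NO_FIRE
        return sample_inversion(eff, rng)
    # Generic numeric fallback: quadrature + root-finding on phi itself.
    if counters is not None:
        counters.phi_evaluations += 1
    eff = IntensityFunction(rate=lambda td: effective_rate(model, state, v, td))
    return sample_inversion(eff, rng)


# ---------------------------------------------------------------------------
# The naive (race-semantics) reference simulator
# ---------------------------------------------------------------------------

def simulate_naive(model: ModelSpec, horizon: float,
                   rng: np.random.Generator | int | None = None,
                   max_events: int = 10 ** 6) -> Trajectory:
    """Ground-truth simulator implementing the race semantics verbatim.

    Every step each agent samples a candidate delay from its effective rate;
    the minimum fires, its successor is drawn from psi at the residence at
    firing, and the loop repeats.  Statistically exact but quadratic —
    intended as the oracle on small instances only.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    state = model.initial_network_state()
    traj = Trajectory(engine="naive", horizon=horizon,
                      initial_state=list(model.initial_state))
    n = model.network.n
    while True:
        best_delay = NO_FIRE
        best_agent = -1
        for v in range(n):
            d = sample_true_delay(model, state, v, rng, horizon - state.t_global,
                                  counters=traj)
            if d < best_delay:
                best_delay = d
                best_agent = v
        if best_agent < 0 or state.t_global + best_delay > horizon:
            state.t_global = horizon
            break
        state.t_global += best_delay
        v = best_agent
        r_fire = state.t_global - state.last_change[v]
        m = neighborhood(model.network, state, v)
        s_old = state.states[v]
        s_new = draw_successor(model, v, s_old, r_fire, m, rng)
        if s_new != s_old:
            state.states[v] = s_new
            state.last_change[v] = state.t_global
            traj.records.append(TransitionRecord(state.t_global, v, s_old, s_new))
        traj.accepted += 1
        if traj.accepted > max_events:
            raise PathologicalModelError(
                f"exceeded {max_events} events before t={horizon}")
    traj.final_state = state
    return traj


# ---------------------------------------------------------------------------
# Bound validation
# ---------------------------------------------------------------------------

@dataclass
class BoundReport:
    n_probes: int
    n_violations: int
    worst_margin: float            # min over probes of (bound - phi)
    mean_acceptance: float         # mean phi / bound over probes with bound > 0
    violations: List[dict] = field(default_factory=list)


def validate_bound(model: ModelSpec, n_probes: int = 10 ** 4,
                   rng: np.random.Generator | int | None = None,
                   horizon: float = 2.0,
                   raise_on_violation: bool = True) -> BoundReport:
    """Stochastic check that every bound dominates phi on random configurations.

    Each probe assigns a random focal state and residence and random
    neighbor states/residences (each residence within the state's
    reachable range and the horizon), then asserts
    ``bound.rate(residence) >= phi``.  The mean acceptance ratio
    ``phi / bound`` forecasts the rejection rate of the rejection-based
    engine.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    net = model.network
    worst = math.inf
    acc_sum = 0.0
    acc_n = 0
    violations: List[dict] = []

    def rand_residence(s: str) -> float:
        cap = min(horizon, model.max_residence(s))
        return rng.random() * cap

    n_states = len(model.states)
    for _ in range(n_probes):
        v = int(rng.integers(net.n))
        s = model.states[int(rng.integers(n_states))]
        rho = rand_residence(s)
        m = []
        for w in net.adjacency[v]:
            sw = model.states[int(rng.integers(n_states))]
            m.append((sw, rand_residence(sw), w))
        phi_val = model.phi(v, s, rho, m)
        if phi_val < 0:
            raise ModelDefinitionError(f"phi returned negative rate for agent {v}")
        b = model.bound(v, s)
        b_val = b.rate(rho)
        margin = b_val - phi_val
        worst = min(worst, margin)
        if b_val > 0:
            acc_sum += min(phi_val / b_val, 1.0)
            acc_n += 1
        if phi_val > b_val * (1.0 + 1e-9) + 1e-12:
            record = {"agent": v, "state": s, "residence": rho,
                      "neighborhood": m, "phi": phi_val, "bound": b_val}
            violations.append(record)
            if raise_on_violation:
                raise BoundInvalidError(
                    f"bound violated for agent {v} in state {s} at residence "
                    f"{rho:.6g}: phi={phi_val:.6g} > bound={b_val:.6g} "
                    f"(neighborhood {m})")
    return BoundReport(n_probes=n_probes, n_violations=len(violations),
                       worst_margin=worst,
                       mean_acceptance=acc_sum / max(acc_n, 1),
                       violations=violations)
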