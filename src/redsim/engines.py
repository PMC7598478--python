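"""Production simulation engines: RED, rejection-free baseline, approximate nMGA.

RED (rejection-based event-driven) keeps one pending event per agent in a
priority queue.  Events are sampled from each agent's rate
over-approximation, so neighbor events never need updating when an agent
fires; the over-sampling is compensated at pop time by rejecting the firing
with probability ``1 - mu/mu_hat``, where ``mu`` is the true instantaneous
rate and ``mu_hat`` the bound evaluated at the sampled delay.  The rejected
pops are the firings of the *shadow process* with rate
``lambda_hat - lambda``; together they leave the accepted-event law exactly
the model's semantics, so RED is statistically exact.

The rejection-free baseline samples events from the true effective rates
and therefore must invalidate and regenerate the events of every neighbor
after each state change (lazy deletion via version stamps).  The
approximate nMGA engine redraws an exponential delay for every agent each
step at its current instantaneous rate; it is exact only for Markovian
models.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .intensity import NO_FIRE
from .model_core import (
    BoundInvalidError,
    ModelSpec,
    NetworkState,
    PathologicalModelError,
    RateBound,
    TransitionRecord,
    Trajectory,
    draw_successor,
    neighborhood,
    sample_true_delay,
)

__all__ = [
    "Event",
    "EventQueue",
    "generate_event",
    "simulate_red",
    "simulate_baseline",
    "simulate_nmga",
    "simulate",
    "step_cost_counters",
    "StepCostReport",
    "ENGINES",
]


@dataclass(frozen=True)
class Event:
    """A prospective firing: agent, bound-at-firing, absolute firing time."""

    agent: int
    mu_hat: float
    t_hat: float      # +inf encodes NO_FIRE (never fires within the horizon)
    version: int = 0  # stamp for lazy deletion (baseline engine only)


class EventQueue:
    """Min-heap of events keyed by firing time, ties broken by agent id.

    A push sequence number makes heap comparisons total (repeated never-fire
    events of one agent would otherwise compare Event objects).
    """

    __slots__ = ("_heap", "_seq")

    def __init__(self):
        self._heap = []
        self._seq = 0

    def push(self, event: Event) -> None:
        self._seq += 1
        heapq.heappush(self._heap, (event.t_hat, event.agent, self._seq, event))

    def pop(self) -> Event:
        return heapq.heappop(self._heap)[3]

    def __len__(self) -> int:
        return len(self._heap)


def generate_event(model: ModelSpec, state: NetworkState, v: int,
                   t_global: float, rng: np.random.Generator,
                   horizon: float = math.inf, version: int = 0) -> Event:
    """Sample agent v's next prospective firing from its rate bound.

    The delay is drawn from the dominating hazard shifted to v's current
    residence; the event records ``mu_hat = lambda_hat(residence + delay)``,
    the bound at the prospective firing.  A delay beyond the horizon (or a
    defective no-fire draw) maps to ``t_hat = +inf``.
    """
    s = state.states[v]
    bound: RateBound = model.bound(v, s)
    r = t_global - state.last_change[v]
    delay = bound.sample_delay(rng, r, horizon - t_global)
    if delay == NO_FIRE or t_global + delay > horizon:
        return Event(v, 0.0, math.inf, version)
    return Event(v, bound.rate(r + delay), t_global + delay, version)


def _coerce_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# RED
# ---------------------------------------------------------------------------

def simulate_red(model: ModelSpec, horizon: float,
                 rng: np.random.Generator | int | None = None,
                 max_events: int = 10 ** 6,
                 instrument: bool = False,
                 rejection_scale: float = 1.0) -> Trajectory:
    """Rejection-based event-driven simulation (statistically exact).

    One pending event per agent; popping an event costs one phi evaluation
    (linear in the agent's degree) and, on acceptance, one event
    regeneration — neighbor events are never touched.

    ``rejection_scale`` multiplies the rejection probability; it exists
    solely as a mutation hook for the statistical validation harness
    (any value other than 1.0 makes the engine deliberately wrong).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = _coerce_rng(rng)
    state = model.initial_network_state()
    traj = Trajectory(engine="red", horizon=horizon,
                      initial_state=list(model.initial_state))
    queue = EventQueue()
    for v in range(model.network.n):
        queue.push(generate_event(model, state, v, 0.0, rng, horizon))

    processed = 0
    while queue:
        ev = queue.pop()
        if ev.t_hat > horizon:
            break
        v = ev.agent
        state.t_global = ev.t_hat
        r = ev.t_hat - state.last_change[v]
        m = neighborhood(model.network, state, v)
        s = state.states[v]
        mu = model.phi(v, s, r, m)
        traj.phi_evaluations += 1
        lookups = model.network.degree(v) + 1
        traj.neighbor_lookups += lookups
        if instrument:
            traj.per_event_neighbor_lookups.append(lookups)
        if mu < 0:
            raise BoundInvalidError(f"phi returned negative rate for agent {v}")

        bound = model.bound(v, s)
        if bound.exact:
            accept = True
        else:
            if mu > ev.mu_hat * (1.0 + 1e-9):
                raise BoundInvalidError(
                    f"true rate {mu:.6g} exceeds bound-at-firing {ev.mu_hat:.6g} "
                    f"for agent {v} in state {s} at t={ev.t_hat:.6g}")
            p_reject = (1.0 - mu / ev.mu_hat) * rejection_scale if ev.mu_hat > 0 else 1.0
            accept = rng.random() >= p_reject

        if accept:
            s_new = draw_successor(model, v, s, r, m, rng)
            if s_new != s:
                state.states[v] = s_new
                state.last_change[v] = ev.t_hat
                traj.records.append(TransitionRecord(ev.t_hat, v, s, s_new))
            traj.accepted += 1
        else:
            traj.rejected += 1
        queue.push(generate_event(model, state, v, ev.t_hat, rng, horizon))

        processed += 1
        if processed > max_events:
            raise PathologicalModelError(
                f"exceeded {max_events} processed events before t={horizon}")
    state.t_global = horizon
    traj.final_state = state
    return traj


# ---------------------------------------------------------------------------
# Rejection-free event-driven baseline
# ---------------------------------------------------------------------------

def simulate_baseline(model: ModelSpec, horizon: float,
                      rng: np.random.Generator | int | None = None,
                      max_events: int = 10 ** 6,
                      instrument: bool = False) -> Trajectory:
    """Event-driven simulation from the true effective rates (exact, no rejections).

    After every state change the events of all neighbors are invalidated
    and regenerated from their current residences, since their rates may
    have changed.  Invalidation uses lazy deletion: each agent carries a
    version stamp and stale events are discarded at pop time (behaviorally
    identical to in-place removal).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = _coerce_rng(rng)
    state = model.initial_network_state()
    traj = Trajectory(engine="baseline", horizon=horizon,
                      initial_state=list(model.initial_state))
    queue = EventQueue()
    n = model.network.n
    version = [0] * n

    def regen(v: int, t_global: float) -> None:
        delay = sample_true_delay(model, state, v, rng, horizon - t_global,
                                  counters=traj)
        t_hat = math.inf if delay == NO_FIRE else t_global + delay
        if t_hat > horizon:
            t_hat = math.inf
        queue.push(Event(v, 0.0, t_hat, version[v]))

    saved_t = state.t_global
    for v in range(n):
        regen(v, 0.0)
    state.t_global = saved_t

    processed = 0
    while queue:
        ev = queue.pop()
        if ev.version != version[ev.agent]:
            continue  # stale (lazily deleted)
        if ev.t_hat > horizon:
            break
        v = ev.agent
        state.t_global = ev.t_hat
        r = ev.t_hat - state.last_change[v]
        m = neighborhood(model.network, state, v)
        s = state.states[v]
        s_new = draw_successor(model, v, s, r, m, rng)
        traj.accepted += 1
        version[v] += 1
        if s_new != s:
            state.states[v] = s_new
            state.last_change[v] = ev.t_hat
            traj.records.append(TransitionRecord(ev.t_hat, v, s, s_new))
            regen(v, ev.t_hat)
            regen_count = 0
            for w in model.network.adjacency[v]:
                version[w] += 1
                regen(w, ev.t_hat)
                regen_count += 1
            traj.neighbor_regenerations += regen_count
            if instrument:
                traj.per_event_neighbor_lookups.append(
                    sum(model.network.degree(w) for w in model.network.adjacency[v]))
        else:
            regen(v, ev.t_hat)  # self-loop: no state transition, no invalidation
            if instrument:
                traj.per_event_neighbor_lookups.append(0)
        processed += 1
        if processed > max_events:
            raise PathologicalModelError(
                f"exceeded {max_events} processed events before t={horizon}")
    state.t_global = horizon
    traj.final_state = state
    return traj


# ---------------------------------------------------------------------------
# Approximate nMGA
# ---------------------------------------------------------------------------

def simulate_nmga(model: ModelSpec, horizon: float,
                  rng: np.random.Generator | int | None = None,
                  max_events: int = 10 ** 6,
                  instrument: bool = False) -> Trajectory:
    """Approximate engine: rates held constant between events.

    Each step draws, for every agent, an exponential delay at its current
    instantaneous rate and fires the minimum.  Exact only when all
    intensities are residence-independent (Markovian); the approximation
    error shrinks as the network grows and inter-event gaps vanish.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = _coerce_rng(rng)
    state = model.initial_network_state()
    traj = Trajectory(engine="nmga", horizon=horizon,
                      initial_state=list(model.initial_state))
    n = model.network.n
    while True:
        best_delay = math.inf
        best_agent = -1
        for v in range(n):
            m = neighborhood(model.network, state, v)
            rate = model.phi(v, state.states[v], state.residence(v), m)
            traj.phi_evaluations += 1
            traj.neighbor_lookups += model.network.degree(v)
            if rate > 0:
                d = rng.exponential(1.0 / rate)
                if d < best_delay:
                    best_delay = d
                    best_agent = v
        if best_agent < 0 or state.t_global + best_delay > horizon:
            break
        state.t_global += best_delay
        v = best_agent
        r = state.t_global - state.last_change[v]
        m = neighborhood(model.network, state, v)
        s = state.states[v]
        s_new = draw_successor(model, v, s, r, m, rng)
        if s_new != s:
            state.states[v] = s_new
            state.last_change[v] = state.t_global
            traj.records.append(TransitionRecord(state.t_global, v, s, s_new))
        traj.accepted += 1
        if traj.accepted > max_events:
            raise PathologicalModelError(
                f"exceeded {max_events} events before t={horizon}")
    state.t_global = horizon
    traj.final_state = state
    return traj


from .model_core import simulate_naive  # noqa: E402  (re-export: engine registry)

ENGINES = {
    "red": simulate_red,
    "baseline": simulate_baseline,
    "nmga": simulate_nmga,
    "naive": simulate_naive,
}


def simulate(engine: str, model: ModelSpec, horizon: float,
             rng=None, **kwargs) -> Trajectory:
    """Run a named engine ('red', 'baseline', 'nmga', 'naive')."""
    try:
        fn = ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    return fn(model, horizon, rng, **kwargs)


# ---------------------------------------------------------------------------
# Step-cost instrumentation
# ---------------------------------------------------------------------------

@dataclass
class StepCostReport:
    engine: str
    processed_events: int
    accepted: int
    rejected: int
    phi_evaluations_per_accepted: float
    neighbor_lookups_per_event: float
    max_neighbor_lookups_per_event: int
    neighbor_regenerations_per_accepted: float


def step_cost_counters(trajectory: Trajectory) -> StepCostReport:
    """Per-event operation counts (the hardware-independent cost measure).

    For RED the per-event neighbor-lookup count is bounded by the firing
    agent's degree plus one; for the baseline it includes the two-hop
    regeneration cost (sum of neighbor degrees).
    """
    processed = trajectory.accepted + trajectory.rejected
    per_event = trajectory.per_event_neighbor_lookups
    return StepCostReport(
        engine=trajectory.engine,
        processed_events=processed,
        accepted=trajectory.accepted,
        rejected=trajectory.rejected,
        phi_evaluations_per_accepted=(
            trajectory.phi_evaluations / trajectory.accepted
            if trajectory.accepted else 0.0),
        neighbor_lookups_per_event=(
            trajectory.neighbor_lookups / processed if processed else 0.0),
        max_neighbor_lookups_per_event=max(per_event) if per_event else 0,
        neighbor_regenerations_per_accepted=(
            trajectory.neighbor_regenerations / trajectory.accepted
            if trajectory.accepted else 0.0),
    )
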