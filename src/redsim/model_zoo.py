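"""Ready-made multi-agent models with their intensities, successors, and bounds.

Five models are registered:

``markovian_sis``
    Classical SIS: infection at rate ``c_i`` per infected neighbor, recovery
    at constant rate ``c_r``; fully memoryless.
``nonmarkovian_sis``
    Infected agents attack susceptible neighbors at rate ``u e^{-u t}``
    (waning infectiousness, residence ``t``); attacks from distinct
    neighbors superpose.  Recovery times are uniform on [0, 1], sampled
    exactly.  Susceptible bound: ``u k_v``.
``complex_cascade``
    S/I/R information cascade: a susceptible agent with at least one
    infected neighbor fires at rate ``e^{-t_dist}`` where ``t_dist`` is the
    residence of the *most recently infected* neighbor; the firing infects
    with probability ``p_i`` and immunizes otherwise.  I and R are absorbing.
``voter_lga``
    Two competing opinions A/B.  The inter-event law is a uniform mixture
    of exponentials with rates in ``[0, o_v]`` (``o_v`` = fraction of
    opposing neighbors), i.e. hazard ``1/t - o_v/(e^{o_v t}-1)``; the
    rejection-based engine dominates it with the ``o_v = 1`` hazard
    (decreasing from 1/2, thinned at c = 1/2) while the exact engines
    sample the mixture Laplace–Gillespie style.
``neural_point_process``
    Multivariate point process: each neuron fires at
    ``f(b + sum_w w/(1+t'))`` with response ``f(x) = max(0, tanh(x))``,
    signed edge weights (a seeded fraction inhibitory), and baseline
    intensity ``b``.  Firing is encoded as alternation between two
    equivalent excitable states so every spike genuinely resets the
    residence clock without any special self-loop rule.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intensity import (
    constant_hazard,
    exponential_decay_hazard,
    sample_exponential_mixture,
    uniform_mixture_rate_sampler,
    voter_hazard,
)
from .model_core import (
    ConstantBound,
    DirectBound,
    IntensityBound,
    ModelSpec,
    ZeroBound,
)
from .network import ContactNetwork

__all__ = [
    "markovian_sis",
    "nonmarkovian_sis",
    "complex_cascade",
    "voter_lga",
    "neural_point_process",
    "random_infected_initial",
    "random_binary_initial",
    "MODELS",
]

_ZERO = ZeroBound()


def random_infected_initial(n: int, fraction: float,
                            rng: np.random.Generator,
                            infected: str = "I", susceptible: str = "S"
                            ) -> List[str]:
    """Initial map with ``max(1, round(fraction*n))`` random infected agents."""
    k = max(1, int(round(fraction * n)))
    chosen = set(rng.choice(n, size=k, replace=False).tolist())
    return [infected if v in chosen else susceptible for v in range(n)]


def random_binary_initial(n: int, rng: np.random.Generator,
                          a: str = "A", b: str = "B") -> List[str]:
    """Uniformly random half/half assignment of two labels."""
    perm = rng.permutation(n)
    half = n // 2
    states = [a] * n
    for v in perm[half:]:
        states[v] = b
    return states


def _coerce_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Markovian SIS
# ---------------------------------------------------------------------------

def markovian_sis(network: ContactNetwork, c_i: float, c_r: float,
                  initial_infected_fraction: float = 0.05,
                  initial_states: Optional[Sequence[str]] = None,
                  seed=None) -> ModelSpec:
    """Memoryless SIS: phi(I) = c_r, phi(S) = c_i * (#infected neighbors)."""
    if c_i < 0 or c_r < 0:
        raise ValueError("rates c_i, c_r must be nonnegative")
    if initial_states is None:
        initial_states = random_infected_initial(
            network.n, initial_infected_fraction, _coerce_rng(seed))

    def phi(v, s, t, m):
        if s == "I":
            return c_r
        return c_i * sum(1 for s2, _, _ in m if s2 == "I")

    def psi(v, s, t, m):
        return {"S": 1.0} if s == "I" else {"I": 1.0}

    recovery = DirectBound(
        sampler=lambda rng, r: rng.exponential(1.0 / c_r) if c_r > 0 else math.inf,
        rate_fn=lambda r: c_r)
    s_bounds = {}  # one ConstantBound per distinct degree

    def bound(v, s):
        if s == "I":
            return recovery
        k = network.degree(v)
        if k not in s_bounds:
            s_bounds[k] = ConstantBound(k * c_i) if k * c_i > 0 else _ZERO
        return s_bounds[k]

    def eff_intensity(v, s, r, m):
        if s == "I":
            return constant_hazard(c_r)
        n_inf = sum(1 for s2, _, _ in m if s2 == "I")
        return constant_hazard(c_i * n_inf)

    return ModelSpec(network=network, states=("S", "I"), phi=phi, psi=psi,
                     initial_state=list(initial_states), bound=bound,
                     effective_intensity=eff_intensity, name="markovian_sis")


# ---------------------------------------------------------------------------
# Non-Markovian SIS (waning infectiousness, uniform recovery)
# ---------------------------------------------------------------------------

def nonmarkovian_sis(network: ContactNetwork, u: float = 0.4,
                     initial_infected_fraction: float = 0.05,
                     initial_states: Optional[Sequence[str]] = None,
                     seed=None) -> ModelSpec:
    """SIS with attack rate ``u e^{-u t'}`` per infected neighbor.

    The susceptible intensity is the superposition of the attack processes
    of all infected neighbors, hence bounded by ``u k_v``.  Recovery times
    are uniform on [0, 1] — hazard ``1/(1-t)`` — and neighbor-independent,
    so they are sampled exactly (never rejected).
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if initial_states is None:
        initial_states = random_infected_initial(
            network.n, initial_infected_fraction, _coerce_rng(seed))

    def infection_pressure(m) -> float:
        return sum(u * math.exp(-u * t2) for s2, t2, _ in m if s2 == "I")

    def phi(v, s, t, m):
        if s == "I":
            return 1.0 / max(1.0 - t, 1e-12)  # uniform[0,1] recovery hazard
        return infection_pressure(m)

    def psi(v, s, t, m):
        return {"S": 1.0} if s == "I" else {"I": 1.0}

    def recovery_sampler(rng, r):
        remaining = 1.0 - r
        if remaining <= 0:
            return 0.0  # unreachable: infected residence never exceeds 1
        return rng.uniform(0.0, remaining)

    recovery = DirectBound(sampler=recovery_sampler,
                           rate_fn=lambda r: 1.0 / max(1.0 - r, 1e-12))
    s_bounds = {}

    def bound(v, s):
        if s == "I":
            return recovery
        k = network.degree(v)
        if k not in s_bounds:
            s_bounds[k] = ConstantBound(u * k)
        return s_bounds[k]

    def eff_intensity(v, s, r, m):
        if s == "I":  # not used (direct sampler), but keep the surface total
            return constant_hazard(0.0)
        amp = infection_pressure(m)
        if amp == 0.0:
            return constant_hazard(0.0)
        return exponential_decay_hazard(amp, u)

    return ModelSpec(
        network=network, states=("S", "I"), phi=phi, psi=psi,
        initial_state=list(initial_states), bound=bound,
        effective_intensity=eff_intensity,
        direct_samplers={"I": lambda v, r, m, rng: recovery_sampler(rng, r)},
        max_residence=lambda s: 1.0 if s == "I" else math.inf,
        name="nonmarkovian_sis")


# ---------------------------------------------------------------------------
# Complex cascade
# ---------------------------------------------------------------------------

def complex_cascade(network: ContactNetwork, p_i: float,
                    initial_infected_fraction: float = 0.05,
                    initial_states: Optional[Sequence[str]] = None,
                    seed=None) -> ModelSpec:
    """S/I/R cascade driven by the most recently infected neighbor.

    ``phi(S) = e^{-t_dist}`` with ``t_dist`` the minimum residence among
    infected neighbors (zero intensity without infected neighbors);
    infected and removed agents are absorbing.  The successor of a firing
    susceptible agent is I with probability ``p_i``, else R.
    """
    if not 0.0 <= p_i <= 1.0:
        raise ValueError("p_i must lie in [0, 1]")
    if initial_states is None:
        initial_states = random_infected_initial(
            network.n, initial_infected_fraction, _coerce_rng(seed))

    def t_dist(m) -> Optional[float]:
        best = None
        for s2, t2, _ in m:
            if s2 == "I" and (best is None or t2 < best):
                best = t2
        return best

    def phi(v, s, t, m):
        if s != "S":
            return 0.0
        td = t_dist(m)
        return 0.0 if td is None else math.exp(-td)

    def psi(v, s, t, m):
        if s == "S":
            return {"I": p_i, "R": 1.0 - p_i}
        return {s: 1.0}  # absorbing states never fire

    s_bound = ConstantBound(1.0)

    def bound(v, s):
        return s_bound if s == "S" else _ZERO

    def eff_intensity(v, s, r, m):
        if s != "S":
            return constant_hazard(0.0)
        td = t_dist(m)
        if td is None:
            return constant_hazard(0.0)
        return exponential_decay_hazard(math.exp(-td), 1.0)

    return ModelSpec(network=network, states=("S", "I", "R"), phi=phi, psi=psi,
                     initial_state=list(initial_states), bound=bound,
                     effective_intensity=eff_intensity, name="complex_cascade")


# ---------------------------------------------------------------------------
# Voter model (Laplace–Gillespie mixture law)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _cached_voter_hazard(o: float):
    return voter_hazard(o)


def _opposing_fraction(s: str, m) -> float:
    if not m:
        return 0.0
    return sum(1 for s2, _, _ in m if s2 != s) / len(m)


def voter_lga(network: ContactNetwork,
              initial_states: Optional[Sequence[str]] = None,
              seed=None, lga_sampling: bool = True) -> ModelSpec:
    """Voter model with mixture-of-exponentials inter-event times.

    ``p_v`` is uniform on ``[0, o_v]`` (``o_v`` = opposing-neighbor
    fraction), giving hazard ``lambda_o(t) = 1/t - o/(e^{o t}-1)``.  The
    rejection-based bound sets ``o_v = 1``; that hazard decreases from 1/2,
    so thinning with ``c = 1/2`` dominates (checked numerically here and
    again at every thinning proposal).  With ``lga_sampling`` the exact
    engines draw delays via the mixture (with the posterior-tilted mixing
    density when regenerating from a positive residence); otherwise they
    invert the closed-form cumulative hazard.
    """
    if initial_states is None:
        initial_states = random_binary_initial(network.n, _coerce_rng(seed))

    bound_hazard = _cached_voter_hazard(1.0)
    grid = np.linspace(1e-9, 50.0, 512)
    if max(bound_hazard(float(t)) for t in grid) > 0.5 * (1 + 1e-12):
        raise AssertionError("voter bound hazard exceeds thinning constant 1/2")
    shared_bound = IntensityBound(bound_hazard, method="thinning", c=0.5)

    def phi(v, s, t, m):
        o = _opposing_fraction(s, m)
        if o == 0.0:
            return 0.0
        return _cached_voter_hazard(o)(t)

    def psi(v, s, t, m):
        return {"B": 1.0} if s == "A" else {"A": 1.0}

    def bound(v, s):
        return shared_bound

    def eff_intensity(v, s, r, m):
        o = _opposing_fraction(s, m)
        if o == 0.0:
            return constant_hazard(0.0)
        return voter_hazard(o, shift=r)

    def make_lga(state_label):
        def sampler(v, r, m, rng):
            o = _opposing_fraction(state_label, m)
            if o == 0.0:
                return math.inf
            return sample_exponential_mixture(
                uniform_mixture_rate_sampler(o, elapsed=r), rng)
        return sampler

    direct = {"A": make_lga("A"), "B": make_lga("B")} if lga_sampling else {}
    return ModelSpec(network=network, states=("A", "B"), phi=phi, psi=psi,
                     initial_state=list(initial_states), bound=bound,
                     effective_intensity=eff_intensity, direct_samplers=direct,
                     name="voter_lga")


# ---------------------------------------------------------------------------
# Neural point process
# ---------------------------------------------------------------------------

def neural_point_process(network: ContactNetwork, b: float = 0.01,
                         inhibitory_fraction: float = 0.2,
                         seed=None) -> ModelSpec:
    """Networked spiking model with signed synapses and tanh response.

    Each neuron fires at ``f(b + sum_{v'} w_{v,v'} / (1 + t'))`` over its
    neighbors' residences ``t'``, with ``f(x) = max(0, tanh(x))`` clamping
    the synaptic drive into [0, 1) — which also furnishes the trivial rate
    bound of one.  Edge weights are -1 with probability
    ``inhibitory_fraction`` (seeded, symmetric, assigned once) and +1
    otherwise.  A spike is an "infinitesimally short activation": the agent
    alternates between two equivalent excitable states so each firing is a
    genuine state change that resets its residence.
    """
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise ValueError("inhibitory_fraction must lie in [0, 1]")
    if b < 0:
        raise ValueError("baseline intensity must be nonnegative")
    rng = _coerce_rng(seed)
    weights: Dict[Tuple[int, int], float] = {
        e: (-1.0 if rng.random() < inhibitory_fraction else 1.0)
        for e in network.edges}

    def w(v, v2):
        return weights[(v, v2) if v < v2 else (v2, v)]

    def drive(v, m, t_delta=0.0):
        return b + sum(w(v, v2) / (1.0 + t2 + t_delta) for _, t2, v2 in m)

    def phi(v, s, t, m):
        return max(0.0, math.tanh(drive(v, m)))

    def psi(v, s, t, m):
        return {"E1": 1.0} if s == "E0" else {"E0": 1.0}

    one = ConstantBound(1.0)

    def bound(v, s):
        return one

    def eff_intensity(v, s, r, m):
        from .intensity import IntensityFunction
        return IntensityFunction(
            rate=lambda td: max(0.0, math.tanh(drive(v, m, td))),
            name="neural_drive")

    return ModelSpec(network=network, states=("E0", "E1"), phi=phi, psi=psi,
                     initial_state=["E0"] * network.n, bound=bound,
                     effective_intensity=eff_intensity,
                     name="neural_point_process")


MODELS = {
    "markovian_sis": markovian_sis,
    "nonmarkovian_sis": nonmarkovian_sis,
    "complex_cascade": complex_cascade,
    "voter_lga": voter_lga,
    "neural_point_process": neural_point_process,
}
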