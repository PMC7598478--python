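# Methods

## Formalism and semantics

An agent model is (G, 𝒮, {φ_v}, {ψ_v}, S₀) on a simple, connected,
undirected contact network.  The reference semantics is a race: each step,
every agent draws a candidate delay from its *effective rate*
λ_v(t_Δ) = φ_v(S(v), R(v)+t_Δ, M_{t_Δ}(v)) — its intensity extrapolated
with all residences advancing together and states frozen — and the
smallest delay fires; the successor is drawn from ψ_v at the residence at
firing.  `simulate_naive` implements this verbatim and serves as the
ground-truth oracle at small scale.  Residences are stored as last-change
times T(v) with R(v) = t_global − T(v), so no per-event bulk updates occur
anywhere in the package.

Three assumptions are enforced rather than merely documented: φ must be
nonnegative (negative values raise immediately), ψ must be a probability
distribution (normalization checked to 1e-12 at every application), and
runs that exceed an event budget (default 10⁶ processed events) abort with
a pathological-model error — the guard against intensities that diverge
with a *neighbor's* residence and would generate infinitely many events in
finite time.

Self-transitions drawn from ψ do not reset T(v) in any engine (they are
"no state transition" events); a model that needs reset-on-fire encodes it
as alternation between two equivalent states, as the neural model does.
This keeps null events and genuine self-loops on the same footing, which
the rejection argument below requires.

## Hazards, defectiveness, and the three samplers

Inter-event laws are hazards λ(t) with cumulative Λ(t); the renewal
identities λ = γ/(1−∫γ) and γ = λe^(−Λ) convert to and from delay
densities (hazard set to zero where the survival denominator vanishes).
Finite Λ(∞) means the law is defective; samplers return the `NO_FIRE`
sentinel (+∞), which engines interpret as "event beyond the horizon".

* **Inversion**: draw x ~ Exp(1), return the smallest t with Λ(t) = x.
  Registered hazards carry closed-form Λ and, where available, Λ⁻¹
  (constant, uniform-density, exponential-decay, sin², voter-mixture);
  otherwise Λ is evaluated by adaptive quadrature split at declared
  breakpoints (tolerance 1e-9) and the root is bracketed by doubling —
  approaching a finite support endpoint geometrically from below, since Λ
  may diverge there (e.g. at t = 2 for the uniform[1,2] hazard) — then
  polished by Brent's method at relative tolerance 1e-9.  Quadrature
  failures raise; they are never silent.
* **Thinning**: propose from a dominating constant c, accept at t with
  probability λ(t)/c.  Any observed λ(t) > c raises a bound-violation
  error, so an invalid dominator cannot silently bias samples.  The
  proposal horizon defaults to the remaining simulation time: later delays
  would be discarded anyway.
* **Exponential mixture (Laplace–Gillespie)**: for laws
  γ(t) = ∫p(λ)λe^(−λt)dλ, draw λ ~ p then t = −ln u/λ.  Regenerating such
  a law from residence r is done by tilting the mixing density with
  e^(−λr) (inverse-CDF sampled); for completely monotone survival this is
  exactly the conditional delay law, so mixture sampling stays exact in
  the event-driven engines where regeneration happens at positive
  residences.  The voter hazard 1/t − o/(e^(ot)−1) is evaluated by series
  (o/2 − o²t/12 + …) for ot < 1e-4 to avoid catastrophic cancellation.

## RED

Each (agent, state) carries a rate over-approximation λ̂_v that dominates
φ_v under every reachable future neighborhood.  Events (v, μ̂, t̂) are
sampled from λ̂_v *shifted to the agent's current residence* — the bound is
a function of residence, so regeneration after a null event conditions on
the elapsed residence — and μ̂ = λ̂_v(residence at firing).  On popping, the
true rate μ is evaluated and the firing is rejected with probability
1 − μ/μ̂.  Null events never reset T(v).  Correctness is the shadow-process
argument: λ̂ = λ + λ̃ with λ̃ ≥ 0, and the null events are precisely the
firings of the λ̃ process, which by construction does not touch the state;
μ > μ̂ is checked at every pop (to relative 1e-9) and raises.

Neighbor-independent rates are flagged for *exact sampling*
(`DirectBound`): their delays are drawn from the true conditional law
(uniform-recovery remainder, exponential recovery), μ̂ = μ by construction,
and the rejection branch is skipped (no acceptance draw is consumed).

The rejection-free baseline samples events from the true effective rates
and regenerates all neighbor events after each state change.
Invalidation uses lazy deletion — a per-agent version stamp, stale events
discarded at pop — which is behaviorally identical to in-place removal
but keeps the queue a plain binary heap.  The approximate nMGA engine
redraws exponential delays at the current instantaneous rates each step;
it is exact only for Markovian models and its bias shrinks with network
size (asserted at 10 vs 100 agents in the suite).

Determinism: each run consumes a single RNG stream; events are initialized
in agent order, then draws follow the loop order.  Identical seed, model,
and engine give bit-identical trajectories.  Ties in t̂ are broken by agent
identifier (they are measure-zero but the heap needs a total order).
Events beyond the horizon are enqueued as +∞ and drained by the stop
condition rather than pre-filtered.

## Rate bounds per zoo model

| model | state | bound | sampling |
|---|---|---|---|
| Markovian SIS | S | k_v·c_i (constant) | exponential |
| | I | c_r | exact (exponential) |
| non-Markovian SIS | S | u·k_v (constant) | exponential |
| | I | uniform[0,1] hazard 1/(1−t) | exact (uniform remainder) |
| cascade | S | 1 (since e^(−t_dist) ≤ 1) | exponential |
| | I, R | 0 (absorbing) | never fires |
| voter | A, B | 1/t − 1/(e^t−1) (o_v = 1) | thinning, c = 1/2 |
| neural | E0, E1 | 1 (tanh response ≤ 1) | exponential |

The voter bound decreases from its t→0 limit 1/2, so c = 1/2 dominates;
this is verified on a grid at model construction and re-checked at every
thinning proposal.  `validate_bound` probes random configurations (random
focal/neighbor states, residences capped by each state's reachable range —
e.g. an infected agent's residence never exceeds 1 under uniform recovery
— and uniform in [0, horizon] otherwise), asserts λ̂ ≥ φ, and reports the
worst margin and the mean acceptance ratio φ/λ̂ as a rejection-rate
forecast.

Non-Markovian SIS attack intensities from distinct infected neighbors
add — superposition of independent attack processes — which is the reading
consistent with the u·k_v bound; the summed pressure A = Σu·e^(−u·r_j)
makes the effective susceptible hazard A·e^(−ut), a closed form the exact
engines invert analytically.  The cascade's t_dist is the minimum
residence among currently infected neighbors.  A consequence worth
flagging: the cascade attack law is defective (total mass e^(−t_dist) ≤ 1),
so even with p_i = 1 a susceptible agent next to a fresh infected neighbor
is ever infected only with probability 1 − e^(−1); runs burn out with the
total intensity decaying to zero without ever reaching it exactly, and
the suite asserts a residual below 1e-6 at a long horizon rather than
exact extinction.

## Synthetic networks and study conditions

Contact networks are erased configuration models: degrees i.i.d. from the
normalized P(k) ∝ k^(−β) on k_min ≤ k ≤ n−1 by inverse CDF (upper cutoff
n−1 because a simple graph cannot realize degree n; an odd degree sum is
repaired by incrementing one uniformly chosen node), uniform stub
matching, self-loops and multi-edges erased, regeneration until connected
(default 100 attempts).  Erasure slightly depletes the largest hub
degrees; the chi-square goodness-of-fit check therefore compares
frequencies on k ∈ [3, 100], where erasure losses are negligible at
n = 10⁴.

Study conditions used throughout the suite, chosen once: β ∈ {2.0, 2.5},
k_min = 3; non-Markovian SIS with u = 0.4, 5% initially infected, horizon
2; voter model started 50/50 at random; neural model with b = 0.01 and
20% inhibitory edges; 50-agent networks for distribution-level
equivalence (2000 replicas per engine), 2-agent chains for the
master-equation oracle, 10³ vs 10⁴ agents for the step-cost scaling
measurement.  The generator emulates the degree heterogeneity of real
contact structures but none of their clustering, degree correlations, or
community structure, and the dynamics exclude birth/death, rewiring, and
exogenous forcing — so passing tests certify the *simulators* against the
model semantics, not the models against real epidemics.

## Cost accounting

Wall-clock time is deliberately not a correctness surface.  Trajectories
count accepted and rejected events, φ evaluations, and neighbor lookups;
`step_cost_counters` reduces them per event.  For RED the per-event
neighbor-lookup count is bounded by deg(v)+1 by construction; the
operational scaling claim is that RED's per-accepted-event φ-evaluation
and neighbor-lookup counts stay within ±20% from 10³ to 10⁴ agents while
the baseline's two-hop regeneration cost grows.  These counts are averaged
over several network realizations per size (5 networks × 4 runs for RED):
under a heavy-tailed degree law a single realization's hub structure
dominates the counters and makes one-draw comparisons meaningless.  The
rejection ratio — hence φ-evaluations per *accepted* event — also depends
on the epidemic trajectory, which at desk scale carries visible
finite-size effects; the ensemble average is the quantity that is stable.

## Known limitations

* Bounds are supplied analytically per model; nothing constructs λ̂ from
  φ automatically, and models whose rates cannot be bounded under all
  reachable neighborhoods (e.g. full-history self-exciting processes,
  or attack rates diverging with a neighbor's freshness like |−log t|)
  are out of scope.
* The exact (joint-survival) non-Markovian Gillespie variant is not
  implemented; only its constant-rate approximation is, as a documented
  approximate engine.
* Engines are single-threaded and in-memory; networks are static and
  undirected (edge *signs* for the neural model are the only edge data).
* `simulate_naive` is quadratic per event and intended only as an oracle
  at tens of agents.
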