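# redsim

Rejection-based event-driven simulation of non-Markovian multi-agent
dynamics on contact networks.

## The problem

Continuous-time spreading processes on networks — epidemics, opinion
dynamics, cascades of shared content, neural spiking — are usually
simulated with Gillespie-style algorithms that assume *memoryless*
(exponential) inter-event times.  Empirically, waiting times are rarely
exponential: infectiousness wanes, opinions persist, synapses decay.  Once
an agent's instantaneous rate depends on residence times (its own, or its
neighbors'), every state change invalidates the pending event times of the
whole neighborhood, and conventional event-driven simulators pay a
two-hop update cost per event that grows with network connectivity.

`redsim` implements **RED** (Rejection-based Event-Driven simulation),
which removes that neighborhood update entirely, together with the
reference algorithms needed to verify it, for users who study
non-Markovian dynamics on networks at desk scale and need statistically
exact trajectories with per-event cost that does not grow with network
size.

## The model and the algorithm

A model is a tuple (G, 𝒮, {φ_v}, {ψ_v}, S₀): a connected undirected
contact network G, a finite local state set 𝒮, and for each agent v an
intensity function φ_v(s, t, M(v)) giving its instantaneous firing rate as
a function of its state s, residence time t, and neighborhood
M(v) = {(S(v′), R(v′), v′)}, plus a successor distribution ψ_v and an
initial state map.  Inter-event laws are expressed as hazards λ(t)
related to delay densities γ by the renewal identities
λ = γ / (1 − ∫γ) and γ = λ·e^(−∫λ); hazards with finite total mass are
*defective* — the agent may never fire.

RED requires, per agent and state, a *rate over-approximation* λ̂_v with
λ̂_v(t) ≥ φ_v under **every** reachable future neighborhood.  It keeps one
pending event (v, μ̂, t̂) per agent in a priority queue, with delays sampled
from λ̂_v and μ̂ = λ̂_v evaluated at the sampled delay.  Popping an event,
it evaluates the true rate μ = φ_v at the current state and **rejects the
firing with probability 1 − μ/μ̂** (a null event), regenerating only that
agent's event either way.  The rejected pops are exactly the firings of
the shadow process with rate λ̂ − λ, so the accepted events follow the
model's semantics exactly — no neighbor updates, no approximation.
Per-event cost is O(deg v) for the φ evaluation plus O(log n) queue work.

Engines provided:

| engine     | events sampled from | neighbor updates | exact? |
|------------|--------------------|------------------|--------|
| `red`      | rate bound λ̂ + rejection | none       | yes    |
| `baseline` | true effective rate | all neighbors per event | yes |
| `nmga`     | current rate, held constant | implicit | only for Markovian models |
| `naive`    | true effective rate, all agents resampled each step | — | yes (reference semantics) |

Model zoo: Markovian SIS, non-Markovian SIS (attack rate u·e^(−ut),
uniform [0,1] recovery), a complex cascade (rate e^(−t_dist) driven by the
most recently infected neighbor), a voter model with
mixture-of-exponentials waiting times (Laplace–Gillespie sampling), and a
multivariate neural point process with signed synapses and tanh response.
Contact networks are read from plain-text edge lists or generated by a
truncated power-law configuration model, P(k) ∝ k^(−β) on
k_min ≤ k ≤ n−1.

## Worked example

```python
import numpy as np
from redsim import (generate_configuration_network, nonmarkovian_sis,
                    simulate_red, simulate_naive, ks_equivalence,
                    sample_inversion, uniform_hazard)

# Inversion sampling: integrate the hazard 1/(2-t) of the uniform[1,2]
# delay law until the accumulated area equals the reference variate 0.69.
t = sample_inversion(uniform_hazard(1.0, 2.0), x=0.69)
print(f"inversion delay at x=0.69: t = {t:.4f}")

# Non-Markovian SIS (u=0.4, 5% initially infected) on a 50-node network.
net = generate_configuration_network(50, beta=2.5, k_min=3, seed=7)
print(f"network: {net.n} agents, {net.n_edges} edges, mean degree {net.degrees.mean():.2f}")

def infected_fraction(engine, seed0, n=500):
    vals = []
    for i in range(n):
        rng = np.random.default_rng(seed0 + i)
        model = nonmarkovian_sis(net, u=0.4, initial_infected_fraction=0.05, seed=rng)
        traj = engine(model, 2.0, rng)
        vals.append(traj.state_fractions(("S", "I"), 2.0)["I"])
    return np.asarray(vals)

red, naive = infected_fraction(simulate_red, 1000), infected_fraction(simulate_naive, 9000)
res = ks_equivalence(red, naive)
print(f"mean infected fraction at t=2: RED {red.mean():.4f}, naive {naive.mean():.4f}")
print(f"two-sample KS: statistic {res.statistic:.4f}, p = {res.pvalue:.3f}")
```

prints

```
inversion delay at x=0.69: t = 1.4984
network: 50 agents, 128 edges, mean degree 5.12
mean infected fraction at t=2: RED 0.0277, naive 0.0304
two-sample KS: statistic 0.0180, p = 1.000
```

The delay 1.4984 is the time at which the cumulative hazard
−ln(2 − t) reaches 0.69 (at t = 1.5 the area is ln 2 ≈ 0.693).  The KS
p-value far above 0.01 says the 500-replica infected-fraction
distributions of the rejection-based engine and the ground-truth race
simulator are statistically indistinguishable.  A single RED run here
processes a few hundred queue events of which most are cheap null events
(e.g. 21 accepted vs 161 rejected) — the price of never touching neighbor
events, amortized by the O(1) cost of a rejection.

There is also a CLI for configured ensemble runs:

```bash
redsim run --config run.yaml --engine red --replicas 100 --out results/
redsim validate --config run.yaml     # bound check + cross-engine KS
```

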