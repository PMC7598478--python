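import math

import numpy as np
import pytest

from redsim.engines import (
    generate_event,
    simulate,
    simulate_baseline,
    simulate_nmga,
    simulate_red,
    step_cost_counters,
)
from redsim.model_core import ConstantBound, ModelSpec, simulate_naive
from redsim.model_zoo import (
    complex_cascade,
    markovian_sis,
    neural_point_process,
    nonmarkovian_sis,
    voter_lga,
)
from redsim.network import ContactNetwork, generate_configuration_network
from redsim.stats import ks_equivalence

from test_model_core import master_equation_p_both_infected, two_node_sis


def single_agent_model(rate=0.3, bound=1.0):
    net = ContactNetwork(1, [])
    return ModelSpec(
        network=net, states=("X", "Y"),
        phi=lambda v, s, r, m: rate,
        psi=lambda v, s, r, m: {"Y": 1.0} if s == "X" else {"X": 1.0},
        initial_state=["X"], bound=lambda v, s: ConstantBound(bound))


class TestGenerateEvent:
    def test_sis_bound_at_firing_is_u_times_degree(self, star10):
        m = nonmarkovian_sis(star10, u=0.4, initial_states=["S"] + ["I"] * 9)
        state = m.initial_network_state()
        ev = generate_event(m, state, 0, 0.0, np.random.default_rng(0))
        assert ev.mu_hat == pytest.approx(0.4 * 9)

    def test_zero_bound_never_fires(self, pair_net):
        m = complex_cascade(pair_net, 0.5, initial_states=["R", "I"])
        state = m.initial_network_state()
        ev = generate_event(m, state, 0, 0.0, np.random.default_rng(1))
        assert ev.t_hat == math.inf and ev.mu_hat == 0.0

    def test_voter_bound_reevaluates_at_the_sampled_delay(self, pair_net):
        """mu_hat equals 1/t - 1/(e^t - 1) at the sampled delay (o_v = 1)."""
        m = voter_lga(pair_net, initial_states=["A", "B"])
        state = m.initial_network_state()
        rng = np.random.default_rng(2)
        for _ in range(20):
            ev = generate_event(m, state, 0, 0.0, rng, horizon=100.0)
            if math.isfinite(ev.t_hat):
                t = ev.t_hat
                assert ev.mu_hat == pytest.approx(
                    1.0 / t - 1.0 / math.expm1(t), abs=1e-9)


class TestEngineBasics:
    @pytest.mark.parametrize("engine", ["red", "baseline", "nmga", "naive"])
    def test_all_zero_model_is_silent(self, engine):
        net = ContactNetwork(2, [(0, 1)])
        m = ModelSpec(network=net, states=("X",),
                      phi=lambda v, s, r, mm: 0.0,
                      psi=lambda v, s, r, mm: {"X": 1.0},
                      initial_state=["X", "X"],
                      bound=lambda v, s: ConstantBound(0.0))
        traj = simulate(engine, m, 3.0, np.random.default_rng(0))
        assert traj.accepted == 0 and traj.rejected == 0
        assert traj.records == []

    @pytest.mark.parametrize("engine", ["red", "baseline", "nmga", "naive"])
    def test_identical_seeds_give_identical_trajectories(self, engine, tiny_net):
        def one(seed):
            rng = np.random.default_rng(seed)
            m = nonmarkovian_sis(tiny_net, 0.4, seed=rng)
            t = simulate(engine, m, 1.5, rng)
            return [(r.time, r.agent, r.new_state) for r in t.records]
        assert one(9) == one(9)
        assert one(9) != one(10)  # and genuinely random across seeds

    @pytest.mark.parametrize("engine", ["red", "baseline"])
    def test_popped_times_nondecreasing_and_records_increase(self, engine, tiny_net):
        rng = np.random.default_rng(4)
        m = markovian_sis(tiny_net, 0.8, 1.0, seed=rng)
        traj = simulate(engine, m, 2.0, rng)
        times = [r.time for r in traj.records]
        assert times == sorted(times)
        assert all(b > a for a, b in zip(times, times[1:]))
        assert all(t <= 2.0 for t in times)

    def test_unknown_engine_is_an_error(self, pair_net):
        m = markovian_sis(pair_net, 1.0, 1.0, initial_states=["I", "S"])
        with pytest.raises(ValueError, match="unknown engine"):
            simulate("exact-nmga", m, 1.0, np.random.default_rng(0))


class TestShadowProcess:
    def test_true_rate_never_exceeds_bound(self, tiny_net):
        """RED asserts mu <= mu_hat at every firing; a clean run proves the
        dominator identity lambda_hat = lambda + lambda_tilde held throughout."""
        rng = np.random.default_rng(5)
        m = nonmarkovian_sis(tiny_net, 0.4, seed=rng)
        traj = simulate_red(m, 2.0, rng)
        assert traj.accepted > 0  # the assertion lives inside the engine

    def test_rejection_frequency_equals_shadow_share(self):
        """Frozen single agent with phi=0.3 under bound 1: null events fire at
        the shadow rate 0.7, so the rejected fraction estimates 0.7."""
        traj = simulate_red(single_agent_model(0.3, 1.0), 3000.0,
                            np.random.default_rng(6))
        n = traj.accepted + traj.rejected
        frac = traj.rejected / n
        assert abs(frac - 0.7) < 3 * math.sqrt(0.7 * 0.3 / n)


class TestMarkovianOracle:
    @pytest.mark.parametrize("engine", ["red", "baseline", "nmga"])
    def test_two_node_sis_marginal(self, engine):
        """P(both infected at t=1) against the matrix-exponential master
        equation; nMGA is exact here because the model is Markovian."""
        n = 4000
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(n):
            traj = simulate(engine, two_node_sis(), 1.0, rng)
            hits += traj.final_state.states.count("I") == 2
        p = master_equation_p_both_infected()
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestExactnessTriangle:
    """RED, baseline, and naive sample the same distribution (reduced scale;
    the full-size protocol lives in the acceptance suite)."""

    def _ensembles(self, factory, horizon, statistic, engines, n, seed0):
        out = {}
        for j, engine in enumerate(engines):
            vals = []
            for i in range(n):
                rng = np.random.default_rng(seed0 + 10_000 * j + i)
                m = factory(rng)
                vals.append(statistic(simulate(engine, m, horizon, rng)))
            out[engine] = np.array(vals)
        return out

    def test_markovian_sis_triangle(self, tiny_net):
        ens = self._ensembles(
            lambda rng: markovian_sis(tiny_net, 0.5, 1.0, seed=rng), 2.0,
            lambda t: t.state_fractions(("S", "I"), 2.0)["I"],
            ["red", "baseline", "naive", "nmga"], 300, 100)
        for a in ("baseline", "naive", "nmga"):
            assert ks_equivalence(ens["red"], ens[a]).pvalue > 0.01

    def test_cascade_triangle(self, tiny_net):
        ens = self._ensembles(
            lambda rng: complex_cascade(tiny_net, 0.6, seed=rng), 4.0,
            lambda t: t.state_fractions(("S", "I", "R"), 4.0)["S"],
            ["red", "baseline", "naive"], 300, 200)
        assert ks_equivalence(ens["red"], ens["baseline"]).pvalue > 0.01
        assert ks_equivalence(ens["red"], ens["naive"]).pvalue > 0.01

    def test_voter_lga_vs_inversion_and_red(self, tiny_net):
        """Mixture (Laplace–Gillespie) sampling, closed-form inversion, and
        RED's thinned o=1 bound all produce the same opinion-fraction law."""
        stat = lambda t: t.state_fractions(("A", "B"), 5.0)["A"]  # noqa: E731
        ens_lga = self._ensembles(
            lambda rng: voter_lga(tiny_net, seed=rng, lga_sampling=True), 5.0,
            stat, ["red", "baseline"], 300, 300)
        ens_inv = self._ensembles(
            lambda rng: voter_lga(tiny_net, seed=rng, lga_sampling=False), 5.0,
            stat, ["baseline"], 300, 400)
        assert ks_equivalence(ens_lga["red"], ens_lga["baseline"]).pvalue > 0.01
        assert ks_equivalence(ens_lga["baseline"], ens_inv["baseline"]).pvalue > 0.01

    def test_neural_spike_counts_agree(self, tiny_net):
        weights_rng = np.random.default_rng(99)
        ens = self._ensembles(
            lambda rng: neural_point_process(
                tiny_net, b=0.01, inhibitory_fraction=0.2,
                seed=np.random.default_rng(99)), 2.0,
            lambda t: t.accepted, ["red", "baseline"], 150, 500)
        assert ks_equivalence(ens["red"], ens["baseline"]).pvalue > 0.01


class TestNMGAApproximation:
    def test_error_shrinks_with_network_size(self):
        """The constant-rate approximation biases the non-Markovian SIS; the
        bias at 10 agents exceeds the bias at 100 agents (exact oracles:
        naive at n=10, rejection-free baseline at n=100)."""
        def mean_inf(engine, n, runs, seed0):
            net = generate_configuration_network(n, 2.5, 3, seed=50 + n)
            vals = []
            for i in range(runs):
                rng = np.random.default_rng(seed0 + i)
                m = nonmarkovian_sis(net, 0.4, initial_infected_fraction=0.1,
                                     seed=rng)
                t = simulate(engine, m, 2.0, rng)
                vals.append(t.state_fractions(("S", "I"), 2.0)["I"])
            return np.mean(vals)

        err_small = abs(mean_inf("nmga", 10, 600, 1000)
                        - mean_inf("naive", 10, 600, 5000))
        err_large = abs(mean_inf("nmga", 100, 600, 1000)
                        - mean_inf("baseline", 100, 600, 5000))
        assert err_small > err_large


class TestStepCost:
    def test_red_lookups_bounded_by_degree_plus_one(self, small_config_net):
        rng = np.random.default_rng(8)
        m = nonmarkovian_sis(small_config_net, 0.4, seed=rng)
        traj = simulate_red(m, 2.0, rng, instrument=True)
        rep = step_cost_counters(traj)
        assert rep.max_neighbor_lookups_per_event <= small_config_net.degrees.max() + 1
        assert rep.rejected == traj.rejected

    def test_baseline_hub_event_regenerates_all_leaves(self, star10):
        """On K_{1,9}, a hub transition forces 9 neighbor regenerations."""
        m = markovian_sis(star10, 1.0, 1.0, initial_states=["I"] + ["S"] * 9)
        traj = simulate_baseline(m, 0.5, np.random.default_rng(1), instrument=True)
        hub_records = [r for r in traj.records if r.agent == 0]
        assert hub_records  # the hub fired at least once
        assert traj.neighbor_regenerations >= 9
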