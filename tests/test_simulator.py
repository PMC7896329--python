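"""Agent-based diffusion dynamics and the aggregate Bass recursion."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bassnet import (
    AggregateBassParams,
    DiffusionEngine,
    SimulationParams,
    adoption_probability,
    aggregate_bass_curve,
    exact_expected_time,
    run_simulation,
    step,
    time_to_fraction,
)
from bassnet.exceptions import InvalidParameterError


class TestAdoptionProbability:
    @pytest.mark.parametrize(
        "alpha,beta,frac,expected",
        [
            (0.0, 0.0, 0.7, 0.0),
            (1.0, 0.0, 0.0, 1.0),
            (0.6, 0.8, 1.0, 1.0),  # cap at 1
            (0.1, 0.4, 0.5, 0.3),
        ],
    )
    def test_values(self, alpha, beta, frac, expected):
        assert adoption_probability(alpha, beta, frac) == pytest.approx(expected)

    @given(
        st.floats(0, 2), st.floats(0, 3), st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_is_a_probability_and_monotone(self, alpha, beta, frac):
        p = adoption_probability(alpha, beta, frac)
        assert 0.0 <= p <= 1.0
        assert adoption_probability(alpha + 0.1, beta, frac) >= p
        assert adoption_probability(alpha, beta + 0.1, frac) >= p

    def test_fraction_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            adoption_probability(0.1, 0.1, 1.2)


class TestStep:
    def test_star_hub_floods_leaves(self, star5):
        params = SimulationParams(alpha=0.0, beta=1.0, seed_node=0)
        out = step(star5, {0}, params, np.random.default_rng(0))
        assert out == set(star5.nodes)

    def test_no_influence_no_change(self, cycle4):
        params = SimulationParams(alpha=0.0, beta=0.0, seed_node=0)
        assert step(cycle4, {0}, params, np.random.default_rng(0)) == {0}

    def test_isolated_node_adopts_through_alpha_only(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)  # degree 0
        params = SimulationParams(alpha=1.0, beta=0.0, seed_node=0)
        out = step(g, {0}, params, np.random.default_rng(0))
        assert out == {0, 1, 2}

    def test_adopters_retained(self, complete4):
        params = SimulationParams(alpha=0.3, beta=0.5, seed_node=0)
        out = step(complete4, {0, 1}, params, np.random.default_rng(1))
        assert {0, 1} <= out

    def test_iterated_steps_reproduce_run_simulation(self, complete4):
        params = SimulationParams(alpha=0.2, beta=0.3, seed_node=0, max_ticks=50, rng_seed=5)
        traj = run_simulation(complete4, params)
        rng = np.random.default_rng(5)
        adopters = {0}
        counts = [1]
        while len(adopters) < 4 and len(counts) <= 50:
            adopters = step(complete4, adopters, params, rng)
            counts.append(len(adopters))
        assert counts == list(traj.cumulative)


class TestRunSimulation:
    def test_alpha_one_saturates_in_one_tick(self, cycle4):
        traj = run_simulation(cycle4, SimulationParams(1.0, 0.0, seed_node=0, rng_seed=0))
        assert traj.time_to_full == 1
        assert traj.saturated

    def test_zero_doses_never_spread(self, star5):
        traj = run_simulation(
            star5, SimulationParams(0.0, 0.0, seed_node=1, max_ticks=20, rng_seed=0)
        )
        assert not traj.saturated
        assert traj.time_to_half is None
        assert list(traj.cumulative) == [1] * 21

    def test_deterministic_given_seed(self, complete4):
        p = SimulationParams(0.2, 0.5, seed_node=2, rng_seed=123)
        t1, t2 = run_simulation(complete4, p), run_simulation(complete4, p)
        assert np.array_equal(t1.cumulative, t2.cumulative)

    def test_seed_must_be_in_graph(self, path3):
        with pytest.raises(InvalidParameterError):
            run_simulation(path3, SimulationParams(0.1, 0.1, seed_node=99))

    def test_mean_full_adoption_time_matches_markov_oracle(self, path3):
        """Path seeded at an end with beta=1: middle node adopts w.p. 1/2 per
        tick, then the far end w.p. 1, so E[time to full] = 3 exactly."""
        assert exact_expected_time(path3, 0, 0.0, 1.0, 1.0) == pytest.approx(3.0)
        engine = DiffusionEngine(path3)
        rng = np.random.default_rng(42)
        times = engine.times_to_fraction(0.0, 1.0, np.zeros(4000, dtype=int), 500, rng)
        assert (times >= 0).all()
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert times.mean() == pytest.approx(3.0, abs=3 * se)

    @given(st.integers(0, 2**31 - 1), st.floats(0, 0.5), st.floats(0, 1.5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_trajectories_monotone_and_bounded(self, seed, alpha, beta):
        g = nx.gnp_random_graph(9, 0.3, seed=seed)
        traj = run_simulation(
            g, SimulationParams(alpha, beta, seed_node=0, max_ticks=60, rng_seed=seed)
        )
        cum = traj.cumulative
        assert cum[0] == 1
        assert (np.diff(cum) >= 0).all()
        assert cum[-1] <= g.number_of_nodes()


class TestTimeToFraction:
    def test_first_crossing(self):
        assert time_to_fraction(np.array([1, 400, 600]), 1000, 0.5) == 2

    def test_censored(self):
        assert time_to_fraction(np.array([1, 2, 3]), 1000, 0.5) is None

    def test_full_fraction_consistent(self, complete4):
        traj = run_simulation(complete4, SimulationParams(0.5, 0.5, seed_node=0, rng_seed=3))
        assert time_to_fraction(traj, 4, 1.0) == traj.time_to_full

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            time_to_fraction(np.array([1]), 4, 0.0)


class TestAggregateBass:
    def test_zero_coefficients_constant(self):
        curve = aggregate_bass_curve(AggregateBassParams(0, 0, 100, 5), 10)
        assert (curve == 5).all()

    def test_fixed_point_at_n_max(self):
        curve = aggregate_bass_curve(AggregateBassParams(0.1, 0.01, 100, 100), 10)
        assert (curve == 100).all()

    def test_strictly_increasing_to_ceiling(self):
        curve = aggregate_bass_curve(AggregateBassParams(0.001, 0.001, 100, 1), 2000)
        assert (np.diff(curve) >= 0).all()
        # strictly increasing until the asymptote is approached
        growing = curve[:-1] < 99.0
        assert (np.diff(curve)[growing] > 0).all()
        assert curve[-1] == pytest.approx(100)

    def test_stochastic_monotonicity_in_alpha(self, star5):
        """Raising alpha cannot lower P(saturate within T)."""
        engine = DiffusionEngine(star5)
        probs = []
        for alpha in (0.05, 0.2, 0.5):
            rng = np.random.default_rng(11)
            times = engine.times_to_fraction(
                alpha, 0.3, np.zeros(3000, dtype=int), 10, rng
            )
            probs.append((times >= 0).mean())
        assert probs[0] <= probs[1] + 0.02 <= probs[2] + 0.04


class TestMeanField:
    def test_complete_graph_matches_exact_chain(self):
        """On a complete graph the adopter count is itself a Markov chain
        (binomial increments); the simulated mean curve must agree with the
        exact chain mean within Monte Carlo error."""
        from bassnet import mean_cumulative_curve

        n, alpha, beta, ticks, reps = 60, 0.01, 0.3, 40, 2000
        g = nx.complete_graph(n)
        mean, sd = mean_cumulative_curve(g, alpha, beta, 0, reps, ticks, rng_seed=8)

        from scipy.stats import binom

        dist = np.zeros(n + 1)
        dist[1] = 1.0
        exact = [1.0]
        for _ in range(ticks):
            new = np.zeros(n + 1)
            for cnt in range(1, n + 1):
                pr = dist[cnt]
                if pr == 0:
                    continue
                if cnt == n:
                    new[n] += pr
                    continue
                p = min(1.0, alpha + beta * cnt / (n - 1))
                k = np.arange(0, n - cnt + 1)
                new[cnt : n + 1] += pr * binom.pmf(k, n - cnt, p)
            dist = new
            exact.append(float(np.arange(n + 1) @ dist))
        se = np.maximum(sd / math.sqrt(reps), 1e-12)
        z = np.abs(mean - np.array(exact)) / se
        # 41 correlated pointwise checks: 4-SE band
        assert z.max() < 4.0
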