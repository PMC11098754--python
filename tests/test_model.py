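"""Stochastic growth model: step rule, analytic limits, SSA oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, ks_2samp

from clonetrace.model import (
    DegenerateModelError,
    LineageState,
    ModelParameters,
    cell_type_composition,
    choose_time_step,
    double_event_probability,
    exact_ssa_reference,
    fit_rates_grid,
    simulate_lineage,
    simulate_organoid,
    step,
)


class TestTimeStep:
    @pytest.mark.parametrize(
        "rates, expected",
        [((1.0, 1.0, 1.0), 0.01), ((2.0, 0.5, 0.0), 0.005), ((0.1, 0.1, 0.1), 0.1)],
    )
    def test_rule(self, rates, expected):
        p = ModelParameters(r_s=rates[0], r_a=rates[1], r_n=rates[2])
        assert choose_time_step(p) == pytest.approx(expected)

    def test_all_zero_rates_degenerate(self):
        with pytest.raises(DegenerateModelError):
            choose_time_step(ModelParameters(r_s=0.0))

    def test_double_event_probability_below_one_percent(self):
        # closed-form Poisson tail at the maximal rate: 1 - e^-x - x e^-x
        p = ModelParameters(r_s=0.1, r_a=0.1, r_n=0.1)
        dt = choose_time_step(p)
        prob = double_event_probability(0.1, dt)
        assert prob == pytest.approx(1 - math.exp(-0.01) - 0.01 * math.exp(-0.01))
        assert prob == pytest.approx(4.97e-5, rel=2e-3)
        assert prob < 0.01

    def test_variant_includes_direct_neurogenesis_rate(self):
        p = ModelParameters(r_s=1.0, r_dn=4.0, variant="direct_neurogenesis")
        assert choose_time_step(p) == pytest.approx(0.01 / 4.0)


class TestStep:
    def test_no_events_without_rates(self, rng):
        p = ModelParameters(r_s=0.0, r_a=0.0, r_n=1.0)
        out = step(LineageState(1, 0, 0), p, 0.01, rng)
        assert out == LineageState(1, 0, 0)

    def test_asymmetric_event_adds_k_n_cells(self, rng):
        # condition on the event happening: iterate until the A cell fires
        p = ModelParameters(r_s=0.0, r_a=0.0, r_n=1.0, k=3)
        state = LineageState(0, 1, 0)
        for _ in range(10_000):
            out = step(state, p, 0.01, rng)
            if out.n > 0:
                break
        assert out == LineageState(0, 1, 3)

    def test_binomial_event_mean(self, rng):
        # E[d_s] = s * r_s * dt = 1.0 for s=100, r_s=1, dt=0.01
        from clonetrace.model import _step_arrays

        n_rep = 100_000
        s = np.full(n_rep, 100, dtype=np.int64)
        a = np.zeros(n_rep, dtype=np.int64)
        n = np.zeros(n_rep, dtype=np.int64)
        p = ModelParameters(r_s=1.0)
        s2, _, _ = _step_arrays(s, a, n, p, 0.01, rng)
        gains = (s2 - 100).mean()
        se = math.sqrt(100 * 0.01 * 0.99 / n_rep)
        assert abs(gains - 1.0) <= 3 * se

    def test_invalid_probability_rejected(self, rng):
        p = ModelParameters(r_s=1.0)
        with pytest.raises(ValueError, match="binomial"):
            step(LineageState(1, 0, 0), p, 2.0, rng)

    @given(
        s=st.integers(0, 50),
        a=st.integers(0, 50),
        n=st.integers(0, 50),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_counts_stay_valid(self, s, a, n, seed):
        """Counts stay non-negative, n never decreases, a never decreases."""
        p = ModelParameters(r_s=1.0, r_a=1.0, r_n=1.0, k=2)
        rng = np.random.default_rng(seed)
        state = LineageState(s, a, n)
        for _ in range(20):
            state2 = step(state, p, choose_time_step(p), rng)
            assert min(state2.s, state2.a, state2.n) >= 0
            assert state2.n >= state.n
            assert state2.a >= state.a
            state = state2


class TestSimulateLineage:
    def test_zero_duration(self):
        p = ModelParameters(r_s=1.0, t_end=0.0, record_times=(0.0,))
        traj = simulate_lineage(p)
        assert traj.times == (0.0,)
        assert traj.states[0] == LineageState(1, 0, 0)

    def test_deterministic_given_seed(self):
        p = ModelParameters(r_s=0.8, r_a=0.4, r_n=1.0, t_end=4.0, seed=99)
        assert simulate_lineage(p) == simulate_lineage(p)

    def test_transition_depletes_s_at_exponential_rate(self):
        # single cell, r_a only: P(s=0 by t) = 1 - e^{-r_a t}
        p = ModelParameters(r_s=0.0, r_a=1.0, r_n=0.0, t_end=2.0, n_lineages=10_000, seed=3)
        sim = simulate_organoid(p)
        frac = (sim.s[-1] == 0).mean()
        expected = 1 - math.exp(-2.0)
        se = math.sqrt(expected * (1 - expected) / p.n_lineages)
        assert abs(frac - expected) <= 4 * se


class TestSimulateOrganoid:
    def test_all_rates_zero_constant(self):
        p = ModelParameters(
            r_s=0.0, t_end=5.0, n_lineages=1000, record_times=(1.0, 5.0), seed=0
        )
        sim = simulate_organoid(p)
        assert (sim.sizes(1.0) == 1).all() and (sim.sizes(5.0) == 1).all()

    def test_yule_mean_size(self):
        # pure symmetric growth: E[size(t)] = e^{r_s t}
        p = ModelParameters(r_s=1.0, variant="symmetric_only", t_end=1.0, n_lineages=10_000, seed=5)
        sizes = simulate_organoid(p).sizes(1.0)
        se = sizes.std(ddof=1) / math.sqrt(sizes.size)
        assert abs(sizes.mean() - math.e) <= 4 * se

    def test_replay_is_bit_identical(self):
        p = ModelParameters(r_s=0.5, r_a=0.5, r_n=1.0, t_end=3.0, n_lineages=500, seed=17)
        a, b = simulate_organoid(p), simulate_organoid(p)
        assert (a.s == b.s).all() and (a.a == b.a).all() and (a.n == b.n).all()

    def test_unrecorded_time_rejected(self):
        p = ModelParameters(r_s=1.0, t_end=1.0, n_lineages=10, record_times=(1.0,))
        sim = simulate_organoid(p)
        with pytest.raises(KeyError):
            sim.sizes(0.5)


class TestExactSSA:
    def test_all_rates_zero_constant(self):
        p = ModelParameters(r_s=0.0, t_end=3.0, record_times=(1.0, 3.0))
        traj = exact_ssa_reference(p)
        assert all(s == LineageState(1, 0, 0) for s in traj.states)

    def test_yule_size_law_geometric(self, rng):
        # P(size=m at t) = q(1-q)^{m-1}, q = e^{-t}; chi-square GOF
        t = 1.0
        p = ModelParameters(r_s=1.0, variant="symmetric_only", t_end=t)
        sizes = np.array(
            [exact_ssa_reference(p, rng).final_state.size for _ in range(4000)]
        )
        q = math.exp(-t)
        cats = np.arange(1, 10)
        probs = q * (1 - q) ** (cats - 1)
        probs = np.append(probs, 1 - probs.sum())
        observed = np.array([(sizes == m).sum() for m in cats] + [(sizes >= 10).sum()])
        res = chisquare(observed, probs * sizes.size)
        assert res.pvalue > 0.01

    def test_tau_leap_matches_ssa_distribution(self, rng):
        # mixed rates: binomial stepper vs exact sampler, two-sample KS
        p = ModelParameters(r_s=0.5, r_a=0.5, r_n=1.0, k=2, t_end=5.0, n_lineages=4000, seed=11)
        tau = simulate_organoid(p).sizes(5.0)
        ssa = np.array([exact_ssa_reference(p, rng).final_state.size for _ in range(4000)])
        assert ks_2samp(tau, ssa).pvalue > 0.01


class TestCellTypeComposition:
    def test_conserves_cells_and_flags(self):
        p = ModelParameters(r_s=0.35, r_a=0.35, r_n=1.4, k=2, t_end=20.0, n_lineages=2000, seed=8)
        sim = simulate_organoid(p)
        comp = cell_type_composition(sim, 20.0)
        assert len(comp) == p.n_lineages
        total = comp["progenitors"].sum() + comp["postmitotic"].sum()
        assert total == sim.sizes(20.0).sum()

    def test_symmetric_only_always_contains_s(self):
        p = ModelParameters(r_s=0.5, variant="symmetric_only", t_end=10.0, n_lineages=500, seed=2)
        comp = cell_type_composition(simulate_organoid(p), 10.0)
        assert comp["contains_s"].all()

    def test_largest_lineages_retain_s(self):
        # S-retaining lineages keep growing; rank correlation between size
        # and the contains-S flag must be positive
        p = ModelParameters(r_s=0.35, r_a=0.35, r_n=1.4, k=2, t_end=30.0, n_lineages=3000, seed=9)
        sim = simulate_organoid(p)
        comp = cell_type_composition(sim, 30.0)
        sizes = sim.sizes(30.0)
        with_s = sizes[comp["contains_s"].to_numpy()]
        without_s = sizes[~comp["contains_s"].to_numpy()]
        assert 0 < comp["contains_s"].sum() < len(comp)
        assert np.median(with_s) > np.median(without_s)

    def test_unrecorded_time_error(self):
        p = ModelParameters(r_s=1.0, t_end=1.0, n_lineages=10, seed=0)
        with pytest.raises(KeyError):
            cell_type_composition(simulate_organoid(p), 0.3)


class TestFitRatesGrid:
    def test_single_point_grid(self):
        template = ModelParameters(r_s=0.5, t_end=4.0, n_lineages=500, seed=1)
        obs = simulate_organoid(template).sizes(4.0)
        best, score, table = fit_rates_grid(obs, [(0.5, 0.0, 0.0)], template)
        assert (best.r_s, best.r_a, best.r_n) == (0.5, 0.0, 0.0)
        assert len(table) == 1 and score >= 0

    def test_recovers_generating_rates(self):
        truth = ModelParameters(r_s=0.6, r_a=0.3, r_n=1.0, k=2, t_end=6.0, n_lineages=2000, seed=21)
        obs = simulate_organoid(truth).sizes(6.0)
        grid = [(rs, ra, 1.0) for rs in (0.3, 0.6, 0.9) for ra in (0.3, 0.6)]
        template = ModelParameters(r_s=1, r_a=1, r_n=1, k=2, t_end=6.0, n_lineages=2000, seed=22)
        best, _, _ = fit_rates_grid(obs, grid, template)
        assert (best.r_s, best.r_a) == (0.6, 0.3)

    def test_symmetric_observed_prefers_zero_transition(self):
        truth = ModelParameters(r_s=0.5, variant="symmetric_only", t_end=6.0, n_lineages=2000, seed=4)
        obs = simulate_organoid(truth).sizes(6.0)
        template = ModelParameters(r_s=1, r_a=1, r_n=1, t_end=6.0, n_lineages=2000, seed=14)
        best, _, _ = fit_rates_grid(obs, [(0.5, 0.0, 0.0), (0.5, 0.5, 0.0)], template)
        assert best.r_a == 0.0

    def test_empty_grid_rejected(self):
        template = ModelParameters(r_s=0.5, t_end=1.0, n_lineages=10)
        with pytest.raises(ValueError, match="grid"):
            fit_rates_grid([1.0, 2.0], [], template)
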