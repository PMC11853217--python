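"""HMM sampler correctness: likelihoods against enumeration, conjugate
conditionals, reversible-jump bookkeeping, penalties, and smoothing."""

import itertools
import math

import numpy as np
import pytest

from methmix import MCMCConfig, PanelSimSpec, simulate_panel
from methmix.types import HMMHyper, HMMParameterState, ValidationError
from methmix import hmm
from methmix.hmm import (apply_penalties, complete_data_loglik,
                         forward_posteriors, gibbs_sweep, marginal_loglik,
                         smooth_sample, split_merge_move, transition_counts)


def _enumerate_marginal(params, y, m, missing):
    tot = -np.inf
    L = len(y)
    for path in itertools.product(range(params.K), repeat=L):
        tot = np.logaddexp(tot, complete_data_loglik(
            params, np.array(path), y, m, missing))
    return tot


class TestCompleteDataLoglik:
    def test_single_site_closed_form(self):
        p = HMMParameterState(1, np.array([0.5]), np.ones((2, 1)))
        ll = complete_data_loglik(p, np.array([0]), np.array([1]), np.array([2]))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_term_by_term_product(self, two_state_params):
        y = np.array([1, 0, 3])
        m = np.array([2, 1, 4])
        s = np.array([0, 0, 1])
        th = two_state_params.thetas
        T = two_state_params.trans
        expected = 0.0
        for l in range(3):
            expected += math.log(math.comb(m[l], y[l]))
            expected += y[l] * math.log(th[s[l]]) + (m[l] - y[l]) * math.log(1 - th[s[l]])
        expected += math.log(T[0, s[0]]) + math.log(T[s[0] + 1, s[1]]) \
            + math.log(T[s[1] + 1, s[2]])
        got = complete_data_loglik(two_state_params, s, y, m)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_all_missing_leaves_transition_terms_only(self, two_state_params):
        y = np.array([1, 0, 1])
        m = np.array([2, 2, 2])
        s = np.array([0, 1, 1])
        missing = np.ones(3, dtype=bool)
        T = two_state_params.trans
        expected = math.log(T[0, 0]) + math.log(T[1, 1]) + math.log(T[2, 1])
        assert complete_data_loglik(two_state_params, s, y, m, missing) == \
            pytest.approx(expected, abs=1e-12)

    def test_state_outside_range_raises(self, two_state_params):
        with pytest.raises(ValidationError):
            complete_data_loglik(two_state_params, np.array([0, 2]),
                                 np.array([1, 1]), np.array([2, 2]))


class TestMarginalLoglik:
    def test_order_one_equals_complete_data_value(self):
        p = HMMParameterState(1, np.array([0.3]), np.ones((2, 1)))
        y = np.array([1, 2, 0])
        m = np.array([3, 4, 2])
        assert marginal_loglik(p, y, m) == pytest.approx(
            complete_data_loglik(p, np.zeros(3, int), y, m), abs=1e-10)

    @pytest.mark.parametrize("K,L,seed", [(2, 6, 0), (3, 5, 1), (2, 8, 2)])
    def test_matches_path_enumeration(self, K, L, seed):
        rng = np.random.default_rng(seed)
        thetas = np.sort(rng.uniform(0.05, 0.95, K))
        trans = rng.dirichlet(np.ones(K), size=K + 1)
        p = HMMParameterState(K, thetas, trans, HMMHyper())
        m = rng.integers(1, 8, L)
        y = rng.binomial(m, 0.5)
        missing = rng.random(L) < 0.25
        assert marginal_loglik(p, y, m, missing) == pytest.approx(
            _enumerate_marginal(p, y, m, missing), abs=1e-10)

    def test_fully_missing_site_changes_nothing(self, two_state_params):
        y = np.array([1, 2, 0])
        m = np.array([2, 3, 1])
        base = marginal_loglik(two_state_params, y, m)
        y2 = np.append(y, 0)
        m2 = np.append(m, 5)
        missing = np.array([False, False, False, True])
        assert marginal_loglik(two_state_params, y2, m2, missing) == \
            pytest.approx(base, abs=1e-12)


class TestGibbsSweep:
    def test_theta_conditional_matches_beta_closed_form(self, rng):
        # states held fixed, single state: theta | data ~ Beta(a+Ty, b+Tm-Ty)
        y = np.array([3, 1, 4])
        m = np.array([5, 2, 6])
        ty, tm = y.sum(), m.sum()
        p = HMMParameterState(1, np.array([0.5]), np.ones((2, 1)))
        draws = np.empty(20_000)
        states = np.zeros(3, dtype=int)
        for i in range(draws.size):
            p2, _ = gibbs_sweep(p, states, y, m, rng, resample_states=False)
            draws[i] = p2.thetas[0]
        a, b = 1 + ty, 1 + tm - ty
        mean, var = a / (a + b), a * b / ((a + b) ** 2 * (a + b + 1))
        se = math.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_all_missing_reproduces_beta_prior(self, rng):
        y = np.zeros(4, dtype=int)
        m = np.zeros(4, dtype=int)
        missing = np.ones(4, dtype=bool)
        p = HMMParameterState(1, np.array([0.5]), np.ones((2, 1)))
        draws = np.array([
            gibbs_sweep(p, np.zeros(4, int), y, m, rng, missing,
                        resample_states=False)[0].thetas[0]
            for _ in range(20_000)])
        # flat Beta(1,1) prior: mean 1/2, var 1/12
        se = math.sqrt(1 / 12 / draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_ffbs_marginals_match_forward_backward(self, rng, two_state_params):
        # path draws at fixed parameters follow the exact posterior
        y = np.array([0, 1, 5, 6, 0])
        m = np.array([6, 6, 6, 6, 6])
        obs = np.ones(5, dtype=bool)
        post = forward_posteriors(two_state_params, y, m)
        emit, _ = hmm._scaled_emission(y, m, obs, two_state_params.thetas)
        init = two_state_params.trans[0].copy()
        T = two_state_params.trans[1:].copy()
        counts = np.zeros((5, 2))
        n = 4000
        from methmix._hmm_kernels import ffbs
        for _ in range(n):
            s = ffbs(emit, init, T, rng.random(5))
            counts[np.arange(5), s] += 1
        freq = counts / n
        se = np.sqrt(np.clip(post * (1 - post), 1e-4, None) / n)
        assert np.all(np.abs(freq - post) < 4 * se)

    def test_thetas_stay_sorted_and_states_relabelled(self, rng, small_panel):
        panel, _ = small_panel
        y, m = panel.counts[:, 0], panel.depths[:, 0]
        missing = panel.missing_mask[:, 0]
        p = HMMParameterState(3, np.array([0.2, 0.5, 0.8]),
                              np.full((4, 3), 1 / 3), HMMHyper())
        states = np.zeros(panel.n_positions, dtype=int)
        for _ in range(20):
            p, states = gibbs_sweep(p, states, y, m, rng, missing)
            assert np.all(np.diff(p.thetas) >= 0)
            assert states.min() >= 0 and states.max() < p.K


class TestSplitMerge:
    def test_rejected_move_leaves_inputs_unchanged(self, rng, small_panel):
        panel, _ = small_panel
        y, m = panel.counts[:, 0], panel.depths[:, 0]
        missing = panel.missing_mask[:, 0]
        cfg = MCMCConfig(n_iter=10, burn_in=1, seed=0)
        p = HMMParameterState(2, np.array([0.3, 0.7]), np.full((3, 2), 0.5))
        states = rng.integers(0, 2, panel.n_positions)
        th0, tr0, s0 = p.thetas.copy(), p.trans.copy(), states.copy()
        for _ in range(30):
            p2, s2, accepted, move = split_merge_move(p, states, y, m, cfg, rng,
                                                      missing)
            if not accepted:
                assert np.array_equal(p2.thetas, th0)
                assert np.array_equal(p2.trans, tr0)
                assert np.array_equal(s2, s0)

    def test_split_then_reverse_merge_restores_configuration(self):
        # the deterministic merge of the two offspring is the exact inverse
        thetas = np.array([0.2, 0.6])
        u = 0.07
        j = 1
        split = np.array([0.2, 0.6 - u, 0.6 + u])
        merged = np.delete(split, j + 1)
        merged[j] = (split[j] + split[j + 1]) / 2
        assert np.allclose(merged, thetas, atol=1e-15)
        states = np.array([0, 1, 1, 0, 1])
        offspring = np.array([0, 1, 2, 0, 2])
        back = np.where(offspring > j + 1, offspring - 1, offspring)
        back[offspring == j + 1] = j
        assert np.array_equal(back, states)

    def test_boundary_orders_never_propose_impossible_moves(self, rng):
        y = np.array([2, 3, 1])
        m = np.array([5, 5, 5])
        cfg = MCMCConfig(n_iter=10, burn_in=1, seed=0)
        hyper = HMMHyper(k_max=1)
        p = HMMParameterState(1, np.array([0.5]), np.ones((2, 1)), hyper)
        p2, s2, accepted, move = split_merge_move(
            p, np.zeros(3, int), y, m, cfg, rng)
        assert move == "none" and not accepted and p2.K == 1

    def test_order_recovery_on_well_separated_data(self):
        spec = PanelSimSpec(n_positions=2000, n_samples_per_group=1,
                            true_order=3, true_thetas=(0.1, 0.5, 0.9),
                            missing_rate=0.2, dmc_fraction=0.0, seed=63)
        panel, _ = simulate_panel(spec)
        res = smooth_sample(panel.counts[:, 1], panel.depths[:, 1],
                            panel.missing_mask[:, 1], panel.positions,
                            MCMCConfig(n_iter=500, burn_in=250, thin=2, seed=80))
        assert np.bincount(res.order_trace).argmax() == 3


class TestPenalties:
    def _params(self, thetas):
        K = len(thetas)
        return HMMParameterState(K, np.asarray(thetas), np.full((K + 1, K), 1 / K))

    def test_near_identical_states_are_collapsed(self, rng):
        cfg = MCMCConfig(n_iter=10, burn_in=1, collapse_tol=0.02, seed=0)
        p = self._params([0.40, 0.40 + 0.01])
        y = np.array([4, 4, 4])
        m = np.array([10, 10, 10])
        p2, s2, _ = apply_penalties(p, np.array([0, 1, 0]), y, m, cfg, rng,
                                    compute_boost=False)
        assert p2.K == 1

    def test_well_separated_states_unchanged(self, rng):
        cfg = MCMCConfig(n_iter=10, burn_in=1, collapse_tol=0.01, seed=0)
        p = self._params([0.1, 0.9])
        p2, _, _ = apply_penalties(p, np.array([0, 1]), np.array([1, 8]),
                                   np.array([10, 10]), cfg, rng,
                                   compute_boost=False)
        assert p2.K == 2
        assert np.allclose(p2.thetas, [0.1, 0.9])

    def test_underfit_boost_fires_on_heterogeneous_state(self, rng):
        cfg = MCMCConfig(n_iter=10, burn_in=1, seed=0)
        # one state forced over clearly bimodal counts -> deviance blows up
        y = np.array([0] * 30 + [30] * 30)
        m = np.full(60, 30)
        p = self._params([0.5])
        _, _, boost = apply_penalties(p, np.zeros(60, int), y, m, cfg, rng)
        assert boost == cfg.underfit_penalty_weight

    def test_single_state_chain_rarely_overfits(self):
        spec = PanelSimSpec(n_positions=800, n_samples_per_group=1,
                            true_order=1, true_thetas=(0.5,),
                            missing_rate=0.2, dmc_fraction=0.0, seed=11)
        panel, _ = simulate_panel(spec)
        res = smooth_sample(panel.counts[:, 1], panel.depths[:, 1],
                            panel.missing_mask[:, 1], panel.positions,
                            MCMCConfig(n_iter=500, burn_in=200, thin=1, seed=7))
        assert np.mean(res.order_trace > 1) <= 0.10


class TestSmoothing:
    def test_constant_fully_methylated_input_pulls_levels_high(self):
        m = np.full(80, 20)
        y = m.copy()
        res = smooth_sample(y, m, None, np.arange(1, 81),
                            MCMCConfig(n_iter=200, burn_in=100, thin=1, seed=3))
        assert np.all(res.fitted >= 0.9)

    def test_fitted_levels_strictly_inside_unit_interval(self, small_panel,
                                                         light_chain):
        panel, _ = small_panel
        res = smooth_sample(panel.counts[:, 2], panel.depths[:, 2],
                            panel.missing_mask[:, 2], panel.positions,
                            light_chain)
        assert np.all(res.fitted > 0) and np.all(res.fitted < 1)

    def test_smoothing_beats_raw_ratio_rmse(self):
        spec = PanelSimSpec(n_positions=1500, n_samples_per_group=1,
                            true_order=2, true_thetas=(0.25, 0.75),
                            missing_rate=0.2, dmc_fraction=0.0, seed=29)
        panel, truth = simulate_panel(spec)
        res = smooth_sample(panel.counts[:, 1], panel.depths[:, 1],
                            panel.missing_mask[:, 1], panel.positions,
                            MCMCConfig(n_iter=400, burn_in=200, thin=2, seed=6))
        true_level = spec.true_thetas[truth.states]
        obs = ~panel.missing_mask[:, 1] & (panel.depths[:, 1] > 0)
        raw = panel.counts[obs, 1] / panel.depths[obs, 1]
        rmse_fit = np.sqrt(np.mean((res.fitted[obs] - true_level[obs]) ** 2))
        rmse_raw = np.sqrt(np.mean((raw - true_level[obs]) ** 2))
        assert rmse_fit < rmse_raw

    def test_missing_entries_get_finite_fitted_values(self, small_panel,
                                                      light_chain):
        panel, _ = small_panel
        col = 1
        assert panel.missing_mask[:, col].any()
        res = smooth_sample(panel.counts[:, col], panel.depths[:, col],
                            panel.missing_mask[:, col], panel.positions,
                            light_chain)
        assert np.all(np.isfinite(res.fitted))

    def test_all_missing_sample_raises(self, light_chain):
        with pytest.raises(ValidationError, match="missing"):
            smooth_sample(np.zeros(10, int), np.zeros(10, int),
                          np.ones(10, bool), np.arange(1, 11), light_chain)

    def test_prior_recovery_with_fixed_order(self, rng):
        # Geweke-style successive-conditional run: resimulate data given the
        # current parameters, then Gibbs-update; theta marginals stay at the
        # flat prior.
        L, K = 30, 2
        hyper = HMMHyper()
        p = HMMParameterState(K, np.array([0.3, 0.7]), np.full((K + 1, K), 0.5),
                              hyper)
        states = rng.integers(0, K, L)
        m = np.full(L, 5)
        keep = []
        for it in range(4000):
            y = rng.binomial(m, p.thetas[states])
            p, states = gibbs_sweep(p, states, y, m, rng)
            if it % 4 == 0:
                keep.append(p.thetas.copy())
        keep = np.asarray(keep)
        # order statistics of two flat-prior draws: means 1/3 and 2/3
        se = np.std(keep, axis=0) / math.sqrt(keep.shape[0] / 8)  # autocorr slack
        assert abs(keep[:, 0].mean() - 1 / 3) < 3 * se[0]
        assert abs(keep[:, 1].mean() - 2 / 3) < 3 * se[1]
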