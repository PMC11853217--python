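"""CARS screening and penalized mixture-AFT EM: oracles and recovery."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from sklearn.metrics import rand_score

from methmix import (SurvivalDataset, SurvivalSimSpec,
                     reference_survival_spec, simulate_survival)
from methmix.survival import (EMConfig, MixtureAFTFit, _e_step, _run_em,
                              cars_screen, fit_fm_aft, mixture_loglik,
                              posterior_membership, presmooth_density,
                              select_order)
from methmix.types import ValidationError


def _uncensored(n=200, d=3, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    X -= X.mean(axis=0)
    beta = np.zeros(d) if beta is None else np.asarray(beta)
    log_t = 1.0 + X @ beta + 0.7 * rng.standard_normal(n)
    return SurvivalDataset(time=np.exp(log_t), status=np.ones(n, dtype=int), X=X)


class TestCarsScreen:
    def test_orthonormal_design_reduces_to_squared_pearson(self):
        rng = np.random.default_rng(4)
        n, d = 400, 6
        q, _ = np.linalg.qr(rng.standard_normal((n, d)))
        X = (q - q.mean(axis=0)) * math.sqrt(n)
        y = X[:, 0] * 0.8 + rng.standard_normal(n)
        data = SurvivalDataset(time=np.exp(y - y.min() + 0.1),
                               status=np.ones(n, dtype=int), X=X)
        scores = cars_screen(data, quantile=0.5)
        pearson = np.array([stats.pearsonr(X[:, j], data.log_time)[0] ** 2
                            for j in range(d)])
        assert np.allclose(scores.scores, pearson, atol=5e-3)

    def test_duplicate_covariates_get_equal_scores(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.standard_normal(n)
        X = np.column_stack([x, x, rng.standard_normal(n)])
        X -= X.mean(axis=0)
        y = x + 0.5 * rng.standard_normal(n)
        data = SurvivalDataset(time=np.exp(y - y.min() + 0.1),
                               status=np.ones(n, dtype=int), X=X)
        scores = cars_screen(data, quantile=0.5)
        assert scores.scores[0] == pytest.approx(scores.scores[1], rel=1e-6)

    def test_selected_count_matches_quantile_rule(self):
        data, _ = simulate_survival(reference_survival_spec(seed=3))
        scores = cars_screen(data, quantile=0.95)
        assert scores.selected.size == math.ceil(0.05 * data.d)

    def test_planted_signals_recovered_in_high_dimension(self):
        d, n = 100, 300
        beta = np.zeros(d)
        true_idx = np.array([3, 20, 47, 65, 88])
        beta[true_idx] = [1.2, -1.0, 1.5, -1.3, 1.1]
        spec = SurvivalSimSpec(
            n_subjects=n, n_covariates=d, component_probs=(1.0,),
            intercepts=(2.0,), coefficients=beta[None, :], sigmas=(1.0,),
            censoring_rate=0.3, covariate_correlation=0.3, seed=31)
        data, _ = simulate_survival(spec)
        scores = cars_screen(data, quantile=0.95)
        assert len(set(true_idx) & set(scores.selected)) >= 4

    def test_too_few_covariates_rejected(self):
        data = _uncensored(d=1)
        with pytest.raises(ValidationError):
            cars_screen(data)


class TestMixtureLoglik:
    def test_single_component_equals_lognormal_regression_loglik(self):
        data = _uncensored(seed=2, beta=[0.5, -0.3, 0.0])
        b0, beta, sig = 0.8, np.array([0.4, -0.2, 0.1]), 0.9
        got = mixture_loglik([1.0], [b0], beta[None, :], [sig], data)
        z = (data.log_time - b0 - data.X @ beta) / sig
        expected = np.sum(stats.norm.logpdf(z) - math.log(sig))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_censored_contribution_matches_quadrature(self):
        t = 2.5
        mu, sig = 0.4, 0.8
        data = SurvivalDataset(time=np.array([t, 1.0]),
                               status=np.array([0, 1]),
                               X=np.array([[0.5], [-0.5]]))
        beta = np.array([[0.0]])
        got = mixture_loglik([1.0], [mu], beta, [sig], data)
        # censored subject: integral of the normal density beyond log t
        tail, _ = integrate.quad(
            lambda v: stats.norm.pdf(v, mu, sig), math.log(t), np.inf)
        ev = stats.norm.logpdf((0.0 - mu) / sig) - math.log(sig)
        assert got == pytest.approx(math.log(tail) + ev, abs=1e-8)

    def test_censored_contribution_vanishes_as_time_to_zero(self):
        data = SurvivalDataset(time=np.array([1e-9, 1.0]),
                               status=np.array([0, 1]),
                               X=np.zeros((2, 1)))
        with_tiny = mixture_loglik([1.0], [0.0], np.zeros((1, 1)), [1.0], data)
        data2 = SurvivalDataset(time=np.array([1.0]), status=np.array([1]),
                                X=np.zeros((1, 1)))
        alone = mixture_loglik([1.0], [0.0], np.zeros((1, 1)), [1.0], data2)
        assert with_tiny == pytest.approx(alone, abs=1e-6)  # log S(0) -> 0

    def test_nonpositive_sigma_rejected(self):
        data = _uncensored(n=30)
        with pytest.raises(ValidationError):
            mixture_loglik([1.0], [0.0], np.zeros((1, 3)), [0.0], data)


class TestFitFmAft:
    def test_unpenalized_single_component_matches_ols(self):
        data = _uncensored(n=250, seed=5, beta=[1.0, -0.5, 0.2])
        fit = fit_fm_aft(data, 1, penalty="lasso", lambda_grid=[0.0], seed=0)
        A = np.column_stack([np.ones(data.n), data.X])
        coef, *_ = np.linalg.lstsq(A, data.log_time, rcond=None)
        assert fit.intercepts[0] == pytest.approx(coef[0], abs=1e-6)
        assert np.allclose(fit.betas[0], coef[1:], atol=1e-6)
        resid = data.log_time - A @ coef
        assert fit.sigmas[0] == pytest.approx(
            math.sqrt(np.mean(resid ** 2)), abs=1e-6)

    def test_infinite_penalty_shrinks_all_coefficients_to_zero(self):
        data = _uncensored(n=150, seed=6, beta=[1.0, 0.5, -0.5])
        fit = fit_fm_aft(data, 1, penalty="lasso", lambda_grid=[1e6], seed=0)
        assert np.all(fit.betas == 0.0)
        assert fit.intercepts[0] == pytest.approx(data.log_time.mean(), abs=1e-6)

    def test_penalized_objective_monotone_over_em_iterations(self):
        data, _ = simulate_survival(reference_survival_spec(seed=9))
        track = []
        _run_em(data, 2, np.array([0.05, 0.05]), np.ones((2, data.d)),
                "lasso", EMConfig(), seed=1, track=track)
        diffs = np.diff(track)
        assert np.all(diffs >= -1e-6 * (np.abs(track[:-1]) + 1))

    def test_reported_zero_coefficients_are_exact_zeros(self):
        data, _ = simulate_survival(reference_survival_spec(seed=4))
        fit = fit_fm_aft(data, 2, seed=4)
        zero = fit.betas[fit.betas == 0]
        assert zero.size > 0  # sparsity actually happens
        assert np.all(np.abs(fit.betas[np.abs(fit.betas) > 0]) >= 1e-5)

    def test_reference_two_component_recovery(self):
        """Median over 10 seeds: intercepts within 0.5, all true nonzero
        signs recovered, support sensitivity >= 6/7, <= 2 false positives,
        and labels as accurate as the true-parameter Bayes classifier."""
        spec0 = reference_survival_spec()
        true_beta = spec0.coefficients
        nz = true_beta != 0
        ints, signs, sens, fps, rand_gap = [], [], [], [], []
        for seed in range(1, 11):
            spec = reference_survival_spec(seed=seed)
            data, truth = simulate_survival(spec)
            fit = fit_fm_aft(data, 2, seed=seed)
            ints.append(np.max(np.abs(fit.intercepts - spec.intercepts)))
            signs.append(np.all(
                (np.sign(fit.betas[nz]) == np.sign(true_beta[nz]))
                | (fit.betas[nz] == 0)))
            sens.append((fit.betas[nz] != 0).sum() / nz.sum())
            fps.append((fit.betas[~nz] != 0).sum())
            tau_o, _, _, _ = _e_step(data, spec.component_probs,
                                     spec.intercepts, spec.coefficients,
                                     np.asarray(spec.sigmas))
            oracle = rand_score(truth.memberships, tau_o.argmax(axis=1))
            fitted = rand_score(truth.memberships, fit.labels)
            rand_gap.append(fitted - (oracle - 0.05))
        assert np.median(ints) < 0.5
        assert np.median(sens) >= 6 / 7
        assert np.median(fps) <= 2
        assert np.median(rand_gap) >= 0.0
        # sign agreement among detected true effects in at least half the seeds
        assert np.mean(signs) >= 0.5


class TestSelectOrder:
    def test_single_component_data_selects_order_one(self):
        picks = []
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 4))
            X -= X.mean(axis=0)
            log_t = 1.5 + 0.8 * X[:, 0] + rng.standard_normal(200)
            data = SurvivalDataset(time=np.exp(log_t),
                                   status=np.ones(200, dtype=int), X=X)
            best_k, _ = select_order(data, range(1, 4), seed=seed)
            picks.append(best_k)
        assert sum(k == 1 for k in picks) >= 8

    def test_bic_identity_recomputes_from_stored_pieces(self):
        data, _ = simulate_survival(reference_survival_spec(seed=2))
        fit = fit_fm_aft(data, 2, seed=2)
        assert fit.bic == pytest.approx(-2 * fit.loglik
                                        + fit.df * math.log(data.n), rel=1e-12)


class TestPosteriorMembership:
    def test_rows_sum_to_one_and_degenerate_mixture(self):
        data = _uncensored(n=60, seed=8)
        fit = MixtureAFTFit(
            K=2, pi=np.array([1.0, 0.0]), intercepts=np.array([1.0, 4.0]),
            betas=np.zeros((2, 3)), sigmas=np.array([1.0, 1.0]),
            lambdas=np.zeros(2), loglik=0.0, bic=0.0,
            tau=np.zeros((60, 2)), labels=np.zeros(60, dtype=int),
            penalty="lasso", converged=True)
        tau, labels, summary = posterior_membership(fit, data)
        assert np.allclose(tau.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(tau[:, 0], 1.0)
        assert set(summary["status"]) == {"event"}

    def test_well_separated_components_give_confident_memberships(self):
        spec = SurvivalSimSpec(
            n_subjects=300, n_covariates=2, component_probs=(0.5, 0.5),
            intercepts=(0.0, 6.0), coefficients=np.zeros((2, 2)),
            sigmas=(0.5, 0.5), censoring_rate=0.1, seed=12)
        data, _ = simulate_survival(spec)
        fit = fit_fm_aft(data, 2, penalty="lasso", lambda_grid=[0.01], seed=1)
        tau, _, _ = posterior_membership(fit, data)
        assert tau.max(axis=1).mean() >= 0.95


class TestPresmoothDensity:
    def _data(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        t = np.exp(rng.normal(1.0, 0.5, n))
        c = rng.exponential(10.0, n)
        return np.minimum(t, c), (t <= c).astype(int)

    def test_density_integrates_to_one_and_nonnegative(self):
        t, s = self._data()
        grid, dens = presmooth_density(t, s)
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_location_shift_equivariance(self):
        t, s = self._data(seed=3)
        grid = np.linspace(0.0, 30.0, 400)
        _, d0 = presmooth_density(t, s, grid=grid, bw=0.3)
        _, d1 = presmooth_density(t + 5.0, s, grid=grid + 5.0, bw=0.3)
        assert np.allclose(d0, d1, atol=1e-10)

    def test_all_censored_rejected(self):
        t, _ = self._data()
        with pytest.raises(ValidationError):
            presmooth_density(t, np.zeros_like(t, dtype=int))
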