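import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

import lendingrisk as lr
from lendingrisk.bym import PosteriorDraws


def _draws(beta, offset, n_tracts):
    beta = np.atleast_2d(beta)
    s = beta.shape[0]
    return PosteriorDraws(
        beta=beta,
        u=np.zeros((s, n_tracts)),
        v=np.zeros((s, n_tracts)),
        tau_u=np.ones(s),
        tau_v=np.ones(s),
        dispersion=None,
        chain=np.zeros(s, dtype=int),
        coefficient_names=[f"b{j}" for j in range(beta.shape[1])],
        offset=offset,
    )


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self):
        y = np.array([1.0, 3.0])
        E = np.ones(2)
        X = np.ones((2, 1))
        draws = _draws(np.full((10, 1), 0.4), np.log(E), 2)
        dic, p_d = lr.compute_dic(draws, y, E, X)
        assert p_d == pytest.approx(0.0, abs=1e-10)
        d_hat = -2 * poisson.logpmf(y, np.exp(0.4)).sum()
        assert dic == pytest.approx(d_hat)

    def test_two_tract_hand_oracle(self):
        """DIC from three hand-written draws equals the deviance arithmetic."""
        y = np.array([2.0, 0.0])
        E = np.array([1.0, 2.0])
        X = np.ones((2, 1))
        betas = np.array([[0.1], [0.3], [-0.2]])
        draws = _draws(betas, np.log(E), 2)
        # hand computation with the full Poisson log-pmf
        devs = [-2 * poisson.logpmf(y, E * np.exp(b)).sum() for b in betas[:, 0]]
        d_bar = np.mean(devs)
        eta_bar = np.log(E) + betas.mean()  # posterior-mean linear predictor
        d_hat = -2 * poisson.logpmf(y, np.exp(eta_bar)).sum()
        dic, p_d = lr.compute_dic(draws, y, E, X)
        assert p_d == pytest.approx(d_bar - d_hat)
        assert dic == pytest.approx(2 * d_bar - d_hat)

    def test_single_draw_rejected(self):
        draws = _draws(np.zeros((1, 1)), np.zeros(2), 2)
        with pytest.raises(ValueError, match="2 posterior draws"):
            lr.compute_dic(draws, np.zeros(2), np.ones(2), np.ones((2, 1)))


class TestWAIC:
    def test_brute_force_oracle(self):
        """WAIC matches a direct per-point density computation."""
        rng = np.random.default_rng(0)
        y = np.array([0.0, 1.0, 2.0, 5.0, 3.0])
        E = np.array([0.5, 1.0, 2.0, 3.0, 1.5])
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        betas = rng.normal(0, 0.3, size=(100, 2))
        draws = _draws(betas, np.log(E), 5)
        # brute force in full precision
        lam = E[None, :] * np.exp(betas @ X.T)
        logp = y[None, :] * np.log(lam) - lam - gammaln(y[None, :] + 1)
        lppd = np.log(np.exp(logp).mean(axis=0)).sum()
        p_waic = logp.var(axis=0, ddof=1).sum()
        waic, p_w = lr.compute_waic(draws, y, E, X)
        assert p_w == pytest.approx(p_waic, rel=1e-10)
        assert waic == pytest.approx(-2 * (lppd - p_waic), rel=1e-10)
        assert p_w >= 0

    def test_strong_signal_beats_intercept_only(self):
        from lendingrisk.experiments import model_ranking_experiment

        result = model_ranking_experiment(seed=0, n_reps=3)
        assert result["waic_rank_correct_rate"] == 1.0
        assert result["dic_rank_correct_rate"] == 1.0


class TestPIT:
    def test_midpoint_strictly_inside_unit_interval(self, fitted_trajectory_model):
        draws, y, E, X, *_ = fitted_trajectory_model
        pit = lr.pit_values(draws, y, E, X, randomized=False)
        assert ((pit > 0) & (pit < 1)).all()

    def test_observation_above_all_mass_gives_pit_one(self):
        draws = _draws(np.zeros((50, 1)), np.log(np.ones(1)), 1)
        pit = lr.pit_values(draws, np.array([80.0]), np.ones(1), np.ones((1, 1)))
        assert pit[0] == pytest.approx(1.0)

    def test_uniform_under_own_predictive(self):
        from lendingrisk.experiments import calibration_experiment

        result = calibration_experiment(seed=0, n_reps=20)
        assert result["ks_pass_rate"] >= 0.95

    def test_randomized_pit_seeded(self, fitted_trajectory_model):
        draws, y, E, X, *_ = fitted_trajectory_model
        a = lr.pit_values(draws, y, E, X, seed=3)
        b = lr.pit_values(draws, y, E, X, seed=3)
        np.testing.assert_array_equal(a, b)


class TestPredictiveStats:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0])
        draws = _draws(np.zeros((10, 1)), np.log(y), 2)  # lambda == y exactly
        mae, rmse = lr.posterior_predictive_stats(draws, y, y, np.ones((2, 1)))
        assert mae == pytest.approx(0.0) and rmse == pytest.approx(0.0)

    def test_hand_residuals(self):
        # predictions are exp(offset) = (2, 2); observations (1, 3) and (2, 4)
        draws = _draws(np.zeros((10, 1)), np.log(np.array([2.0, 2.0])), 2)
        X = np.ones((2, 1))
        mae, rmse = lr.posterior_predictive_stats(draws, np.array([1.0, 3.0]), None, X)
        assert mae == pytest.approx(1.0) and rmse == pytest.approx(1.0)
        mae2, rmse2 = lr.posterior_predictive_stats(draws, np.array([2.0, 4.0]), None, X)
        assert mae2 == pytest.approx(1.0) and rmse2 == pytest.approx(np.sqrt(2))


class TestVarianceToMean:
    def test_constant_counts(self):
        assert lr.variance_to_mean(np.ones(4)) == 0.0

    def test_hand_value_n_minus_one_convention(self):
        assert lr.variance_to_mean(np.array([0.0, 4.0])) == pytest.approx(4.0)

    def test_poisson_equidispersion(self):
        y = np.random.default_rng(0).poisson(5.0, size=200_000)
        assert lr.variance_to_mean(y) == pytest.approx(1.0, abs=0.02)

    def test_zero_mean_warns(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(lr.variance_to_mean(np.zeros(3)))


class TestESS:
    def test_iid_normal_near_n(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        assert 8_000 <= lr.effective_sample_size(x) <= 12_000

    def test_ar1_closed_form(self):
        rho, n = 0.9, 200_000
        rng = np.random.default_rng(2)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert lr.effective_sample_size(x) == pytest.approx(expected, rel=0.2)

    def test_constant_chain_reports_length_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert lr.effective_sample_size(np.full(500, 3.0)) == 500.0

    def test_agrees_with_arviz_on_iid_draws(self):
        """Cross-check against an independent ESS implementation."""
        import arviz as az

        x = np.random.default_rng(3).standard_normal(5_000)
        ours = lr.effective_sample_size(x)
        theirs = float(az.ess(x[None, :]))
        assert ours == pytest.approx(theirs, rel=0.25)


def test_diagnose_fit_bundle(fitted_trajectory_model):
    draws, y, E, X, *_ = fitted_trajectory_model
    diag = lr.diagnose_fit(draws, y, E, X)
    assert diag.rmse >= diag.mae >= 0
    assert diag.p_waic >= 0
    assert all(0 <= p <= 1 for p in diag.pit)
    assert set(diag.ess) >= set(draws.coefficient_names)
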