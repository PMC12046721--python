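import numpy as np
import pandas as pd
import pytest

import lendingrisk as lr
from lendingrisk.bym import PosteriorDraws
from lendingrisk.design import ADI_DUMMIES, TRAJECTORY_DUMMIES


def _draws_from_beta(beta, n_tracts=1, offset=None, names=None):
    """Hand-built PosteriorDraws with zero random effects."""
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
        coefficient_names=names or [f"b{j}" for j in range(beta.shape[1])],
        offset=offset if offset is not None else np.zeros(n_tracts),
    )


class TestBuildDesign:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        from lendingrisk.trajectory import TRAJECTORY_LEVELS

        return pd.DataFrame(
            {
                "trajectory": rng.choice(TRAJECTORY_LEVELS, n),
                "adi_decile": rng.integers(1, 11, n),
                "diversity": rng.uniform(0, 0.85, n),
            }
        )

    def test_full_model_has_fourteen_columns(self):
        X, names = lr.build_design(self._table(200, seed=1))
        assert X.shape[1] == 14  # intercept + 3 trajectory + 9 ADI + diversity
        assert names[0] == "intercept"
        assert tuple(names[1:4]) == TRAJECTORY_DUMMIES
        assert tuple(names[4:13]) == ADI_DUMMIES
        assert names[13] == "diversity"

    def test_reference_tract_row_is_intercept_only(self):
        df = self._table(200, seed=1)
        df.loc[0, ["trajectory", "adi_decile", "diversity"]] = ["disinvested", 1, 0.0]
        X, _ = lr.build_design(df)
        assert X[0, 0] == 1.0 and not X[0, 1:].any()

    def test_trajectory_only_four_columns(self):
        X, names = lr.build_design(self._table(100, seed=2), ("trajectory",))
        assert X.shape[1] == 4

    def test_absent_category_refused(self):
        df = self._table(50, seed=3)
        df["trajectory"] = "disinvested"  # dummies would be all-zero
        with pytest.raises(ValueError, match="absent"):
            lr.build_design(df, ("trajectory",))


class TestFitBYM:
    def test_posterior_matches_glm_oracle(self):
        """No random effects + flat prior: posterior mean == IRLS MLE (2 MCSE).

        The in-package Newton solver initializes the chain; statsmodels is
        the independent oracle here.
        """
        import statsmodels.api as sm
        from lendingrisk.experiments import glm_oracle_experiment, _latent_design
        from lendingrisk.synthetic import SimulationConfig, simulate_study

        result = glm_oracle_experiment(seed=0)
        assert result["max_abs_z_vs_mle"] < 2.0

        # and the package's own IRLS agrees with statsmodels to tight tolerance
        cfg = SimulationConfig(n_rows=5, n_cols=10, seed=0, fixed_expected=2.0)
        table, _, truth = simulate_study(cfg)
        _, X, names, y, E = _latent_design(table, truth)
        mine, _ = lr.poisson_irls(y, np.log(E), X)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(E)).fit()
        np.testing.assert_allclose(mine, ref.params, atol=1e-8)

    def test_sum_to_zero_every_retained_draw(self, fitted_trajectory_model):
        draws, *_ = fitted_trajectory_model
        assert np.abs(draws.u.sum(axis=1)).max() < 1e-8

    def test_all_zero_counts_push_risk_down(self):
        adj = lr.generate_adjacency(4, 4, "rook")
        y = np.zeros(16)
        E = np.full(16, 0.5)
        X = np.ones((16, 1))
        draws = lr.fit_bym(
            y, E, X, adj,
            lr.ModelSpec(covariates=()),
            lr.MCMCSettings(chains=1, iterations=1500, burn_in=500, thin=1, seed=0),
        )
        assert np.exp(draws.beta[:, 0]).mean() < 1.0
        rr = draws.relative_risk(X)
        assert np.median(rr) < 1.0

    def test_zero_expected_count_rejected(self):
        adj = lr.generate_adjacency(2, 2, "rook")
        with pytest.raises(ValueError, match="expected counts"):
            lr.fit_bym(
                np.ones(4), np.array([1.0, 0.0, 1.0, 1.0]), np.ones((4, 1)), adj
            )

    def test_negative_binomial_large_dispersion_matches_poisson(self):
        """NB with dispersion -> inf is the Poisson model (shared fixture)."""
        from lendingrisk.experiments import _latent_design
        from lendingrisk.synthetic import SimulationConfig, simulate_study

        cfg = SimulationConfig(n_rows=8, n_cols=8, seed=13, fixed_expected=5.0)
        table, adj, truth = simulate_study(cfg)
        _, X, names, y, E = _latent_design(table, truth)
        settings = lr.MCMCSettings(chains=1, iterations=3000, burn_in=1000, thin=2, seed=3)
        pois = lr.fit_bym(y, E, X, adj, lr.ModelSpec(covariates=("trajectory",)), settings, names)
        nb = lr.fit_bym(
            y, E, X, adj,
            lr.ModelSpec(covariates=("trajectory",), likelihood="negative_binomial",
                         fixed_dispersion=1e6),
            settings, names,
        )
        sd = pois.beta.std(axis=0, ddof=1)
        assert np.all(np.abs(pois.beta.mean(axis=0) - nb.beta.mean(axis=0)) < 4 * sd / 10)

    def test_prior_sensitivity_reports_bounded_shift(self, fitted_trajectory_model):
        """Refitting under the weaker N(0,10)/Gamma(0.1,0.01) priors yields
        finite, comparable exponentiated effects on the standard fixture."""
        draws, y, E, X, names, adj = fitted_trajectory_model
        weak = lr.fit_bym(
            y, E, X, adj,
            lr.ModelSpec(covariates=("trajectory",), prior_beta=(0.0, 10.0),
                         prior_precision=(0.1, 0.01)),
            lr.MCMCSettings(chains=1, iterations=2000, burn_in=500, thin=2, seed=7),
            coefficient_names=names,
        )
        delta = np.abs(np.exp(draws.beta).mean(axis=0) - np.exp(weak.beta).mean(axis=0))
        assert np.isfinite(delta).all(), f"prior-sensitivity shifts: {delta}"

    def test_seeded_determinism(self):
        adj = lr.generate_adjacency(3, 3, "rook")
        y = np.arange(9.0)
        E = np.full(9, 2.0)
        X = np.ones((9, 1))
        settings = lr.MCMCSettings(chains=2, iterations=600, burn_in=100, thin=1, seed=5)
        d1 = lr.fit_bym(y, E, X, adj, lr.ModelSpec(covariates=()), settings)
        d2 = lr.fit_bym(y, E, X, adj, lr.ModelSpec(covariates=()), settings)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.u, d2.u)


class TestSummaries:
    def test_degenerate_posterior(self):
        draws = _draws_from_beta(np.full((200, 1), np.log(2.0)))
        summary = lr.summarize_relative_risks(draws, np.ones((1, 1)))
        row = summary.coefficients.iloc[0]
        assert row["rr_mean"] == pytest.approx(2.0)
        assert row["rr_lo_2.5"] == pytest.approx(2.0)
        assert row["rr_hi_97.5"] == pytest.approx(2.0)

    def test_lognormal_mean_identity(self):
        rng = np.random.default_rng(0)
        draws = _draws_from_beta(rng.normal(0, 0.1, size=(100_000, 1)))
        summary = lr.summarize_relative_risks(draws, np.ones((1, 1)))
        assert summary.coefficients["rr_mean"][0] == pytest.approx(
            np.exp(0.005), abs=2e-3
        )

    def test_reference_tract_rr_is_intercept(self):
        rng = np.random.default_rng(1)
        beta = np.column_stack([rng.normal(0.3, 0.2, 500), rng.normal(1.0, 0.2, 500)])
        X = np.array([[1.0, 0.0]])  # reference covariates, u = v = 0
        draws = _draws_from_beta(beta, n_tracts=1)
        summary = lr.summarize_relative_risks(draws, X)
        assert summary.tracts["rr_median"][0] == pytest.approx(
            np.median(np.exp(beta[:, 0]))
        )

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            lr.summarize_relative_risks(_draws_from_beta(np.zeros((50, 1))), np.ones((1, 1)))


class TestExceedance:
    def test_point_mass_at_three(self):
        draws = _draws_from_beta(np.full((300, 1), np.log(3.0)))
        probs = lr.exceedance_probabilities(draws, np.ones((1, 1)))
        assert probs["pr_rr_gt_2"][0] == 1.0
        assert probs["pr_rr_gt_4"][0] == 0.0

    def test_monotone_in_threshold(self, fitted_trajectory_model):
        draws, y, E, X, *_ = fitted_trajectory_model
        probs = lr.exceedance_probabilities(draws, X, thresholds=(1, 2, 3, 4))
        stacked = np.vstack([probs[f"pr_rr_gt_{c}"] for c in (1, 2, 3, 4)])
        assert (np.diff(stacked, axis=0) <= 0).all()
        assert ((stacked >= 0) & (stacked <= 1)).all()

    def test_lognormal_median_exceedance(self):
        rng = np.random.default_rng(2)
        draws = _draws_from_beta(rng.normal(0, 1, size=(200_000, 1)))
        probs = lr.exceedance_probabilities(draws, np.ones((1, 1)), thresholds=(1.0,))
        assert probs["pr_rr_gt_1"][0] == pytest.approx(0.5, abs=5e-3)
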