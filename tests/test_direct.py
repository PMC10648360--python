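"""Direct mapping estimators: OLS geometry, Tobit likelihood, beta-mixture."""

import warnings

import numpy as np
import pytest
from scipy import special, stats

from sf6dmap import (
    BetaMixtureRegression,
    LinearUtilityRegression,
    TobitRegression,
    fit_betamix,
    fit_ols,
    fit_tobit,
    predict_direct,
)


def tobit_loglik_oracle(beta, sigma, X, y, limit=1.0):
    """Censored-normal log-likelihood written independently of the estimator."""
    eta = X @ np.asarray(beta)
    cens = y >= limit
    ll = stats.norm.logpdf(y[~cens], loc=eta[~cens], scale=sigma).sum()
    ll += stats.norm.logsf(limit, loc=eta[cens], scale=sigma).sum()
    return float(ll)


class TestOLS:
    def test_intercept_only_mean(self):
        X = np.ones((5, 1))
        fit = fit_ols(X, np.full(5, 0.5))
        assert fit.coef_[0] == pytest.approx(0.5)
        np.testing.assert_allclose(fit.predict(X), 0.5)

    def test_exact_line(self):
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        fit = fit_ols(X, np.array([1.0, 3.0, 5.0]))
        np.testing.assert_allclose(fit.coef_, [1.0, 2.0], atol=1e-12)
        assert predict_direct(fit, [[1.0, 3.0]])[0] == pytest.approx(7.0)

    def test_residuals_orthogonal_to_design(self, cohort):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M3")
        y = cohort["utility"].to_numpy()
        fit = fit_ols(X, y)
        resid = y - fit.predict(X)
        assert np.max(np.abs(resid @ X)) / len(y) < 1e-8

    def test_matches_statsmodels(self, cohort):
        import statsmodels.api as sm_api

        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M5")
        y = cohort["utility"].to_numpy()
        ours = fit_ols(X, y)
        ref = sm_api.OLS(y, X).fit()
        np.testing.assert_allclose(ours.coef_, ref.params, rtol=1e-7)
        assert ours.loglik_ == pytest.approx(ref.llf, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(X, np.arange(10.0), feature_names=["intercept", "a", "a2"])


class TestTobit:
    def test_equals_ols_without_censoring(self, rng):
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = 0.3 + 0.1 * X[:, 1] + 0.05 * rng.normal(size=300)  # well below 1
        ols = fit_ols(X, y)
        tob = fit_tobit(X, y)
        assert tob.n_censored_ == 0
        np.testing.assert_allclose(tob.coef_, ols.coef_, atol=1e-6)
        assert tob.sigma_ == pytest.approx(ols.sigma_, abs=1e-6)

    def test_recovers_slope_under_heavy_censoring(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.normal(size=n)
        latent = 1.0 + 0.25 * x + 0.2 * rng.normal(size=n)
        y = np.minimum(latent, 1.0)  # ~ 40-50% at the ceiling
        X = np.column_stack([np.ones(n), x])
        fit = fit_tobit(X, y)
        assert fit.n_censored_ == pytest.approx(0.45 * n, rel=0.25)
        assert fit.coef_[1] == pytest.approx(0.25, abs=0.05)
        assert fit.sigma_ == pytest.approx(0.2, abs=0.03)

    def test_loglik_beats_grid_oracle(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.normal(size=n)
        y = np.minimum(0.8 + 0.2 * x + 0.15 * rng.normal(size=n), 1.0)
        X = np.column_stack([np.ones(n), x])
        fit = fit_tobit(X, y)
        assert fit.loglik_ == pytest.approx(
            tobit_loglik_oracle(fit.coef_, fit.sigma_, X, y), abs=1e-8
        )
        grid_best = max(
            tobit_loglik_oracle([b0, b1], s, X, y)
            for b0 in np.linspace(0.7, 0.9, 9)
            for b1 in np.linspace(0.1, 0.3, 9)
            for s in np.linspace(0.1, 0.25, 7)
        )
        assert fit.loglik_ >= grid_best - 1e-9

    def test_loglik_at_least_ols_start(self, cohort):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M3")
        y = cohort["utility"].to_numpy()
        fit = fit_tobit(X, y)
        ols = fit_ols(X, y)
        start_ll = tobit_loglik_oracle(ols.coef_, ols.sigma_, X, y)
        assert fit.loglik_ >= start_ll - 1e-9

    def test_all_censored_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="interior"):
            fit_tobit(X, np.ones(5))

    def test_censored_mean_prediction_below_limit(self, cohort):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M1")
        fit = fit_tobit(X, cohort["utility"].to_numpy())
        assert (fit.predict(X) <= 1.0 + 1e-12).all()
        # censored mean shrinks the latent index toward the limit from below
        assert (fit.predict(X) <= fit.predict(X, kind="latent") + 1e-12).all()


class TestBetaMixture:
    def test_interceptonly_boundary_probability_is_sample_share(self, rng):
        n = 200
        y = np.where(rng.random(n) < 0.3, 1.0, 0.5 + 0.1 * rng.random(n))
        share = float(np.mean(y == 1.0))
        X = np.ones((n, 1))
        fit = fit_betamix(X, y, bounds=(0.0, 1.0), n_starts=2)
        assert fit.boundary_probability(X)[0] == pytest.approx(share, abs=1e-4)

    def test_single_component_recovery_vs_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 2000
        mu, phi = 0.4, 5.0
        y = rng.beta(mu * phi, (1 - mu) * phi, size=n)
        X = np.ones((n, 1))
        fit = fit_betamix(X, y, bounds=(0.0, 1.0), n_starts=2)
        mu_hat = float(special.expit(fit.coef_mu_[0, 0]))
        assert mu_hat == pytest.approx(mu, abs=0.03)
        assert fit.phi_[0] == pytest.approx(phi, rel=0.20)
        # independent grid maximum-likelihood oracle
        grid_best = -np.inf
        for m in np.linspace(0.35, 0.45, 21):
            for p in np.linspace(4.0, 6.5, 26):
                ll = stats.beta.logpdf(y, m * p, (1 - m) * p).sum()
                grid_best = max(grid_best, ll)
        assert fit.loglik_ >= grid_best - 1e-6

    def test_prediction_matches_monte_carlo_sampler(self, cohort, tariff):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M3")
        y = cohort["utility"].to_numpy()
        fit = fit_betamix(X, y, bounds=(tariff.min_utility, 1.0), n_starts=2)
        row = X[:1]
        pred = fit.predict(row)[0]
        rng = np.random.default_rng(0)
        nmc = 1_000_000
        lb, ub = fit.bounds
        pb = fit.boundary_probability(row)[0]
        mus = special.expit(row @ fit.coef_mu_.T)[0]
        comps = rng.choice(fit.components, size=nmc, p=fit.weights_)
        a = mus[comps] * fit.phi_[comps]
        b = (1 - mus[comps]) * fit.phi_[comps]
        draws = lb + (ub - lb) * rng.beta(a, b)
        draws = np.where(rng.random(nmc) < pb, ub, draws)
        assert pred == pytest.approx(draws.mean(), abs=0.002)

    def test_loglik_nondecreasing_in_components(self, cohort, tariff):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M1")
        y = cohort["utility"].to_numpy()
        lls = []
        for c in (1, 2):
            fit = fit_betamix(
                X, y, components=c, bounds=(tariff.min_utility, 1.0), n_starts=4
            )
            if fit.converged_:
                lls.append(fit.loglik_)
        assert len(lls) >= 2 and lls[1] >= lls[0] - 1e-6

    def test_component_means_ordered(self, cohort, tariff):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M1")
        y = cohort["utility"].to_numpy()
        fit = fit_betamix(
            X, y, components=2, bounds=(tariff.min_utility, 1.0), n_starts=4
        )
        mu_bar = special.expit(X.mean(axis=0) @ fit.coef_mu_.T)
        assert np.all(np.diff(mu_bar) >= 0)

    def test_overparameterised_fit_flagged(self, rng):
        X = np.ones((10, 1))
        y = 0.4 + 0.2 * rng.random(10)
        with pytest.warns(UserWarning, match="non-converged"):
            fit = fit_betamix(X, y, components=3, bounds=(0.0, 1.0), n_starts=2)
        assert not fit.converged_

    def test_boundary_requested_without_mass_errors(self, rng):
        y = 0.4 + 0.2 * rng.random(50)
        with pytest.raises(ValueError, match="boundary"):
            BetaMixtureRegression(bounds=(0.0, 1.0), boundary_mass=True).fit(
                np.ones((50, 1)), y
            )

    def test_boundary_only_model_predicts_ub(self):
        fit = BetaMixtureRegression.from_dict(
            {
                "components": 1,
                "truncated": False,
                "bounds": [0.315, 1.0],
                "gap": 0.0,
                "coef_mu": [[0.0]],
                "lnphi": [1.0],
                "weight_logits": [],
                "coef_boundary": [50.0],  # p(x) ~ 1 everywhere
                "loglik": 0.0,
                "n_obs": 1,
                "n_params": 4,
            }
        )
        np.testing.assert_allclose(fit.predict(np.ones((4, 1))), 1.0, atol=1e-12)

    def test_truncated_variant_uses_truncated_mean(self, rng):
        n = 600
        y = 0.3 + 0.4 * rng.beta(2.0, 2.0, size=n)
        X = np.ones((n, 1))
        gap = 0.08
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = fit_betamix(X, y, bounds=(0.0, 1.0), boundary_mass=False, n_starts=2)
            trunc = fit_betamix(
                X,
                y,
                bounds=(0.0, 1.0),
                truncated=True,
                gap=gap,
                boundary_mass=False,
                n_starts=2,
            )
        # the truncated mean must sit below the untruncated one for the
        # same parameters; both predictions stay inside the support
        assert trunc.predict(X)[0] <= 1.0 - 0.0  # inside bounds
        assert trunc.upper_ == pytest.approx(1.0 - gap)

    def test_serialization_round_trip(self, cohort, tariff):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M3")
        y = cohort["utility"].to_numpy()
        fit = fit_betamix(X, y, bounds=(tariff.min_utility, 1.0), n_starts=2)
        back = BetaMixtureRegression.from_dict(fit.to_dict())
        np.testing.assert_allclose(back.predict(X), fit.predict(X), atol=1e-12)


class TestSerialization:
    def test_ols_and_tobit_round_trip(self, cohort):
        from sf6dmap import build_design_matrix

        X, _ = build_design_matrix(cohort, "M3")
        y = cohort["utility"].to_numpy()
        for fit, cls in (
            (fit_ols(X, y), LinearUtilityRegression),
            (fit_tobit(X, y), TobitRegression),
        ):
            back = cls.from_dict(fit.to_dict())
            np.testing.assert_allclose(back.predict(X), fit.predict(X), atol=1e-12)
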