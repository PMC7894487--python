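"""Gibbs sampler correctness: limits, determinism, recovery, summaries."""

import numpy as np
import pytest

from natdiv.pglmm import (MCMCSettings, PriorSpec, ChainDraws,
                          PosteriorSamples, gibbs_fit, glmm_fit,
                          posterior_summary)

FAST = MCMCSettings(n_iter=6000, burn_in=1000, thin=5, n_chains=1, seed=0)


class TestSettings:
    def test_retained_count_formula(self):
        s = MCMCSettings(520_000, 20_000, 100, 3, 0)
        assert s.n_retained == 5000

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=0, thin=0)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(V=0)


class TestGibbsFit:
    def test_same_seed_identical_chains(self, latent_fit_problem):
        p = latent_fit_problem
        f1 = gibbs_fit(p["y"], p["X"], p["A"], settings=FAST)
        f2 = gibbs_fit(p["y"], p["X"], p["A"], settings=FAST)
        np.testing.assert_array_equal(f1.chains[0].beta, f2.chains[0].beta)
        np.testing.assert_array_equal(f1.chains[0].sigma2_e,
                                      f2.chains[0].sigma2_e)

    def test_different_seed_differs(self, latent_fit_problem):
        p = latent_fit_problem
        f1 = gibbs_fit(p["y"], p["X"], p["A"], settings=FAST)
        f2 = gibbs_fit(p["y"], p["X"], p["A"],
                       settings=MCMCSettings(6000, 1000, 5, 1, 1))
        assert not np.array_equal(f1.chains[0].beta, f2.chains[0].beta)

    def test_ols_limit_without_random_effect(self):
        # sigma2_p frozen at ~0 and a flat beta prior: posterior mean -> OLS
        rng = np.random.default_rng(12)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ np.array([2.0, 1.0, -0.5]) + rng.normal(0, 1, n)
        fit = gibbs_fit(y, X, np.eye(n),
                        settings=MCMCSettings(20_000, 2000, 3, 1, 4),
                        fixed_sigma2_p=1e-10)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        summ = posterior_summary(fit)
        for i, name in enumerate(fit.labels):
            draws = fit.pooled(name)
            se = 3 * draws.std(ddof=1) / np.sqrt(summ.loc[name, "eff_samp"])
            assert abs(summ.loc[name, "post_mean"] - ols[i]) < se

    def test_conjugate_posterior_with_frozen_variances(self):
        # A = I, variances fixed: each beta draw is an exact draw from the
        # analytic Gaussian posterior of the marginal model
        rng = np.random.default_rng(13)
        n, s2p, s2e = 60, 0.5, 1.0
        X = rng.standard_normal((n, 3))
        y = X @ np.array([0.6, -0.2, 0.3]) + rng.normal(0, np.sqrt(s2p + s2e), n)
        priors = PriorSpec(beta_var=1e10)
        fit = gibbs_fit(y, X, np.eye(n), priors=priors,
                        settings=MCMCSettings(8000, 0, 1, 1, 5),
                        fixed_sigma2_p=s2p, fixed_sigma2_e=s2e)
        prec = X.T @ X / (s2p + s2e) + np.eye(3) / priors.beta_var
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ y) / (s2p + s2e)
        draws = fit.chains[0].beta
        m = draws.shape[0]
        for i in range(3):
            se = 3 * np.sqrt(cov[i, i] / m)
            assert abs(draws[:, i].mean() - mean[i]) < se
        emp = np.cov(draws.T)
        assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) < 0.10

    def test_variance_draws_positive_deviance_finite(self, latent_fit_problem):
        p = latent_fit_problem
        fit = gibbs_fit(p["y"], p["X"], p["A"], settings=FAST)
        c = fit.chains[0]
        assert (c.sigma2_p > 0).all() and (c.sigma2_e > 0).all()
        assert np.isfinite(c.deviance).all()

    def test_chain_stability_under_longer_runs(self, latent_fit_problem):
        p = latent_fit_problem
        short = gibbs_fit(p["y"], p["X"], p["A"],
                          settings=MCMCSettings(6000, 1000, 5, 1, 9))
        long = gibbs_fit(p["y"], p["X"], p["A"],
                         settings=MCMCSettings(60_000, 1000, 5, 1, 9))
        for name in short.labels:
            d_short, d_long = short.pooled(name), long.pooled(name)
            band = 3 * (d_short.std(ddof=1) / np.sqrt(200)
                        + d_long.std(ddof=1) / np.sqrt(2000))
            assert abs(d_short.mean() - d_long.mean()) < band

    def test_non_psd_matrix_rejected(self):
        A = np.eye(5)
        A[0, 1] = A[1, 0] = 2.0  # eigenvalue < 0
        with pytest.raises(ValueError, match="positive semidefinite"):
            gibbs_fit(np.zeros(5), np.ones((5, 1)), A, settings=FAST)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gibbs_fit(np.zeros(4), np.ones((5, 1)), np.eye(5), settings=FAST)


class TestGlmmFit:
    def test_singleton_groups_match_identity_pglmm(self):
        rng = np.random.default_rng(21)
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(0, 1, n)
        groups = [f"g{i:03d}" for i in range(n)]  # sorted == row order
        f_grp = glmm_fit(y, X, groups, settings=FAST)
        f_phy = gibbs_fit(y, X, np.eye(n), settings=FAST)
        np.testing.assert_allclose(f_grp.chains[0].beta,
                                   f_phy.chains[0].beta, atol=1e-10)

    def test_recovers_group_variance(self):
        rng = np.random.default_rng(22)
        n_orders, per = 30, 6
        n = n_orders * per
        groups = np.repeat([f"o{i:02d}" for i in range(n_orders)], per)
        g = rng.normal(0, 1.0, n_orders)  # sigma2_g = 1
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([0.0, 0.5]) + g[np.arange(n) // per] \
            + rng.normal(0, 1.0, n)
        fit = glmm_fit(y, X, groups,
                       settings=MCMCSettings(20_000, 2000, 10, 1, 3))
        summ = posterior_summary(fit)
        lo, hi = summ.loc["sigma2_p", ["hpd_lower", "hpd_upper"]]
        assert lo < 1.0 < hi

    def test_unmapped_rows_rejected(self):
        with pytest.raises(ValueError, match="group label"):
            glmm_fit(np.zeros(3), np.ones((3, 1)), ["a", "", "b"],
                     settings=FAST)


class TestPosteriorSummary:
    @staticmethod
    def _from_draws(draws_by_chain, label="b0"):
        chains = []
        for d in draws_by_chain:
            d = np.asarray(d, dtype=float)
            m = len(d)
            chains.append(ChainDraws(
                beta=d[:, None], sigma2_p=np.ones(m), sigma2_e=np.ones(m),
                u=np.zeros((m, 1)), deviance=np.zeros(m)))
        settings = MCMCSettings(n_iter=len(draws_by_chain[0]), burn_in=0,
                                thin=1, n_chains=len(draws_by_chain))
        return PosteriorSamples(labels=[label], chains=chains,
                                settings=settings, priors=PriorSpec())

    def test_degenerate_draws(self):
        s = self._from_draws([np.full(100, 0.5)])
        summ = posterior_summary(s)
        assert summ.loc["b0", "post_mean"] == 0.5
        assert summ.loc["b0", "hpd_lower"] == summ.loc["b0", "hpd_upper"] == 0.5

    def test_iid_normal_draws(self):
        rng = np.random.default_rng(30)
        s = self._from_draws([rng.standard_normal(5000)])
        summ = posterior_summary(s)
        assert abs(summ.loc["b0", "post_mean"]) < 3 / np.sqrt(5000)
        assert summ.loc["b0", "pmcmc"] > 0.8
        assert summ.loc["b0", "eff_samp"] == pytest.approx(5000, rel=0.25)
        assert summ.loc["b0", "hpd_lower"] == pytest.approx(-1.96, abs=0.15)
        assert summ.loc["b0", "hpd_upper"] == pytest.approx(1.96, abs=0.15)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(31)
        d = rng.standard_normal(2000) + 0.5
        s_pos = self._from_draws([d])
        s_neg = self._from_draws([-d])
        a, b = posterior_summary(s_pos), posterior_summary(s_neg)
        assert a.loc["b0", "post_mean"] == pytest.approx(
            -b.loc["b0", "post_mean"])
        assert a.loc["b0", "pmcmc"] == b.loc["b0", "pmcmc"]

    def test_pmcmc_floor(self):
        s = self._from_draws([np.abs(np.random.default_rng(1).standard_normal(500)) + 0.1])
        summ = posterior_summary(s)
        assert summ.loc["b0", "pmcmc"] == pytest.approx(2 / 500)
        assert summ.loc["b0", "pmcmc_str"].startswith("<")
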