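"""Sampler correctness: conjugate oracles, beta-binomial limit, bookkeeping."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import hostassay as ha
from hostassay.mcmc import (MCMCSettings, ModelSpec, PriorSpec,
                            fit_binary_glmm, fit_gaussian_lmm)


def pure_intercept_table(y):
    n = len(y)
    return pd.DataFrame(
        {
            "pupal_mass_mg": y,
            "survived": y,
            "dev_time_days": y,
            "population": ["p1"] * n,
            "host": ["h1"] * n,
            "culture": ["c1"] * n,
            "sex": ["F"] * n,
        }
    )


class TestSettingsBookkeeping:
    def test_stored_draw_count(self):
        s = MCMCSettings(iterations=100, burnin=0, thin=1)
        assert s.n_stored == 100

    def test_published_protocol_draw_count(self):
        s = MCMCSettings.published_protocol()
        assert s.n_stored == 10_000

    @pytest.mark.parametrize("kw", [
        dict(iterations=100, burnin=100),
        dict(iterations=100, burnin=0, thin=0),
    ])
    def test_invalid_settings(self, kw):
        with pytest.raises(ValueError):
            MCMCSettings(**kw)


class TestGaussianSampler:
    def test_pure_intercept_recovers_known_mean(self):
        rng = np.random.default_rng(0)
        y = 26.3 + rng.standard_normal(300)
        spec = ModelSpec("mass", "gaussian", ())
        settings = MCMCSettings(iterations=3000, burnin=500, thin=2, seed=1)
        draws = fit_gaussian_lmm(pure_intercept_table(y), spec,
                                 settings=settings)
        b0 = draws.intercept()
        assert abs(b0.mean() - 26.3) < 3 * b0.std() + 3 / np.sqrt(len(y))

    def test_matches_closed_form_at_fixed_variances(self, fixtures):
        """With every variance fixed, the location posterior is exactly
        multivariate normal; sampled moments must agree with it."""
        table = fixtures["small"]
        spec = ModelSpec.mass()
        fixed = {"host": 20.0, "population": 1.0, "population:host": 5.0,
                 "sex": 2.0, "culture": 0.5, "residual": 14.0}
        settings = MCMCSettings(iterations=6000, burnin=1000, thin=5, seed=2)
        draws = fit_gaussian_lmm(table, spec, settings=settings,
                                 fixed_variances=fixed)

        # independent closed-form oracle built from a dense design matrix
        df = table[table["pupal_mass_mg"].notna() & table["sex"].notna()]
        y = df["pupal_mass_mg"].to_numpy()
        cols = [np.ones((len(df), 1))]
        names = ["intercept"]
        for term in spec.random_terms:
            vals = (df[term] if ":" not in term
                    else df["population"].astype(str) + ":" + df["host"])
            dummies = pd.get_dummies(vals)
            # match sampler level ordering (sorted categories)
            dummies = dummies[sorted(dummies.columns)]
            cols.append(dummies.to_numpy(float))
            names += [f"u_{term}[{c}]" for c in dummies.columns]
        C = np.hstack(cols)
        ve = fixed["residual"]
        prior_prec = np.concatenate(
            [[1e-8]] + [np.full(len(draws.levels[t]), 1.0 / fixed[t])
                        for t in spec.random_terms])
        P = C.T @ C / ve + np.diag(prior_prec)
        cov = np.linalg.inv(P)
        mean = cov @ (C.T @ y / ve)

        for j, name in enumerate(names):
            chain = draws.params[name].to_numpy()
            se = 4 * chain.std() / np.sqrt(50)  # conservative chain SE
            assert chain.mean() == pytest.approx(mean[j], abs=se + 0.05)
            assert chain.std() == pytest.approx(
                np.sqrt(cov[j, j]), rel=0.25)

    def test_prior_recovery_with_uninformative_likelihood(self):
        """With the residual fixed enormous the likelihood is flat, so
        variance draws must reproduce their scaled-inverse-chi-square prior."""
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "pupal_mass_mg": rng.standard_normal(60),
                "host": np.repeat([f"h{i}" for i in range(6)], 10),
                "population": ["p1", "p2"] * 30,
                "culture": ["c1"] * 60,
                "sex": ["F"] * 60,
            }
        )
        spec = ModelSpec("mass", "gaussian", ("host",))
        priors = PriorSpec(V=1.0, nu=4.0)
        settings = MCMCSettings(iterations=42_000, burnin=2000, thin=40,
                                seed=4)
        draws = fit_gaussian_lmm(table, spec, priors=priors,
                                 settings=settings,
                                 fixed_variances={"residual": 1e10})
        x = draws.params["var_host"].to_numpy()
        # prior: IG(shape=nu/2, scale=nu*V/2) = IG(2, 2)
        ks = stats.kstest(x, stats.invgamma(2.0, scale=2.0).cdf)
        assert ks.pvalue > 0.001

    def test_zero_variance_response_aborts(self):
        table = pure_intercept_table(np.full(50, 5.0))
        with pytest.raises(ValueError, match="zero variance"):
            fit_gaussian_lmm(table, ModelSpec("mass", "gaussian", ()),
                             settings=MCMCSettings(100, 10, seed=0))

    def test_single_level_term_aborts(self):
        rng = np.random.default_rng(5)
        table = pure_intercept_table(rng.standard_normal(50))
        with pytest.raises(ValueError, match="single level"):
            fit_gaussian_lmm(table, ModelSpec("mass", "gaussian", ("host",)),
                             settings=MCMCSettings(100, 10, seed=0))

    def test_matches_reml_on_one_way_layout(self):
        """Posterior mean of a well-identified variance component should
        land near the REML estimate from an independent fitter."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n_groups, per = 15, 40
        u = rng.standard_normal(n_groups) * 2.0
        y = 10 + np.repeat(u, per) + rng.standard_normal(n_groups * per)
        table = pd.DataFrame(
            {
                "pupal_mass_mg": y,
                "host": np.repeat([f"h{i:02d}" for i in range(n_groups)], per),
                "population": ["p1", "p2"] * (n_groups * per // 2),
                "culture": ["c1"] * n_groups * per,
                "sex": ["F"] * n_groups * per,
            }
        )
        spec = ModelSpec("mass", "gaussian", ("host",))
        settings = MCMCSettings(iterations=4000, burnin=1000, thin=3, seed=7)
        draws = fit_gaussian_lmm(table, spec, settings=settings)
        ours = draws.params["var_host"].mean()
        groups = table["host"]
        md = sm.MixedLM(y, np.ones_like(y), groups=groups).fit(reml=True)
        reml = float(np.asarray(md.cov_re)[0, 0])
        assert ours == pytest.approx(reml, rel=0.35)


class TestBinarySampler:
    def test_beta_binomial_limit(self):
        """With the fixed residual shrunk toward zero, a pure-intercept fit
        must agree with the conjugate Beta(1,1)-binomial posterior."""
        y = np.zeros(300)
        y[:90] = 1.0
        spec = ModelSpec("survival", "binary-logit", ())
        priors = PriorSpec(fixed_residual=0.04)
        settings = MCMCSettings(iterations=30_000, burnin=10_000, thin=20,
                                seed=8)
        draws = fit_binary_glmm(pure_intercept_table(y), spec, priors,
                                settings)
        p_draws = expit(draws.intercept())
        beta_mean = (90 + 1) / (300 + 2)
        assert p_draws.mean() == pytest.approx(beta_mean, abs=0.015)

    def test_posterior_predictive_matches_data_proportion(self, fixtures,
                                                          strong_fit):
        """Marginal posterior-predictive survival (integrating the fixed
        residual by quadrature) should match the observed proportion."""
        table = fixtures["strong_host"]
        draws = strong_fit
        nodes, weights = np.polynomial.hermite_e.hermegauss(21)
        weights = weights / weights.sum()
        mu = np.array(draws.intercept())[:, None] + 0.0
        for term in draws.spec.random_terms:
            vals = (table[term] if ":" not in term
                    else table["population"].astype(str) + ":" + table["host"])
            idx = {lv: j for j, lv in enumerate(draws.levels[term])}
            codes = vals.map(idx).to_numpy()
            mu = mu + draws.group_effect_matrix(term)[:, codes]
        sd = np.sqrt(draws.params["var_residual"].to_numpy())[:, None]
        pred = sum(w * expit(mu + z * sd) for z, w in zip(nodes, weights))
        grand = pred.mean()
        obs = table["survived"].mean()
        se = np.sqrt(obs * (1 - obs) / len(table))
        assert abs(grand - obs) < 3 * se + 0.02

    def test_non_binary_response_rejected(self):
        t = pure_intercept_table(np.array([0.0, 1.0, 2.0] * 20))
        with pytest.raises(ValueError, match="binary"):
            fit_binary_glmm(t, ModelSpec("survival", "binary-logit", ()),
                            settings=MCMCSettings(100, 10, seed=0))

    def test_degenerate_response_rejected(self):
        t = pure_intercept_table(np.ones(40))
        with pytest.raises(ValueError, match="constant"):
            fit_binary_glmm(t, ModelSpec("survival", "binary-logit", ()),
                            settings=MCMCSettings(100, 10, seed=0))

    def test_residual_held_fixed(self, strong_fit):
        assert (strong_fit.params["var_residual"] == 1.0).all()


class TestDeterminismAndSerialisation:
    def test_identical_draws_for_identical_seed(self, fixtures):
        settings = MCMCSettings(iterations=600, burnin=100, thin=2, seed=21)
        a = fit_binary_glmm(fixtures["small"], ModelSpec.survival(),
                            settings=settings)
        b = fit_binary_glmm(fixtures["small"], ModelSpec.survival(),
                            settings=settings)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_draws_roundtrip(self, strong_fit, tmp_path):
        prefix = tmp_path / "surv"
        strong_fit.save(prefix)
        loaded = ha.PosteriorDraws.load(prefix)
        pd.testing.assert_frame_equal(loaded.params, strong_fit.params)
        assert loaded.spec == strong_fit.spec
        assert loaded.levels == strong_fit.levels
        assert loaded.settings == strong_fit.settings


class TestModelSpecRules:
    def test_sex_excluded_outside_mass(self):
        with pytest.raises(ValueError, match="sex"):
            ModelSpec("survival", "binary-logit", ("host", "sex"))

    def test_table_specs(self):
        assert "sex" in ModelSpec.mass().random_terms
        assert "sex" not in ModelSpec.survival().random_terms
        assert "sex" not in ModelSpec.devtime().random_terms

    def test_family_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_lmm(pure_intercept_table(np.arange(20.0)),
                             ModelSpec.survival())
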