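"""Metropolis-within-Gibbs sampler for the three-level logistic model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cslink.hierarchical import (
    McmcConfig,
    ModelSpec,
    PosteriorChain,
    PriorSpec,
    ThreeLevelLogisticModel,
    dic,
    gibbs_variance_draw,
    log_posterior,
    model_ladder,
    summarize_posterior,
)
from cslink.simulate import SimulationConfig, simulate_population


def _toy_data(rng, n=50, n_clusters=5, n_regions=2):
    cluster = rng.integers(0, n_clusters, n)
    return pd.DataFrame(
        {
            "caesarean": rng.integers(0, 2, n),
            "education": rng.integers(0, 2, n),
            "age": rng.random(n),
            "cluster_id": [f"C{c}" for c in cluster],
            "region_id": [f"R{c % n_regions}" for c in cluster],
        }
    )


def _chain_stub(model, beta_draws, deviance):
    beta_draws = np.asarray(beta_draws, dtype=float)
    n = len(beta_draws)
    return PosteriorChain(
        beta=beta_draws,
        beta_names=model.spec.fixed_effect_names,
        u=np.zeros((n, model.n_clusters)),
        v=np.zeros((n, model.n_regions)),
        a={},
        b={},
        sigma2_cluster=np.ones(n),
        sigma2_region=np.ones(n),
        sigma2_a={},
        sigma2_b={},
        deviance=np.asarray(deviance, dtype=float),
        cluster_ids=model.cluster_ids,
        region_ids=model.region_ids,
        acceptance={},
        config=McmcConfig(n_iter=max(n, 2), burn_in=0 if n > 1 else 0, thin=1)
        if n > 1
        else McmcConfig(n_iter=2, burn_in=1, thin=1),
    )


class TestLogPosterior:
    def _params(self, rng, spec, n_clusters, n_regions):
        return {
            "beta": {name: rng.normal() for name in spec.fixed_effect_names},
            "u": rng.normal(size=n_clusters),
            "v": rng.normal(size=n_regions),
            "a": {cov: rng.normal(size=n_clusters) for cov in spec.random_slopes},
            "b": {cov: rng.normal(size=n_regions) for cov in spec.random_slopes},
            "sigma2_cluster": 0.8,
            "sigma2_region": 1.3,
            "sigma2_a": {cov: 0.5 for cov in spec.random_slopes},
            "sigma2_b": {cov: 0.6 for cov in spec.random_slopes},
        }

    def test_empty_data_reduces_to_log_prior(self):
        spec = ModelSpec(level1_covariates=["education"])
        priors = PriorSpec()
        params = {
            "beta": {"intercept": 1.0, "education": -0.5},
            "u": [],
            "v": [],
            "sigma2_cluster": 2.0,
            "sigma2_region": 3.0,
            "sigma2_a": {},
            "sigma2_b": {},
            "a": {},
            "b": {},
        }
        lp = log_posterior(params, pd.DataFrame(), spec, priors)
        expected = (
            stats.norm.logpdf(1.0, 0, np.sqrt(1000))
            + stats.norm.logpdf(-0.5, 0, np.sqrt(1000))
            + stats.invgamma.logpdf(2.0, 0.01, scale=0.01)
            + stats.invgamma.logpdf(3.0, 0.01, scale=0.01)
        )
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_single_observation_likelihood_is_log_half_at_zero(self):
        spec = ModelSpec()
        priors = PriorSpec()
        data = pd.DataFrame({"caesarean": [1], "cluster_id": ["C0"], "region_id": ["R0"]})
        params = {
            "beta": {"intercept": 0.0},
            "u": np.zeros(1),
            "v": np.zeros(1),
            "sigma2_cluster": 1.0,
            "sigma2_region": 1.0,
            "sigma2_a": {},
            "sigma2_b": {},
            "a": {},
            "b": {},
        }
        with_data = log_posterior(params, data, spec, priors)
        prior_only = log_posterior(
            params | {"u": [], "v": []}, pd.DataFrame(), spec, priors
        ) + 2 * stats.norm.logpdf(0.0, 0, 1.0)
        assert with_data - prior_only == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_term_by_term_summation_oracle(self, rng):
        data = _toy_data(rng)
        spec = ModelSpec(level1_covariates=["education", "age"], random_slopes=["age"])
        priors = PriorSpec()
        cluster_ids = np.unique(data["cluster_id"])
        region_ids = np.unique(data["region_id"])
        params = self._params(rng, spec, len(cluster_ids), len(region_ids))
        lp = log_posterior(params, data, spec, priors)

        # brute-force oracle: per-term log densities summed in a plain loop
        expected = 0.0
        for name in spec.fixed_effect_names:
            expected += stats.norm.logpdf(params["beta"][name], 0, np.sqrt(1000))
        for key in ("sigma2_cluster", "sigma2_region"):
            expected += stats.invgamma.logpdf(params[key], 0.01, scale=0.01)
        for cov in spec.random_slopes:
            expected += stats.invgamma.logpdf(params["sigma2_a"][cov], 0.01, scale=0.01)
            expected += stats.invgamma.logpdf(params["sigma2_b"][cov], 0.01, scale=0.01)
            for val in params["a"][cov]:
                expected += stats.norm.logpdf(val, 0, np.sqrt(params["sigma2_a"][cov]))
            for val in params["b"][cov]:
                expected += stats.norm.logpdf(val, 0, np.sqrt(params["sigma2_b"][cov]))
        for val in params["u"]:
            expected += stats.norm.logpdf(val, 0, np.sqrt(params["sigma2_cluster"]))
        for val in params["v"]:
            expected += stats.norm.logpdf(val, 0, np.sqrt(params["sigma2_region"]))
        for _, row in data.iterrows():
            c = list(cluster_ids).index(row["cluster_id"])
            r = list(region_ids).index(row["region_id"])
            eta = (
                params["beta"]["intercept"]
                + params["beta"]["education"] * row["education"]
                + params["beta"]["age"] * row["age"]
                + row["age"] * (params["a"]["age"][c] + params["b"]["age"][r])
                + params["u"][c]
                + params["v"][r]
            )
            p = 1 / (1 + np.exp(-eta))
            expected += np.log(p) if row["caesarean"] else np.log(1 - p)
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_variance_is_rejected(self):
        spec = ModelSpec()
        params = {
            "beta": {"intercept": 0.0},
            "u": [],
            "v": [],
            "sigma2_cluster": 0.0,
            "sigma2_region": 1.0,
            "sigma2_a": {},
            "sigma2_b": {},
            "a": {},
            "b": {},
        }
        assert log_posterior(params, pd.DataFrame(), spec, PriorSpec()) == -np.inf


class TestChainAccounting:
    def test_default_retained_draw_count(self):
        """Burn-in-then-thin accounting gives floor((175000-25000)/25)
        = 6000 retained draws with the full-scale defaults."""
        assert McmcConfig().retained == 6000

    def test_total_mode_retains_7000(self):
        """Thinning the whole chain (including burn-in) gives 175000/25
        = 7000, the accounting some software reports."""
        assert McmcConfig(count_mode="total").retained == 7000

    def test_retained_iterations_match_count(self):
        for cfg in (McmcConfig(), McmcConfig(count_mode="total"), McmcConfig(n_iter=107, burn_in=13, thin=7)):
            assert len(cfg.retained_iterations()) == cfg.retained

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="thin"):
            McmcConfig(thin=0)


class TestSampler:
    def test_prior_only_run_recovers_prior_moments(self):
        """With no observations the posterior is the prior: beta draws
        match Normal(0, 1000) moments and the inverse-gamma variance
        draws match the IG(0.01, 0.01) quantiles (its mean is undefined,
        so quantiles are compared on the log scale)."""
        spec = ModelSpec(level1_covariates=["education"])
        model = ThreeLevelLogisticModel(pd.DataFrame(), spec)
        res = model.fit(PriorSpec(), McmcConfig(n_iter=20_000, burn_in=4_000, thin=4, seed=11))
        beta = res.chain.beta
        sd = np.sqrt(1000)
        for j in range(2):
            assert beta[:, j].mean() == pytest.approx(0.0, abs=3.0)
            assert beta[:, j].std() == pytest.approx(sd, rel=0.12)
            lo, hi = np.quantile(beta[:, j], [0.025, 0.975])
            assert lo == pytest.approx(-1.96 * sd, rel=0.15)
            assert hi == pytest.approx(1.96 * sd, rel=0.15)
        for draws in (res.chain.sigma2_cluster, res.chain.sigma2_region):
            for q in (0.25, 0.5, 0.75):
                theoretical = stats.invgamma.ppf(q, 0.01, scale=0.01)
                assert np.log(np.quantile(draws, q)) == pytest.approx(np.log(theoretical), abs=5.0)

    def test_identical_seed_reproduces_chain(self, rng):
        data = _toy_data(rng, n=120)
        spec = ModelSpec(level1_covariates=["education"])
        cfg = McmcConfig(n_iter=1200, burn_in=200, thin=2, seed=5)
        a = ThreeLevelLogisticModel(data, spec).fit(PriorSpec(), cfg)
        b = ThreeLevelLogisticModel(data, spec).fit(PriorSpec(), cfg)
        np.testing.assert_array_equal(a.chain.beta, b.chain.beta)
        np.testing.assert_array_equal(a.chain.u, b.chain.u)
        np.testing.assert_array_equal(a.chain.sigma2_cluster, b.chain.sigma2_cluster)
        np.testing.assert_array_equal(a.chain.deviance, b.chain.deviance)

    def test_separation_warns_but_fits(self, rng):
        data = _toy_data(rng, n=80)
        data["caesarean"] = data["education"]  # perfect prediction
        with pytest.warns(UserWarning, match="perfectly predicts"):
            model = ThreeLevelLogisticModel(data, ModelSpec(level1_covariates=["education"]))
        res = model.fit(PriorSpec(), McmcConfig(n_iter=600, burn_in=100, thin=1, seed=2))
        assert np.isfinite(res.chain.beta).all()

    def test_acceptance_rates_adapt_into_target_band(self, rng):
        data = _toy_data(rng, n=200)
        res = ThreeLevelLogisticModel(data, ModelSpec(level1_covariates=["education"])).fit(
            PriorSpec(), McmcConfig(n_iter=4000, burn_in=2000, thin=2, seed=3)
        )
        acc = res.chain.acceptance
        assert np.all((acc["beta"] > 0.1) & (acc["beta"] < 0.6))
        assert 0.1 < acc["u"] < 0.6
        assert 0.1 < acc["v"] < 0.6

    def test_recovers_planted_effect_at_small_scale(self):
        """Single-replicate recovery smoke test: a strong education
        effect lands inside its 95% credible interval."""
        config = SimulationConfig(
            n_regions=4,
            clusters_per_region=25,
            women_per_cluster=12,
            fixed_effects={"intercept": -1.5, "education": 1.2},
            sigma2_cluster=0.3,
            sigma2_region=0.3,
            distance_effect=0.0,
            slope_variances={},
            n_facilities=10,
            n_caesarean_facilities=8,
            seed=17,
        )
        ds = simulate_population(config)
        res = ThreeLevelLogisticModel(ds.women_table, ModelSpec(level1_covariates=["education"])).fit(
            PriorSpec(), McmcConfig(n_iter=6000, burn_in=2000, thin=2, seed=17)
        )
        s = res.summary().set_index("parameter")
        assert s.loc["beta_education", "ci_lower"] < 1.2 < s.loc["beta_education", "ci_upper"]


class TestGibbsVarianceStep:
    def test_draws_match_analytic_inverse_gamma_conditional(self):
        """Given fixed random effects, the sampled variance follows the
        conjugate InverseGamma(shape + m/2, scale + SS/2) exactly."""
        rng = np.random.default_rng(8)
        effects = rng.normal(0, 1.4, size=60)
        priors = PriorSpec()
        draws = gibbs_variance_draw(rng, effects, priors, size=40_000)
        shape = priors.ig_shape + 30.0
        scale = priors.ig_scale + 0.5 * (effects**2).sum()
        qs = np.linspace(0.02, 0.98, 25)
        sampled_q = np.quantile(draws, qs)
        analytic_q = stats.invgamma.ppf(qs, shape, scale=scale)
        np.testing.assert_allclose(sampled_q, analytic_q, rtol=0.05)
        ks = stats.kstest(draws, lambda x: stats.invgamma.cdf(x, shape, scale=scale))
        assert ks.pvalue > 0.001


class TestSummaries:
    def test_constant_chain_collapses_interval(self, rng):
        model = ThreeLevelLogisticModel(_toy_data(rng), ModelSpec(level1_covariates=["education"]))
        chain = _chain_stub(model, np.full((150, 2), 1.7), np.full(150, 3.0))
        s = summarize_posterior(chain).set_index("parameter")
        assert s.loc["beta_intercept", ["mean", "ci_lower", "ci_upper"]].tolist() == pytest.approx([1.7, 1.7, 1.7])

    def test_normal_draws_give_normal_quantiles(self, rng):
        model = ThreeLevelLogisticModel(_toy_data(rng), ModelSpec(level1_covariates=["education"]))
        draws = np.random.default_rng(4).normal(size=(10_000, 2))
        chain = _chain_stub(model, draws, np.zeros(10_000))
        s = summarize_posterior(chain).set_index("parameter")
        assert s.loc["beta_intercept", "ci_lower"] == pytest.approx(-1.96, abs=0.08)
        assert s.loc["beta_intercept", "ci_upper"] == pytest.approx(1.96, abs=0.08)

    def test_odds_ratio_interval_is_exponentiated_coefficient_interval(self, rng):
        model = ThreeLevelLogisticModel(_toy_data(rng), ModelSpec(level1_covariates=["education"]))
        draws = np.random.default_rng(4).normal(0.5, 0.2, size=(2000, 2))
        chain = _chain_stub(model, draws, np.zeros(2000))
        s = summarize_posterior(chain).set_index("parameter")
        row = s.loc["beta_education"]
        assert row["or_lower"] == pytest.approx(np.exp(row["ci_lower"]))
        assert row["or_upper"] == pytest.approx(np.exp(row["ci_upper"]))
        assert row["or_lower"] < row["or"] < row["or_upper"]

    def test_too_few_draws_rejected(self, rng):
        model = ThreeLevelLogisticModel(_toy_data(rng), ModelSpec(level1_covariates=["education"]))
        chain = _chain_stub(model, np.zeros((50, 2)), np.zeros(50))
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(chain)


class TestDic:
    def test_degenerate_chain_has_zero_effective_parameters(self, rng):
        data = _toy_data(rng, n=40)
        model = ThreeLevelLogisticModel(data, ModelSpec(level1_covariates=["education"]))
        eta = np.zeros(len(data))
        dev = -2 * (data["caesarean"] @ eta - len(data) * np.log(2.0))
        chain = _chain_stub(model, np.zeros((150, 2)), np.full(150, dev))
        dic_val, p_eff, dbar, dhat = dic(chain, model)
        assert p_eff == pytest.approx(0.0, abs=1e-9)
        assert dic_val == pytest.approx(dhat, abs=1e-9)

    def test_two_draw_chain_matches_hand_arithmetic(self):
        data = pd.DataFrame({"caesarean": [1, 0], "cluster_id": ["A", "A"], "region_id": ["X", "X"]})
        model = ThreeLevelLogisticModel(data, ModelSpec())
        # draws beta0 = 0 and 2; deviances computed by hand
        d1 = -2 * (2 * np.log(0.5))
        d2 = -2 * (2.0 - 2 * np.log1p(np.exp(2.0)))
        chain = _chain_stub(model, np.array([[0.0], [2.0]]), np.array([d1, d2]))
        dic_val, p_eff, dbar, dhat = dic(chain, model)
        assert dbar == pytest.approx((d1 + d2) / 2)
        expected_dhat = -2 * (1.0 - 2 * np.log1p(np.exp(1.0)))  # at posterior mean beta0=1
        assert dhat == pytest.approx(expected_dhat, abs=1e-12)
        assert p_eff == pytest.approx(dbar - expected_dhat, abs=1e-12)
        assert dic_val == pytest.approx(expected_dhat + 2 * (dbar - expected_dhat), abs=1e-12)

    def test_single_draw_rejected(self, rng):
        model = ThreeLevelLogisticModel(_toy_data(rng), ModelSpec(level1_covariates=["education"]))
        chain = _chain_stub(model, np.zeros((1, 2)), np.zeros(1))
        with pytest.raises(ValueError, match="2 retained"):
            dic(chain, model)


class TestModelLadder:
    @pytest.fixture(scope="class")
    def null_world(self):
        config = SimulationConfig(
            n_regions=8,
            clusters_per_region=12,
            women_per_cluster=10,
            fixed_effects={"intercept": -1.0, "education": 0.0, "age": 0.0},
            sigma2_cluster=0.8,
            sigma2_region=0.8,
            distance_effect=0.0,
            slope_variances={},
            n_facilities=10,
            n_caesarean_facilities=8,
            seed=23,
        )
        return simulate_population(config)

    def test_ladder_table_structure_and_null_pcv(self, null_world):
        """Four models, the full variance-table column set, and near-zero
        explained variance when no covariate truly matters."""
        spec = ModelSpec(
            level1_covariates=["education", "age"],
            level2_covariate="distance_scaled",
            random_slopes=["education"],
        )
        results, table = model_ladder(
            null_world.women_table,
            spec,
            PriorSpec(),
            McmcConfig(n_iter=3000, burn_in=1000, thin=2, seed=31),
        )
        assert len(results) == 4 and len(table) == 4
        for col in ("sigma2_C", "sigma2_R", "ICC_C_pct", "ICC_R_pct", "PCV_C_pct", "PCV_R_pct", "DIC"):
            assert col in table.columns
        assert "slope_var_education_cluster" in table.columns
        # nothing to explain: no systematic variance reduction (bounds
        # reflect posterior-mean noise at this desk scale, where the
        # region variance rests on only 8 groups)
        assert abs(table.loc[1, "PCV_C_pct"]) < 40.0
        assert abs(table.loc[1, "PCV_R_pct"]) < 50.0

    def test_planted_distance_effect_raises_cluster_pcv(self):
        """A strong cluster-level distance effect is only absorbed once
        the level-2 covariate enters (Model 3 vs Model 1)."""
        config = SimulationConfig(
            n_regions=4,
            clusters_per_region=22,
            women_per_cluster=12,
            fixed_effects={"intercept": -0.5, "education": 0.0},
            sigma2_cluster=0.05,
            sigma2_region=0.2,
            distance_effect=-3.5,
            slope_variances={},
            n_facilities=12,
            n_caesarean_facilities=4,
            seed=29,
        )
        ds = simulate_population(config)
        spec = ModelSpec(level1_covariates=["education"], level2_covariate="distance_scaled")
        _, table = model_ladder(
            ds.women_table, spec, PriorSpec(), McmcConfig(n_iter=4000, burn_in=1500, thin=2, seed=37)
        )
        assert table.loc[3, "PCV_C_pct"] > table.loc[1, "PCV_C_pct"]

    def test_ladder_failure_names_model(self, rng):
        data = _toy_data(rng, n=30)
        data.loc[:, "caesarean"] = 2  # invalid outcome
        with pytest.raises(RuntimeError, match="Model 0"):
            model_ladder(data, ModelSpec(level1_covariates=["education"]))
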