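"""Three-level Bayesian hierarchical logistic regression.

Women (level 1) nest in survey clusters (level 2) nest in regions
(level 3).  The outcome is Bernoulli with

    logit P(y_ij = 1) = x_ij' beta + u_c(ij) + v_r(ij)
                        + sum_k x_ij,k (a_k,c(ij) + b_k,r(ij))

where u, v are cluster/region random intercepts and a_k, b_k optional
random slopes, all independent normals with their own variances.  Priors
follow the weakly-informative convention of the motivating analysis:
Normal(0, 1000) on each fixed effect and InverseGamma(0.01, 0.01) on
every variance component.

The posterior is explored with Metropolis-within-Gibbs: component-wise
adaptive random-walk Metropolis for the fixed effects, blocked (per
cluster / per region, exploiting conditional independence) random-walk
Metropolis for the random effects, and conjugate inverse-gamma Gibbs
draws for the variances.  Step sizes adapt only during burn-in so the
post-burn-in chain is a fixed-kernel Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from cslink.variance import VarianceComponents, icc_three_level, build_variance_table

LEVEL1_DEFAULT = ["education", "wealth_rich", "anc_1_3", "anc_4plus", "age", "parity", "age_first_birth"]


@dataclass
class ModelSpec:
    """What enters the three-level logistic model.

    ``random_slopes`` lists level-1 covariates whose effects vary across
    clusters and regions (independent variances per covariate per level,
    no slope-intercept correlation).
    """

    outcome: str = "caesarean"
    level1_covariates: list = field(default_factory=list)
    level2_covariate: str | None = None
    random_slopes: list = field(default_factory=list)
    cluster_col: str = "cluster_id"
    region_col: str = "region_id"

    def __post_init__(self) -> None:
        extra = set(self.random_slopes) - set(self.level1_covariates)
        if extra:
            raise ValueError(f"random slopes {sorted(extra)} are not level-1 covariates")

    @property
    def fixed_effect_names(self) -> list:
        names = ["intercept", *self.level1_covariates]
        if self.level2_covariate:
            names.append(self.level2_covariate)
        return names


@dataclass
class PriorSpec:
    """Normal prior on fixed effects, inverse-gamma on variances."""

    beta_mean: float = 0.0
    beta_var: float = 1000.0
    ig_shape: float = 0.01
    ig_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.beta_var <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("prior variance and inverse-gamma parameters must be > 0")


@dataclass
class McmcConfig:
    """Chain length, thinning, and adaptation settings.

    ``count_mode`` controls retained-draw accounting: ``"post_burnin"``
    discards burn-in first and then thins (floor((n_iter - burn_in)/thin)
    draws); ``"total"`` thins the whole chain including burn-in
    (n_iter/thin draws), an alternative accounting some software reports.
    """

    n_iter: int = 175_000
    burn_in: int = 25_000
    thin: int = 25
    seed: int = 0
    adapt_window: int = 50
    target_accept: tuple[float, float] = (0.2, 0.5)
    count_mode: str = "post_burnin"

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.count_mode not in ("post_burnin", "total"):
            raise ValueError("count_mode must be 'post_burnin' or 'total'")

    @classmethod
    def test_scale(cls, seed: int = 0, **kwargs) -> "McmcConfig":
        """Reduced chain (15,000 / 5,000 / thin 5) for desk-scale runs."""
        return cls(n_iter=15_000, burn_in=5_000, thin=5, seed=seed, **kwargs)

    @property
    def retained(self) -> int:
        if self.count_mode == "total":
            return self.n_iter // self.thin
        return (self.n_iter - self.burn_in) // self.thin

    def retained_iterations(self) -> np.ndarray:
        """Iteration indices kept: every ``thin``-th draw of the relevant
        range, so the count matches :attr:`retained` exactly."""
        if self.count_mode == "total":
            return np.arange(self.thin - 1, self.n_iter, self.thin)
        return np.arange(self.burn_in + self.thin - 1, self.n_iter, self.thin)


@dataclass
class PosteriorChain:
    """Retained MCMC draws of every model parameter.

    ``beta`` is (draws, p) in ``beta_names`` order; ``u``/``v`` are
    (draws, n_clusters)/(draws, n_regions); slope draws are keyed by
    covariate.  ``deviance`` holds -2 log-likelihood per retained draw.
    """

    beta: np.ndarray
    beta_names: list
    u: np.ndarray
    v: np.ndarray
    a: dict
    b: dict
    sigma2_cluster: np.ndarray
    sigma2_region: np.ndarray
    sigma2_a: dict
    sigma2_b: dict
    deviance: np.ndarray
    cluster_ids: np.ndarray
    region_ids: np.ndarray
    acceptance: dict
    config: McmcConfig

    @property
    def n_draws(self) -> int:
        return len(self.beta)

    def scalar_draws(self) -> pd.DataFrame:
        """Fixed effects, variances and deviance as one tidy frame."""
        data = {f"beta_{name}": self.beta[:, j] for j, name in enumerate(self.beta_names)}
        data["sigma2_cluster"] = self.sigma2_cluster
        data["sigma2_region"] = self.sigma2_region
        for cov, draws in self.sigma2_a.items():
            data[f"sigma2_slope_{cov}_cluster"] = draws
        for cov, draws in self.sigma2_b.items():
            data[f"sigma2_slope_{cov}_region"] = draws
        data["deviance"] = self.deviance
        return pd.DataFrame(data)


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def gibbs_variance_draw(rng: np.random.Generator, effects: np.ndarray, priors: PriorSpec, size: int | None = None):
    """Conjugate draw of a random-effect variance given its effects.

    The full conditional of sigma^2 under a Normal(0, sigma^2) likelihood
    for ``m`` effects and an InverseGamma(shape, scale) prior is
    InverseGamma(shape + m/2, scale + sum(effects^2)/2); an inverse-gamma
    variate is the scale divided by a Gamma(shape, 1) variate.
    """
    effects = np.asarray(effects, dtype=float)
    shape = priors.ig_shape + 0.5 * effects.size
    scale = priors.ig_scale + 0.5 * (effects**2).sum()
    return scale / rng.gamma(shape, size=size)


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Bernoulli-logit log-likelihood terms, underflow-safe."""
    return float(y @ eta - _softplus(eta).sum())


def log_posterior(params: dict, data: pd.DataFrame, spec: ModelSpec, priors: PriorSpec) -> float:
    """Unnormalised log posterior at a parameter point.

    ``params`` holds ``beta`` (dict name -> value), ``u`` / ``v`` arrays
    aligned with the sorted cluster/region ids in ``data``, optional
    slope dicts ``a`` / ``b``, and variances ``sigma2_cluster``,
    ``sigma2_region`` plus ``sigma2_a`` / ``sigma2_b`` dicts.  With empty
    data the likelihood term vanishes and only the priors remain.
    """
    for key in ("sigma2_cluster", "sigma2_region"):
        if params[key] <= 0:
            return -np.inf
    lp = 0.0
    beta = params["beta"]
    for name in spec.fixed_effect_names:
        lp += stats.norm.logpdf(beta[name], priors.beta_mean, np.sqrt(priors.beta_var))
    lp += stats.invgamma.logpdf(params["sigma2_cluster"], priors.ig_shape, scale=priors.ig_scale)
    lp += stats.invgamma.logpdf(params["sigma2_region"], priors.ig_shape, scale=priors.ig_scale)
    u = np.asarray(params.get("u", []), dtype=float)
    v = np.asarray(params.get("v", []), dtype=float)
    lp += stats.norm.logpdf(u, 0.0, np.sqrt(params["sigma2_cluster"])).sum()
    lp += stats.norm.logpdf(v, 0.0, np.sqrt(params["sigma2_region"])).sum()
    for cov in spec.random_slopes:
        s2a = params["sigma2_a"][cov]
        s2b = params["sigma2_b"][cov]
        if s2a <= 0 or s2b <= 0:
            return -np.inf
        lp += stats.invgamma.logpdf(s2a, priors.ig_shape, scale=priors.ig_scale)
        lp += stats.invgamma.logpdf(s2b, priors.ig_shape, scale=priors.ig_scale)
        lp += stats.norm.logpdf(np.asarray(params["a"][cov]), 0.0, np.sqrt(s2a)).sum()
        lp += stats.norm.logpdf(np.asarray(params["b"][cov]), 0.0, np.sqrt(s2b)).sum()

    if len(data) == 0:
        return float(lp)

    y, X, cluster_idx, region_idx, _, _ = _design(data, spec)
    eta = X @ np.array([beta[name] for name in spec.fixed_effect_names])
    if len(u):
        eta = eta + u[cluster_idx]
    if len(v):
        eta = eta + v[region_idx]
    for cov in spec.random_slopes:
        xk = data[cov].to_numpy(dtype=float)
        eta = eta + xk * (np.asarray(params["a"][cov])[cluster_idx] + np.asarray(params["b"][cov])[region_idx])
    return float(lp + bernoulli_loglik(y, eta))


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Outcome vector, fixed-effect design matrix and group index arrays."""
    if len(data):
        y = data[spec.outcome].to_numpy(dtype=float)
        cols = [np.ones(len(data))]
        for cov in spec.level1_covariates:
            cols.append(data[cov].to_numpy(dtype=float))
        if spec.level2_covariate:
            cols.append(data[spec.level2_covariate].to_numpy(dtype=float))
        X = np.column_stack(cols)
    else:
        y = np.zeros(0)
        X = np.zeros((0, len(spec.fixed_effect_names)))
    if len(data):
        cluster_ids, cluster_idx = np.unique(data[spec.cluster_col].to_numpy(), return_inverse=True)
        region_ids, region_idx = np.unique(data[spec.region_col].to_numpy(), return_inverse=True)
    else:
        cluster_ids = region_ids = np.array([])
        cluster_idx = region_idx = np.zeros(0, dtype=int)
    return y, X, cluster_idx, region_idx, cluster_ids, region_ids


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance band."""

    def __init__(self, n: int, initial: float, low: float, high: float):
        self.log_s = np.full(n, np.log(initial))
        self.target = 0.5 * (low + high)
        self.accepted = np.zeros(n)
        self.proposed = np.zeros(n)

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self) -> None:
        with np.errstate(invalid="ignore"):
            rate = np.where(self.proposed > 0, self.accepted / np.maximum(self.proposed, 1), self.target)
        self.log_s += 0.66 * (rate - self.target)
        self.log_s = np.clip(self.log_s, np.log(1e-4), np.log(50.0))
        self.accepted[:] = 0
        self.proposed[:] = 0


class ThreeLevelLogisticModel:
    """Model object binding data to a :class:`ModelSpec`.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per woman with the outcome, covariates and the cluster /
        region id columns named in the spec.
    spec : ModelSpec
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        missing = [
            c
            for c in (spec.outcome, *spec.level1_covariates, spec.cluster_col, spec.region_col)
            if len(data) and c not in data.columns
        ]
        if spec.level2_covariate and len(data) and spec.level2_covariate not in data.columns:
            missing.append(spec.level2_covariate)
        if missing:
            raise KeyError(f"data lacks columns {missing}")
        self.data = data
        self.spec = spec
        (self.y, self.X, self.cluster_idx, self.region_idx, self.cluster_ids, self.region_ids) = _design(data, spec)
        if len(data):
            outcome_values = set(np.unique(self.y).tolist())
            if not outcome_values <= {0.0, 1.0}:
                raise ValueError("outcome must be binary 0/1")
            if outcome_values in ({0.0}, {1.0}):
                warnings.warn("outcome is constant; the posterior is driven by the prior")
            self._check_separation()
        self.n_clusters = len(self.cluster_ids)
        self.n_regions = len(self.region_ids)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec | None = None, **spec_kwargs) -> "ThreeLevelLogisticModel":
        if spec is None:
            spec = ModelSpec(**spec_kwargs)
        return cls(data, spec)

    def _check_separation(self) -> None:
        for cov in self.spec.level1_covariates:
            x = self.data[cov].to_numpy(dtype=float)
            if set(np.unique(x).tolist()) <= {0.0, 1.0}:
                for level in (0.0, 1.0):
                    sub = self.y[x == level]
                    if len(sub) > 0 and (sub.min() == sub.max()) and len(sub) < len(self.y):
                        warnings.warn(
                            f"covariate {cov!r} perfectly predicts the outcome at level {level:g}; "
                            "the proper priors regularise the fit"
                        )
                        return

    # ------------------------------------------------------------------
    def fit(
        self,
        priors: PriorSpec | None = None,
        mcmc: McmcConfig | None = None,
        center: bool = True,
    ) -> "ThreeLevelLogisticResults":
        """Run the Metropolis-within-Gibbs sampler.

        ``center=True`` recentres the *stored* draws (sum-to-zero of each
        random-effect block within its parent, with the removed means
        pushed up one level); the transformation leaves every linear
        predictor, hence the likelihood and deviance, unchanged, and the
        live sampler state is untouched.
        """
        priors = priors or PriorSpec()
        mcmc = mcmc or McmcConfig()
        chain = self._run_sampler(priors, mcmc, center)
        return ThreeLevelLogisticResults(self, chain, priors, mcmc)

    def _run_sampler(self, priors: PriorSpec, mcmc: McmcConfig, center: bool) -> PosteriorChain:
        rng = np.random.default_rng(mcmc.seed)
        spec = self.spec
        y, X = self.y, self.X
        n_obs = len(y)
        p = X.shape[1]
        C, R = self.n_clusters, self.n_regions
        cluster_idx, region_idx = self.cluster_idx, self.region_idx
        slope_covs = list(spec.random_slopes)
        xk = {cov: self.data[cov].to_numpy(dtype=float) if n_obs else np.zeros(0) for cov in slope_covs}

        beta = np.zeros(p)
        u = np.zeros(C)
        v = np.zeros(R)
        a = {cov: np.zeros(C) for cov in slope_covs}
        b = {cov: np.zeros(R) for cov in slope_covs}
        s2_u, s2_v = 1.0, 1.0
        s2_a = {cov: 1.0 for cov in slope_covs}
        s2_b = {cov: 1.0 for cov in slope_covs}

        eta = X @ beta if n_obs else np.zeros(0)
        sp = _softplus(eta)
        yX = X.T @ y if n_obs else np.zeros(p)

        beta_scale = _AdaptiveScale(p, 0.1, *mcmc.target_accept)
        u_scale = _AdaptiveScale(1, 0.5, *mcmc.target_accept)
        v_scale = _AdaptiveScale(1, 0.5, *mcmc.target_accept)
        a_scale = {cov: _AdaptiveScale(1, 0.5, *mcmc.target_accept) for cov in slope_covs}
        b_scale = {cov: _AdaptiveScale(1, 0.5, *mcmc.target_accept) for cov in slope_covs}

        retain_iter = mcmc.retained_iterations()
        retain_set = np.zeros(mcmc.n_iter, dtype=bool)
        retain_set[retain_iter] = True
        n_keep = len(retain_iter)

        out_beta = np.empty((n_keep, p))
        out_u = np.empty((n_keep, C))
        out_v = np.empty((n_keep, R))
        out_a = {cov: np.empty((n_keep, C)) for cov in slope_covs}
        out_b = {cov: np.empty((n_keep, R)) for cov in slope_covs}
        out_s2u = np.empty(n_keep)
        out_s2v = np.empty(n_keep)
        out_s2a = {cov: np.empty(n_keep) for cov in slope_covs}
        out_s2b = {cov: np.empty(n_keep) for cov in slope_covs}
        out_dev = np.empty(n_keep)

        prior_prec = 1.0 / priors.beta_var

        def group_metropolis(effect, group_idx, n_groups, s2, scale_obj, multiplier=None):
            """One blocked RW-Metropolis sweep over conditionally
            independent group effects (clusters or regions)."""
            nonlocal eta, sp
            step = scale_obj.scale[0]
            delta = rng.normal(0.0, step, size=n_groups)
            log_unif = np.log(rng.random(n_groups))
            if n_obs:
                d_eta = delta[group_idx] if multiplier is None else delta[group_idx] * multiplier
                eta_new = eta + d_eta
                sp_new = _softplus(eta_new)
                dlik = np.bincount(group_idx, weights=y * d_eta - sp_new + sp, minlength=n_groups)
            else:
                dlik = np.zeros(n_groups)
            new_effect = effect + delta
            dprior = (effect**2 - new_effect**2) / (2.0 * s2)
            accept = log_unif < dlik + dprior
            effect[accept] = new_effect[accept]
            if n_obs and accept.any():
                acc_obs = accept[group_idx]
                eta = np.where(acc_obs, eta_new, eta)
                sp = np.where(acc_obs, sp_new, sp)
            scale_obj.proposed[0] += n_groups
            scale_obj.accepted[0] += accept.sum()
            return effect

        keep = 0
        for it in range(mcmc.n_iter):
            # --- fixed effects: component-wise RW Metropolis
            for j in range(p):
                step = beta_scale.scale[j]
                d = rng.normal(0.0, step)
                new_bj = beta[j] + d
                dprior = ((beta[j] - priors.beta_mean) ** 2 - (new_bj - priors.beta_mean) ** 2) * 0.5 * prior_prec
                if n_obs:
                    eta_new = eta + d * X[:, j]
                    sp_new = _softplus(eta_new)
                    dlik = d * yX[j] - sp_new.sum() + sp.sum()
                else:
                    dlik = 0.0
                beta_scale.proposed[j] += 1
                if np.log(rng.random()) < dlik + dprior:
                    beta[j] = new_bj
                    if n_obs:
                        eta, sp = eta_new, sp_new
                    beta_scale.accepted[j] += 1

            # --- random intercepts (blocked over groups)
            if C:
                u = group_metropolis(u, cluster_idx, C, s2_u, u_scale)
            if R:
                v = group_metropolis(v, region_idx, R, s2_v, v_scale)
            # --- random slopes
            for cov in slope_covs:
                if C:
                    a[cov] = group_metropolis(a[cov], cluster_idx, C, s2_a[cov], a_scale[cov], xk[cov])
                if R:
                    b[cov] = group_metropolis(b[cov], region_idx, R, s2_b[cov], b_scale[cov], xk[cov])

            # --- conjugate inverse-gamma Gibbs steps for variances
            s2_u = gibbs_variance_draw(rng, u, priors)
            s2_v = gibbs_variance_draw(rng, v, priors)
            for cov in slope_covs:
                s2_a[cov] = gibbs_variance_draw(rng, a[cov], priors)
                s2_b[cov] = gibbs_variance_draw(rng, b[cov], priors)

            # --- adaptation (burn-in only, preserves post-burn-in ergodicity)
            if it < mcmc.burn_in and (it + 1) % mcmc.adapt_window == 0:
                beta_scale.update()
                u_scale.update()
                v_scale.update()
                for cov in slope_covs:
                    a_scale[cov].update()
                    b_scale[cov].update()

            if retain_set[it]:
                out_beta[keep] = beta
                out_u[keep] = u
                out_v[keep] = v
                for cov in slope_covs:
                    out_a[cov][keep] = a[cov]
                    out_b[cov][keep] = b[cov]
                out_s2u[keep] = s2_u
                out_s2v[keep] = s2_v
                for cov in slope_covs:
                    out_s2a[cov][keep] = s2_a[cov]
                    out_s2b[cov][keep] = s2_b[cov]
                out_dev[keep] = -2.0 * bernoulli_loglik(y, eta) if n_obs else 0.0
                keep += 1

        if center and C and R:
            self._center_draws(out_beta, out_u, out_v, out_a, out_b)

        acceptance = {
            "beta": beta_scale.accepted / np.maximum(beta_scale.proposed, 1),
            "u": float(u_scale.accepted[0] / max(u_scale.proposed[0], 1)),
            "v": float(v_scale.accepted[0] / max(v_scale.proposed[0], 1)),
        }
        return PosteriorChain(
            beta=out_beta,
            beta_names=spec.fixed_effect_names,
            u=out_u,
            v=out_v,
            a=out_a,
            b=out_b,
            sigma2_cluster=out_s2u,
            sigma2_region=out_s2v,
            sigma2_a=out_s2a,
            sigma2_b=out_s2b,
            deviance=out_dev,
            cluster_ids=self.cluster_ids,
            region_ids=self.region_ids,
            acceptance=acceptance,
            config=mcmc,
        )

    def _center_draws(self, out_beta, out_u, out_v, out_a, out_b) -> None:
        """Sum-to-zero recentring of stored random-effect draws.

        Cluster effects are centred within their region, the removed
        means added to the region effect; region effects are centred
        overall, the mean added to the corresponding fixed effect.  The
        per-draw linear predictor is invariant under this map.
        """
        region_of_cluster = np.empty(self.n_clusters, dtype=int)
        region_of_cluster[self.cluster_idx] = self.region_idx
        names = self.spec.fixed_effect_names

        def center_pair(eff_c, eff_r, beta_col):
            for r in range(self.n_regions):
                members = region_of_cluster == r
                if members.any():
                    m = eff_c[:, members].mean(axis=1)
                    eff_c[:, members] -= m[:, None]
                    eff_r[:, r] += m
            grand = eff_r.mean(axis=1)
            eff_r -= grand[:, None]
            out_beta[:, beta_col] += grand

        center_pair(out_u, out_v, names.index("intercept"))
        for cov in self.spec.random_slopes:
            center_pair(out_a[cov], out_b[cov], names.index(cov))


def summarize_posterior(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior mean and equal-tail 95% credible interval per parameter.

    Fixed effects additionally get odds-ratio-scale (exponentiated)
    columns; the exponential is monotone, so the OR interval is the
    exponentiated coefficient interval.
    """
    if chain.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    draws = chain.scalar_draws().drop(columns="deviance")
    rows = []
    for name, col in draws.items():
        x = col.to_numpy()
        lo, hi = np.quantile(x, [0.025, 0.975])
        row = {"parameter": name, "mean": x.mean(), "ci_lower": lo, "ci_upper": hi}
        if name.startswith("beta_"):
            row.update({"or": np.exp(x.mean()), "or_lower": np.exp(lo), "or_upper": np.exp(hi)})
        rows.append(row)
    return pd.DataFrame(rows)


def dic(chain: PosteriorChain, model: ThreeLevelLogisticModel) -> tuple[float, float, float, float]:
    """Deviance information criterion from the retained chain.

    Dbar is the mean posterior deviance, Dhat the deviance at the
    posterior means of all parameters, pD = Dbar - Dhat the effective
    parameter count, and DIC = Dhat + 2 pD.
    """
    if chain.n_draws < 2:
        raise ValueError("DIC requires at least 2 retained draws")
    dbar = float(chain.deviance.mean())
    beta_mean = chain.beta.mean(axis=0)
    eta = model.X @ beta_mean
    if model.n_clusters:
        eta = eta + chain.u.mean(axis=0)[model.cluster_idx]
    if model.n_regions:
        eta = eta + chain.v.mean(axis=0)[model.region_idx]
    for cov in model.spec.random_slopes:
        xkv = model.data[cov].to_numpy(dtype=float)
        eta = eta + xkv * (chain.a[cov].mean(axis=0)[model.cluster_idx] + chain.b[cov].mean(axis=0)[model.region_idx])
    dhat = -2.0 * bernoulli_loglik(model.y, eta)
    pd_eff = dbar - dhat
    return dhat + 2.0 * pd_eff, pd_eff, dbar, dhat


class ThreeLevelLogisticResults:
    """Posterior summaries, variance components and DIC for a fit."""

    def __init__(self, model: ThreeLevelLogisticModel, chain: PosteriorChain, priors: PriorSpec, mcmc: McmcConfig):
        self.model = model
        self.chain = chain
        self.priors = priors
        self.mcmc = mcmc

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self.chain)

    def dic(self) -> tuple[float, float, float, float]:
        return dic(self.chain, self.model)

    @property
    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(
            sigma2_C=float(self.chain.sigma2_cluster.mean()),
            sigma2_R=float(self.chain.sigma2_region.mean()),
        )

    def icc(self) -> tuple[float, float]:
        return icc_three_level(self.variance_components, "latent_logistic")

    def slope_variance_means(self) -> dict:
        return {
            cov: (float(self.chain.sigma2_a[cov].mean()), float(self.chain.sigma2_b[cov].mean()))
            for cov in self.model.spec.random_slopes
        }


def ladder_specs(full_spec: ModelSpec) -> list[ModelSpec]:
    """The four-model ladder: empty, +fixed effects, +random slopes,
    +level-2 covariate."""
    empty = replace(full_spec, level1_covariates=[], level2_covariate=None, random_slopes=[])
    m1 = replace(full_spec, level2_covariate=None, random_slopes=[])
    m2 = replace(full_spec, level2_covariate=None)
    return [empty, m1, m2, full_spec]


def model_ladder(
    data: pd.DataFrame,
    full_spec: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> tuple[list[ThreeLevelLogisticResults], pd.DataFrame]:
    """Fit the model ladder and assemble the variance/ICC/PCV/DIC table.

    Models are fitted in order (the empty model first, as the PCV
    reference); a failure aborts with the failing model named.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    results = []
    ladder_entries = []
    for i, spec in enumerate(ladder_specs(full_spec)):
        try:
            res = ThreeLevelLogisticModel(data, spec).fit(priors, replace(mcmc, seed=mcmc.seed + i))
        except Exception as exc:  # noqa: BLE001 - annotate which rung failed
            raise RuntimeError(f"model ladder failed at Model {i}: {exc}") from exc
        results.append(res)
        vc = res.variance_components
        ladder_entries.append(
            {
                "model": f"Model {i}",
                "model_index": i,
                "sigma2_C": vc.sigma2_C,
                "sigma2_R": vc.sigma2_R,
                "slope_variances": res.slope_variance_means(),
                "dic": res.dic()[0],
            }
        )
    return results, build_variance_table(ladder_entries)
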