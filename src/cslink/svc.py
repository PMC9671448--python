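"""Moran-eigenvector spatially varying coefficient (SNVC) regression.

Cluster-level caesarean counts are first Gaussianised (log transform,
optionally followed by a sinh-arcsinh ("SAL") adjustment of skew and
tail weight), then regressed on cluster covariates in a linear mixed
model whose coefficients may vary over space:

    y* = X b + sum_k diag(x_k) E gamma_k + sum_k x_k o delta_k + eps

E holds the leading Moran eigenvectors of the doubly-centred proximity
matrix exp(-d_ij / r) (positive eigenvalues only, i.e. positively
autocorrelated map patterns), gamma_k ~ N(0, tau_k^2 Lambda(alpha_k))
gives the spatially varying part with eigenvalue-graded shrinkage, and
delta_k ~ N(0, psi_k^2 I) the non-spatial coefficient heterogeneity.
Variance parameters are estimated by restricted maximum likelihood with
the residual variance profiled out; constant coefficients b are reported
with GLS standard errors, t- and p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class EigenBasis:
    """Retained Moran eigenvectors and eigenvalues.

    Columns of ``vectors`` are orthonormal and centred (each sums to
    zero); ``values`` are the matching positive eigenvalues in
    decreasing order.  ``kernel_range`` is the exponential-decay range r
    of the proximity kernel.
    """

    vectors: np.ndarray
    values: np.ndarray
    kernel_range: float
    retention_threshold: float

    @property
    def n_components(self) -> int:
        return self.vectors.shape[1]


def moran_eigenvectors(coords: np.ndarray, retention_fraction: float = 0.25) -> EigenBasis:
    """Eigenbasis of the doubly-centred exponential proximity matrix.

    C_ij = exp(-d_ij / r) with r the maximum nearest-neighbour distance
    (zero diagonal); the eigenvectors of M C M (M = I - 11'/n) with
    eigenvalue above ``retention_fraction`` of the largest are retained.
    Those eigenvectors are the classic Moran map patterns: large
    eigenvalues correspond to smooth, positively autocorrelated fields.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3 or len(np.unique(coords, axis=0)) < 3:
        raise ValueError("need at least 3 distinct locations")
    d = squareform(pdist(coords))
    nn = np.where(d > 0, d, np.inf).min(axis=1)
    r = float(nn[np.isfinite(nn)].max())
    c = np.exp(-d / r)
    np.fill_diagonal(c, 0.0)
    m = np.eye(n) - 1.0 / n
    eigval, eigvec = np.linalg.eigh(m @ c @ m)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval / eigval[0] > retention_fraction
    keep &= eigval > 0
    if not keep.any():
        raise ValueError("no positive spatial structure: no eigenvector retained")
    return EigenBasis(
        vectors=eigvec[:, keep],
        values=eigval[keep],
        kernel_range=r,
        retention_threshold=retention_fraction,
    )


# ---------------------------------------------------------------------------
# response transformation


@dataclass
class TransformSpec:
    """How to Gaussianise per-cluster caesarean counts.

    ``log_gaussian``: y* = log(count + offset).  ``sal``: the log step
    followed by a sinh-arcsinh adjustment z = sinh(tail * asinh((y - loc)
    / scale) - skew); parameters are fitted by maximum likelihood unless
    supplied.
    """

    mode: str = "log_gaussian"
    offset: float = 0.5
    location: float | None = None
    scale: float | None = None
    skew: float | None = None
    tail: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("log_gaussian", "sal"):
            raise ValueError(f"unknown transform mode {self.mode!r}")


@dataclass
class CountTransform:
    """A fitted monotone transform with its inverse."""

    values: np.ndarray
    spec: TransformSpec
    params: dict = field(default_factory=dict)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.spec.mode == "sal":
            loc, scale = self.params["location"], self.params["scale"]
            skew, tail = self.params["skew"], self.params["tail"]
            y = loc + scale * np.sinh((np.arcsinh(z) + skew) / tail)
        else:
            y = z
        return np.exp(y) - self.spec.offset


def _sal_negloglik(theta: np.ndarray, y: np.ndarray) -> float:
    loc, log_scale, skew, log_tail = theta
    scale, tail = np.exp(log_scale), np.exp(log_tail)
    w = (y - loc) / scale
    # overflow during optimizer exploration maps to -inf likelihood
    with np.errstate(over="ignore"):
        z = np.sinh(tail * np.arcsinh(w) - skew)
        log_jac = np.log(tail) - log_scale + 0.5 * np.log1p(z**2) - 0.5 * np.log1p(w**2)
        ll = stats.norm.logpdf(z) + log_jac
    total = ll.sum()
    return -float(total) if np.isfinite(total) else 1e12


def transform_counts(counts: np.ndarray, births: np.ndarray | None, spec: TransformSpec | None = None) -> CountTransform:
    """Gaussianise caesarean counts for the spatial regression.

    Counts must be non-negative; ``births`` is accepted for interface
    symmetry (an exposure covariate is handled in the regression design,
    not inside the transform).
    """
    spec = spec or TransformSpec()
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    y = np.log(counts + spec.offset)
    if spec.mode == "log_gaussian":
        return CountTransform(values=y, spec=spec, params={})

    if all(getattr(spec, name) is not None for name in ("location", "scale", "skew", "tail")):
        loc, scale, skew, tail = spec.location, spec.scale, spec.skew, spec.tail
    else:
        x0 = np.array([y.mean(), np.log(y.std() + 1e-9), 0.0, 0.0])
        res = optimize.minimize(_sal_negloglik, x0, args=(y,), method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        loc, scale, skew, tail = res.x[0], float(np.exp(res.x[1])), res.x[2], float(np.exp(res.x[3]))
    z = np.sinh(tail * np.arcsinh((y - loc) / scale) - skew)
    return CountTransform(values=z, spec=spec, params={"location": loc, "scale": scale, "skew": skew, "tail": tail})


# ---------------------------------------------------------------------------
# SNVC mixed model


class SNVCModel:
    """Spatially and non-spatially varying coefficient model.

    Parameters
    ----------
    y : array-like
        Transformed (Gaussianised) cluster-level response.
    X : pandas.DataFrame
        Cluster-level covariates; an intercept column is added unless
        ``add_intercept=False``.
    basis : EigenBasis
        Moran eigenvector basis at the same clusters (row order must
        match ``X``).
    """

    def __init__(self, y: np.ndarray, X: pd.DataFrame, basis: EigenBasis, add_intercept: bool = True):
        self.y = np.asarray(y, dtype=float)
        X = X.copy()
        if add_intercept:
            if "intercept" in X.columns:
                raise ValueError("X already has an intercept column")
            X.insert(0, "intercept", 1.0)
        self.X = X
        self.basis = basis
        if len(self.y) != len(X):
            raise ValueError("y and X lengths differ")
        if basis.vectors.shape[0] != len(X):
            raise ValueError("basis rows must match X rows")
        xmat = X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
            raise ValueError("X is rank deficient")

    def fit(
        self,
        svc_covariates: list | None = None,
        nonspatial_covariates: list | None = None,
        maxiter: int = 300,
    ) -> "SNVCResults":
        """Estimate variance parameters by profiled REML.

        ``svc_covariates`` get a spatially varying random coefficient
        (tau^2, decay exponent alpha); ``nonspatial_covariates`` get an
        i.i.d. random coefficient (psi^2).  Defaults: every design
        column for both sets (the full SNVC specification).  With both
        sets empty the model is ordinary least squares.
        """
        cols = list(self.X.columns)
        svc = cols.copy() if svc_covariates is None else list(svc_covariates)
        nsv = svc.copy() if nonspatial_covariates is None else list(nonspatial_covariates)
        for name in (*svc, *nsv):
            if name not in cols:
                raise ValueError(f"{name!r} is not a design column")

        y = self.y
        xmat = self.X.to_numpy(dtype=float)
        n, p = xmat.shape
        E, lam = self.basis.vectors, self.basis.values
        L = len(lam)
        lam_norm = lam / lam.max()

        # per-covariate building blocks of V
        ek = {k: xmat[:, cols.index(k)][:, None] * E for k in svc}
        d2 = {k: xmat[:, cols.index(k)] ** 2 for k in nsv}

        n_par = 2 * len(svc) + len(nsv)
        history: list[float] = []

        def unpack(theta):
            tau = {k: np.exp(theta[2 * i]) for i, k in enumerate(svc)}
            alpha = {k: theta[2 * i + 1] for i, k in enumerate(svc)}
            psi = {k: np.exp(theta[2 * len(svc) + j]) for j, k in enumerate(nsv)}
            return tau, alpha, psi

        def build_v0(theta):
            tau, alpha, psi = unpack(theta)
            v0 = np.eye(n)
            for k in svc:
                lam_a = lam_norm ** alpha[k]
                lam_a *= L / lam_a.sum()
                root = ek[k] * np.sqrt(tau[k] * lam_a)
                v0 += root @ root.T
            for k in nsv:
                v0[np.diag_indices(n)] += psi[k] * d2[k]
            return v0

        def reml_negloglik(theta):
            v0 = build_v0(theta)
            try:
                chol = np.linalg.cholesky(v0)
            except np.linalg.LinAlgError:
                return 1e12
            logdet_v0 = 2.0 * np.log(np.diag(chol)).sum()
            xv = np.linalg.solve(v0, xmat)
            yv = np.linalg.solve(v0, y)
            xtvx = xmat.T @ xv
            bhat = np.linalg.solve(xtvx, xv.T @ y)
            resid = y - xmat @ bhat
            quad = resid @ np.linalg.solve(v0, resid)
            if quad <= 0:
                return 1e12
            sigma2 = quad / (n - p)
            sign, logdet_xtvx = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return 1e12
            nll = 0.5 * ((n - p) * np.log(sigma2) + logdet_v0 + logdet_xtvx + (n - p))
            history.append(float(nll))
            return float(nll)

        if n_par:
            x0 = np.zeros(n_par)
            x0[0 : 2 * len(svc) : 2] = np.log(0.1)  # tau^2 / sigma^2 ratios
            x0[1 : 2 * len(svc) : 2] = 1.0  # alpha
            x0[2 * len(svc) :] = np.log(0.1)
            bounds = []
            for _ in svc:
                bounds.extend([(np.log(1e-8), np.log(1e4)), (0.0, 4.0)])
            bounds.extend([(np.log(1e-8), np.log(1e4))] * len(nsv))
            opt = optimize.minimize(
                reml_negloglik, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
            )
            if not opt.success and "ABNORMAL" in str(opt.message):
                raise RuntimeError(f"REML optimisation failed: {opt.message}; trace={history[-5:]}")
            theta = opt.x
        else:
            theta = np.zeros(0)

        # final solve at the optimum
        v0 = build_v0(theta)
        xv = np.linalg.solve(v0, xmat)
        xtvx = xmat.T @ xv
        bhat = np.linalg.solve(xtvx, xv.T @ y)
        resid = y - xmat @ bhat
        sigma2 = float(resid @ np.linalg.solve(v0, resid) / (n - p)) if n > p else np.nan
        cov_b = sigma2 * np.linalg.inv(xtvx)
        se = np.sqrt(np.diag(cov_b))
        tval = bhat / se
        pval = 2 * stats.t.sf(np.abs(tval), df=n - p)

        tau, alpha, psi = unpack(theta) if n_par else ({}, {}, {})
        # BLUPs of the varying parts
        v0_inv_resid = np.linalg.solve(v0, resid)
        surfaces = {}
        gamma_hat = {}
        delta_hat = {}
        boundary = 1e-7
        for k in cols:
            surf = np.full(n, bhat[cols.index(k)])
            if k in svc and tau[k] > boundary:
                lam_a = lam_norm ** alpha[k]
                lam_a *= L / lam_a.sum()
                g = tau[k] * lam_a * (ek[k].T @ v0_inv_resid)
                gamma_hat[k] = g
                surf = surf + E @ g
            elif k in svc:
                gamma_hat[k] = np.zeros(L)
            if k in nsv and psi[k] > boundary:
                dlt = psi[k] * xmat[:, cols.index(k)] * v0_inv_resid
                delta_hat[k] = dlt
                surf = surf + dlt
            elif k in nsv:
                delta_hat[k] = np.zeros(n)
            if k in svc or k in nsv:
                surfaces[k] = surf

        reml_ll = -reml_negloglik(theta) if n_par else -reml_negloglik(np.zeros(0))
        history_arr = np.array(history)
        return SNVCResults(
            model=self,
            coef=pd.DataFrame(
                {"variable": cols, "estimate": bhat, "std_error": se, "t_value": tval, "p_value": pval}
            ),
            sigma2=sigma2,
            tau2={k: tau[k] * sigma2 for k in svc},
            alpha=alpha,
            psi2={k: psi[k] * sigma2 for k in nsv},
            surfaces=surfaces,
            gamma=gamma_hat,
            delta=delta_hat,
            reml_loglik=float(reml_ll),
            objective_trace=history_arr,
            svc_covariates=svc,
            nonspatial_covariates=nsv,
        )


@dataclass
class SNVCResults:
    """Constant coefficients, variance components and fitted surfaces."""

    model: SNVCModel
    coef: pd.DataFrame
    sigma2: float
    tau2: dict
    alpha: dict
    psi2: dict
    surfaces: dict
    gamma: dict
    delta: dict
    reml_loglik: float
    objective_trace: np.ndarray
    svc_covariates: list
    nonspatial_covariates: list

    def summary(self) -> pd.DataFrame:
        """Constant-coefficient table (estimate, SE, t, p)."""
        return self.coef.copy()

    def coefficient_surface(self, covariate: str) -> np.ndarray:
        """Per-location coefficient beta_i,k (constant + spatial BLUP +
        non-spatial deviation); constant when both variances are at the
        zero boundary."""
        if covariate in self.surfaces:
            return self.surfaces[covariate]
        cols = list(self.model.X.columns)
        return np.full(len(self.model.y), self.coef["estimate"].to_numpy()[cols.index(covariate)])

    def surface_geojson(self, coords: np.ndarray, covariates: list | None = None) -> dict:
        """Coefficient surfaces as a GeoJSON Point FeatureCollection."""
        coords = np.asarray(coords, dtype=float)
        covariates = covariates or sorted(self.surfaces)
        features = []
        for i, (x, y) in enumerate(coords):
            props = {f"beta_{k}": float(self.coefficient_surface(k)[i]) for k in covariates}
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": props,
                }
            )
        return {"type": "FeatureCollection", "features": features}


def snvc_report(fit: SNVCResults, coords: np.ndarray | None = None) -> tuple[pd.DataFrame, dict | None]:
    """Coefficient table plus (optionally) GeoJSON surface export."""
    table = fit.summary()
    geo = fit.surface_geojson(coords) if coords is not None else None
    return table, geo
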