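"""Synthetic populations, facilities, and coefficient surfaces.

The generator emulates a linked national survey design: ``n_regions``
administrative regions tile a planar study window, survey clusters fall
inside their region's tile, and women nest within clusters.  The binary
caesarean outcome is drawn from a three-level logistic model

    logit P(y=1) = x'beta + u_cluster + v_region + sum_k x_k (a_k + b_k)

with independent normal random intercepts (u, v) and optional per-
covariate random slopes (a at cluster level, b at region level).  The
realised random effects and every parameter used are returned as ground
truth, so downstream estimators can be checked against the generating
process.

Default sizes and effect magnitudes follow the national-survey scale the
package targets: 11 regions, ~622 clusters, ~11 women per cluster,
marginal caesarean prevalence near 3.65%, cluster/region intercept
variances 1.04 and 2.19 on the log-odds scale.  Continuous covariates are
carried on a min-max [0, 1] scale, under which the default log-odds
effects correspond to the adjusted odds ratios of the motivating survey
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from cslink.linkage import PointSet, link_nearest_cs_facility
from cslink.scores import INDICATOR_SETS

#: Default fixed effects (log-odds, covariates on their generated scales).
#: The intercept is calibrated so the marginal prevalence is close to the
#: 3.65% national figure under the default covariate and variance setup.
DEFAULT_FIXED_EFFECTS = {
    "intercept": -7.37,
    "education": 1.03,       # OR 2.80
    "wealth_rich": 0.59,     # OR 1.80
    "anc_1_3": 1.07,         # OR 2.91
    "anc_4plus": 1.54,       # OR 4.67
    "age": 3.34,             # OR 28.13 per min-max unit
    "parity": -3.51,         # OR 0.03 per min-max unit
    "age_first_birth": 1.98, # OR 7.27 per min-max unit
}

DEFAULT_COVARIATE_MODEL = {
    "p_education": 0.48,
    "p_wealth_rich": 0.40,
    "p_anc": (0.37, 0.31, 0.32),  # none / 1-3 / >=4 visits
    "age_range": (15.0, 49.0),
    "age_mean": 28.0,
    "age_sd": 7.0,
    "afb_range": (12.0, 35.0),
    "afb_mean": 19.0,
    "afb_sd": 3.5,
    "parity_lambda": 3.0,
    "parity_max": 12,
}

LEVEL1_COVARIATES = ["education", "wealth_rich", "anc_1_3", "anc_4plus", "age", "parity", "age_first_birth"]


@dataclass
class SvcSurfaceSpec:
    """Smooth spatial field used as a spatially varying coefficient.

    ``kind`` is ``"linear"`` (a planar gradient along ``direction``) or
    ``"gaussian_mixture"`` (sum of Gaussian bumps at ``centers`` with
    bandwidths ``widths`` and signed ``weights``); ``amplitude`` scales
    the field around ``baseline``.
    """

    kind: str = "gaussian_mixture"
    amplitude: float = 1.0
    baseline: float = 0.0
    direction: tuple[float, float] = (0.0, 1.0)
    centers: tuple = ((250.0, 250.0), (750.0, 750.0))
    widths: tuple = (200.0, 200.0)
    weights: tuple = (1.0, -1.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic linked-survey world.

    Counts may be single integers or inclusive ``(low, high)`` ranges to
    emulate unbalanced survey designs.  All variances are on the
    log-odds (latent) scale.
    """

    n_regions: int = 11
    clusters_per_region: int | tuple[int, int] = (42, 71)
    women_per_cluster: int | tuple[int, int] = (8, 14)
    spatial_extent: tuple[float, float] = (1500.0, 1000.0)
    fixed_effects: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    sigma2_region: float = 2.19
    sigma2_cluster: float = 1.04
    slope_variances: dict = field(default_factory=dict)
    covariate_model: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    n_facilities: int = 214
    n_caesarean_facilities: int = 179
    distance_effect: float = -2.12  # log-odds per min-max distance unit (OR 0.12)
    svc_surface_spec: SvcSurfaceSpec | None = None
    svc_covariate: str = "age_first_birth"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        for name in ("clusters_per_region", "women_per_cluster"):
            value = getattr(self, name)
            low = value[0] if isinstance(value, tuple) else value
            if low < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sigma2_region < 0 or self.sigma2_cluster < 0:
            raise ValueError("variances must be >= 0")
        for cov, (s2c, s2r) in self.slope_variances.items():
            if s2c < 0 or s2r < 0:
                raise ValueError(f"slope variance for {cov!r} must be >= 0")
        if self.n_facilities < 0 or self.n_caesarean_facilities < 0:
            raise ValueError("facility counts must be >= 0")
        if self.n_caesarean_facilities > self.n_facilities:
            raise ValueError("flagged facilities cannot exceed total facilities")
        if min(self.spatial_extent) <= 0:
            raise ValueError("spatial_extent must be positive")


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them."""

    women_table: pd.DataFrame
    cluster_table: pd.DataFrame
    facility_table: pd.DataFrame
    truth: dict


def _draw_count(rng: np.random.Generator, value: int | tuple[int, int], size: int) -> np.ndarray:
    if isinstance(value, tuple):
        low, high = value
        return rng.integers(low, high + 1, size=size)
    return np.full(size, int(value))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():  # resampling keeps the distribution truncated, not clipped
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _region_tiles(n_regions: int, extent: tuple[float, float]) -> list[tuple[float, float, float, float]]:
    """Partition the study window into a near-square grid of region tiles."""
    width, height = extent
    n_cols = int(np.ceil(np.sqrt(n_regions)))
    n_rows = int(np.ceil(n_regions / n_cols))
    tiles = []
    for r in range(n_regions):
        row, col = divmod(r, n_cols)
        tiles.append(
            (
                col * width / n_cols,
                (col + 1) * width / n_cols,
                row * height / n_rows,
                min(row + 1, n_rows) * height / n_rows,
            )
        )
    return tiles


def _region_of_points(x: np.ndarray, y: np.ndarray, n_regions: int, extent: tuple[float, float]) -> np.ndarray:
    width, height = extent
    n_cols = int(np.ceil(np.sqrt(n_regions)))
    n_rows = int(np.ceil(n_regions / n_cols))
    col = np.minimum((x / (width / n_cols)).astype(int), n_cols - 1)
    row = np.minimum((y / (height / n_rows)).astype(int), n_rows - 1)
    return np.minimum(row * n_cols + col, n_regions - 1)


def simulate_facilities(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Facility table: uniform locations, caesarean flags, indicator items.

    The first ``n_caesarean_facilities`` facilities (by id) carry the
    caesarean-provision flag.  Binary service indicators (6 general, 7
    availability, 9 readiness items) are driven by a latent facility
    quality score so that the indicator sets have the correlated
    structure a principal-component summary expects.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_facilities
    if config.n_caesarean_facilities == 0:
        warnings.warn("no facility provides caesarean sections; downstream linkage will fail")
    width, height = config.spatial_extent
    x = rng.uniform(0, width, size=n)
    y = rng.uniform(0, height, size=n)
    table = pd.DataFrame(
        {
            "facility_id": [f"F{i:04d}" for i in range(n)],
            "x": x,
            "y": y,
            "region_id": _region_of_points(x, y, config.n_regions, config.spatial_extent),
            "provides_caesarean": np.arange(n) < config.n_caesarean_facilities,
        }
    )
    quality = rng.normal(size=n)  # latent quality induces within-set correlation
    for cols in INDICATOR_SETS.values():
        for j, col in enumerate(cols):
            cut = rng.normal(scale=0.5)
            noise = rng.normal(scale=0.8, size=n)
            table[col] = (quality + noise > cut).astype(int)
    return table


def simulate_svc_surface(coords: np.ndarray, spec: SvcSurfaceSpec) -> np.ndarray:
    """Evaluate a smooth coefficient field at the given planar points."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise ValueError("coords must be non-empty")
    if len(coords) > 1 and np.allclose(coords, coords[0]):
        warnings.warn("all coordinates identical; returning constant field")
        return np.full(len(coords), spec.baseline)
    if spec.kind == "linear":
        d = np.asarray(spec.direction, dtype=float)
        norm = np.hypot(*d)
        if norm == 0:
            raise ValueError("linear surface needs a non-zero direction")
        proj = coords @ (d / norm)
        span = proj.max() - proj.min()
        centered = proj - proj.mean()
        field_values = centered / (span / 2) if span > 0 else np.zeros(len(coords))
    elif spec.kind == "gaussian_mixture":
        field_values = np.zeros(len(coords))
        for (cx, cy), h, w in zip(spec.centers, spec.widths, spec.weights):
            d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
            field_values += w * np.exp(-d2 / (2 * h**2))
    else:
        raise ValueError(f"unknown surface kind {spec.kind!r}")
    return spec.baseline + spec.amplitude * field_values


def _simulate_covariates(rng: np.random.Generator, n: int, model: dict) -> pd.DataFrame:
    """Women's covariates; continuous ones min-max scaled to [0, 1]."""
    lo_a, hi_a = model["age_range"]
    lo_f, hi_f = model["afb_range"]
    age = _truncated_normal(rng, model["age_mean"], model["age_sd"], lo_a, hi_a, n)
    afb = _truncated_normal(rng, model["afb_mean"], model["afb_sd"], lo_f, hi_f, n)
    parity_raw = 1 + rng.poisson(model["parity_lambda"] - 1, size=n)
    parity_raw = np.minimum(parity_raw, model["parity_max"])
    anc = rng.choice(3, size=n, p=np.asarray(model["p_anc"]) / np.sum(model["p_anc"]))
    return pd.DataFrame(
        {
            "education": rng.binomial(1, model["p_education"], size=n),
            "wealth_rich": rng.binomial(1, model["p_wealth_rich"], size=n),
            "anc_1_3": (anc == 1).astype(int),
            "anc_4plus": (anc == 2).astype(int),
            "age": (age - lo_a) / (hi_a - lo_a),
            "parity": (parity_raw - 1) / (model["parity_max"] - 1),
            "age_first_birth": (afb - lo_f) / (hi_f - lo_f),
            "age_years": age,
            "age_first_birth_years": afb,
            "parity_count": parity_raw,
        }
    )


def simulate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full linked synthetic dataset.

    Draws regions, clusters and women; simulates facilities, links each
    cluster to its nearest caesarean facility to obtain the distance
    covariate (min-max scaled); draws random intercepts and slopes; and
    samples the binary outcome from the three-level logistic model.  All
    realised random effects, the distance covariate and (optionally) the
    spatially varying coefficient field are stored in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    tiles = _region_tiles(config.n_regions, config.spatial_extent)

    n_clusters_per_region = _draw_count(rng, config.clusters_per_region, config.n_regions)
    cluster_rows = []
    for r, n_c in enumerate(n_clusters_per_region):
        x0, x1, y0, y1 = tiles[r]
        xs = rng.uniform(x0, x1, size=n_c)
        ys = rng.uniform(y0, y1, size=n_c)
        for x, y in zip(xs, ys):
            cluster_rows.append({"region_id": r, "x": x, "y": y, "urban": rng.random() < 0.25})
    cluster_table = pd.DataFrame(cluster_rows)
    cluster_table.insert(0, "cluster_id", [f"C{i:04d}" for i in range(len(cluster_table))])
    n_clusters = len(cluster_table)

    facility_table = simulate_facilities(config, rng)

    # distance covariate from linkage (min-max scaled per design)
    if config.n_caesarean_facilities > 0:
        points = PointSet.from_frame(cluster_table, "cluster_id")
        linked = link_nearest_cs_facility(points, facility_table)
        distance_km = linked["distance_km"].to_numpy()
    else:
        distance_km = np.zeros(n_clusters)
    span = distance_km.max() - distance_km.min()
    distance_scaled = (distance_km - distance_km.min()) / span if span > 0 else np.zeros(n_clusters)
    cluster_table["distance_km"] = distance_km
    cluster_table["distance_scaled"] = distance_scaled

    # random intercepts
    u = rng.normal(0.0, np.sqrt(config.sigma2_cluster), size=n_clusters)
    v = rng.normal(0.0, np.sqrt(config.sigma2_region), size=config.n_regions)

    # random slopes per covariate, cluster and region level
    slopes_cluster: dict[str, np.ndarray] = {}
    slopes_region: dict[str, np.ndarray] = {}
    for cov, (s2c, s2r) in config.slope_variances.items():
        slopes_cluster[cov] = rng.normal(0.0, np.sqrt(s2c), size=n_clusters)
        slopes_region[cov] = rng.normal(0.0, np.sqrt(s2r), size=config.n_regions)

    svc_field = None
    if config.svc_surface_spec is not None:
        coords = cluster_table[["x", "y"]].to_numpy()
        svc_field = simulate_svc_surface(coords, config.svc_surface_spec)

    n_women_per_cluster = _draw_count(rng, config.women_per_cluster, n_clusters)
    cluster_idx = np.repeat(np.arange(n_clusters), n_women_per_cluster)
    n_women = len(cluster_idx)
    region_idx = cluster_table["region_id"].to_numpy()[cluster_idx]

    covariates = _simulate_covariates(rng, n_women, config.covariate_model)

    beta = config.fixed_effects
    eta = np.full(n_women, beta.get("intercept", 0.0))
    for cov in LEVEL1_COVARIATES:
        coef = beta.get(cov, 0.0)
        x_cov = covariates[cov].to_numpy(dtype=float)
        slope = np.zeros(n_women)
        if cov in slopes_cluster:
            slope = slopes_cluster[cov][cluster_idx] + slopes_region[cov][region_idx]
        if svc_field is not None and cov == config.svc_covariate:
            slope = slope + svc_field[cluster_idx]
        eta += (coef + slope) * x_cov
    eta += config.distance_effect * distance_scaled[cluster_idx]
    eta += u[cluster_idx] + v[region_idx]

    prob = 1.0 / (1.0 + np.exp(-eta))
    outcome = rng.binomial(1, prob)

    women_table = covariates.copy()
    women_table.insert(0, "region_id", region_idx)
    women_table.insert(0, "cluster_id", cluster_table["cluster_id"].to_numpy()[cluster_idx])
    women_table.insert(0, "woman_id", [f"W{i:05d}" for i in range(n_women)])
    women_table["distance_scaled"] = distance_scaled[cluster_idx]
    women_table["caesarean"] = outcome

    truth = {
        "config": asdict(config),
        "u_cluster": u,
        "v_region": v,
        "slopes_cluster": slopes_cluster,
        "slopes_region": slopes_region,
        "svc_field": svc_field,
        "linear_predictor": eta,
        "probabilities": prob,
    }
    return SyntheticDataset(
        women_table=women_table,
        cluster_table=cluster_table,
        facility_table=facility_table,
        truth=truth,
    )
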