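"""Spatial hotspot statistics on cluster-level caesarean rates.

The pipeline follows fixed-distance-band hotspot practice: compute the
average nearest-neighbour distance to seed a distance band, confirm global
clustering with Moran's I (analytic z-test under the randomisation
assumption), scan bands of increasing radius for the distance of maximum
clustering (incremental spatial autocorrelation), then localise clusters
with the self-inclusive Getis-Ord Gi* statistic, classifying hot/cold
spots at the 90/95/99% tiers after Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

GI_CLASSES = ["cold99", "cold95", "cold90", "not significant", "hot90", "hot95", "hot99"]


@dataclass
class SpatialWeights:
    """Distance-band spatial weights.

    ``matrix[i, j] > 0`` iff ``j`` is a neighbour of ``i`` (within
    ``band_km``); the diagonal is positive only when ``include_self``.
    ``scheme`` is ``"binary"`` (w in {0,1}) or ``"row"`` (rows sum to 1).
    """

    matrix: np.ndarray
    band_km: float
    include_self: bool
    scheme: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def neighbor_counts(self) -> np.ndarray:
        off_diag = self.matrix.copy()
        np.fill_diagonal(off_diag, 0.0)
        return (off_diag > 0).sum(axis=1)


@dataclass
class MoranResult:
    """Global Moran's I with analytic randomisation inference."""

    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    n: int


def min_distance_for_neighbors(coords: np.ndarray) -> float:
    """Mean over features of the nearest-neighbour distance (km).

    The conventional starting band for a distance-band weights matrix:
    at this distance the average feature has at least one neighbour.
    Duplicate points contribute distance 0.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 points")
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def build_distance_band_weights(
    coords: np.ndarray,
    band_km: float,
    scheme: str = "binary",
    include_self: bool = False,
) -> SpatialWeights:
    """Fixed-distance-band weights: ``w_ij = 1`` iff ``d_ij <= band_km``.

    Isolated features (no neighbour within the band) are retained with a
    warning.  Row standardisation divides each row by its sum.
    """
    if band_km <= 0:
        raise ValueError("band_km must be > 0")
    if scheme not in ("binary", "row"):
        raise ValueError(f"unknown scheme {scheme!r}")
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    w = (d <= band_km).astype(float)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    isolated = int((off.sum(axis=1) == 0).sum())
    if isolated:
        warnings.warn(f"{isolated} feature(s) have no neighbour within {band_km} km")
    if scheme == "row":
        row_sums = w.sum(axis=1, keepdims=True)
        np.divide(w, row_sums, out=w, where=row_sums > 0)
    return SpatialWeights(matrix=w, band_km=band_km, include_self=include_self, scheme=scheme)


def global_morans_i(values: np.ndarray, weights: SpatialWeights) -> MoranResult:
    """Global Moran's I with z-test under the randomisation assumption.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2, with z the
    deviations from the mean.  E[I] = -1/(n-1); the variance uses the
    standard randomisation (permutation) moments, so the z-test is the
    analytic counterpart of a permutation test.
    """
    x = np.asarray(values, dtype=float)
    w = weights.matrix
    if weights.include_self and np.trace(w) > 0:
        raise ValueError("Moran's I requires weights without self-neighbours")
    n = len(x)
    if n != w.shape[0]:
        raise ValueError("values and weights dimensions differ")
    z = x - x.mean()
    m2 = (z**2).sum()
    if m2 == 0:
        raise ValueError("zero variance: values are constant")
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("all-empty weights")

    I = (n / s0) * (z @ w @ z) / m2

    # randomisation-assumption moments (Cliff & Ord)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    b2 = n * (z**4).sum() / m2**2
    var_num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var_i = var_num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zscore = (I - e_i) / np.sqrt(var_i)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(I), expected=e_i, variance=float(var_i), z=float(zscore), p_value=float(p), n=n)


def incremental_spatial_autocorrelation(
    values: np.ndarray,
    coords: np.ndarray,
    start_km: float | None = None,
    step_km: float | None = None,
    n_bands: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Moran z-score across increasing distance bands; peak = max z.

    Returns a band table (band_km, I, z, p, skipped flag) and the peak
    band distance (smallest band on ties).  Bands whose weights are
    degenerate (no neighbour pairs) are skipped with a note.
    """
    coords = np.asarray(coords, dtype=float)
    mindist = min_distance_for_neighbors(coords)
    if start_km is None:
        start_km = mindist
    elif start_km < mindist:
        warnings.warn(
            f"start_km={start_km:.3g} is below the mean nearest-neighbour distance {mindist:.3g}; "
            "some features may lack neighbours in early bands"
        )
    if step_km is None:
        step_km = start_km

    rows = []
    for b in range(n_bands):
        band = start_km + b * step_km
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = build_distance_band_weights(coords, band, scheme="binary", include_self=False)
            res = global_morans_i(values, w)
        except ValueError as exc:
            rows.append({"band_km": band, "I": np.nan, "z": np.nan, "p_value": np.nan, "note": str(exc)})
            continue
        rows.append({"band_km": band, "I": res.I, "z": res.z, "p_value": res.p_value, "note": ""})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["z"])
    if valid.empty:
        raise ValueError("no band produced a valid Moran statistic")
    peak = float(valid.loc[valid["z"].idxmax(), "band_km"])  # idxmax returns first (smallest band) on ties
    return table, peak


def getis_ord_gi_star(values: np.ndarray, weights: SpatialWeights) -> pd.DataFrame:
    """Self-inclusive Getis-Ord Gi* z-scores per feature.

    Gi* compares the weighted local sum around (and including) each
    feature with its expectation under the global mean; the z-score is

        (sum_j w_ij x_j - Xbar W_i) /
            (S sqrt((n sum_j w_ij^2 - W_i^2) / (n - 1)))

    with Xbar, S the global mean and s.d. (including i).  Features whose
    neighbourhood spans all features have an undefined (0/0) score and
    are returned as z=0 with ``saturated=True``.
    """
    x = np.asarray(values, dtype=float)
    w = weights.matrix
    if not weights.include_self or np.any(np.diag(w) == 0):
        raise ValueError("Gi* requires include_self=True weights")
    n = len(x)
    if n < 3:
        raise ValueError("Gi* requires n >= 3")
    xbar = x.mean()
    s = np.sqrt(((x - xbar) ** 2).mean())
    if s <= 1e-12 * max(1.0, np.abs(x).max()):
        s = 0.0  # constant to machine precision: all z-scores are 0
    wi = w.sum(axis=1)
    wi2 = (w**2).sum(axis=1)
    num = w @ (x - xbar)  # == sum_j w_ij x_j - xbar W_i, but exact for constant x
    inner = (n * wi2 - wi**2) / (n - 1)
    denom = s * np.sqrt(np.clip(inner, 0.0, None))
    saturated = denom <= 0
    z = np.zeros(n)
    np.divide(num, denom, out=z, where=~saturated)
    if s == 0:
        z[:] = 0.0
        saturated[:] = False
    return pd.DataFrame({"gi_z": z, "saturated": saturated})


def fdr_classify(
    z_scores: np.ndarray,
    alpha_levels: tuple[float, ...] = (0.10, 0.05, 0.01),
) -> pd.DataFrame:
    """Hot/cold-spot classes from Gi* z-scores after BH-FDR correction.

    Two-sided normal p-values are BH-adjusted; each feature is labelled
    by the smallest alpha at which it stays significant, signed by z
    (hot99/hot95/hot90 / not significant / cold90/cold95/cold99).
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        return pd.DataFrame({"gi_z": [], "p_value": [], "p_adjusted": [], "classification": []})
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    p = 2 * stats.norm.sf(np.abs(z))
    p_adj = multipletests(p, method="fdr_bh")[1]

    labels = np.full(z.shape, "not significant", dtype=object)
    tier = {0.10: "90", 0.05: "95", 0.01: "99"}
    for alpha in sorted(alpha_levels, reverse=True):  # tighter alphas overwrite looser ones
        sig = p_adj <= alpha
        suffix = tier.get(alpha, f"{100 * (1 - alpha):g}")
        labels[sig & (z > 0)] = f"hot{suffix}"
        labels[sig & (z < 0)] = f"cold{suffix}"
    return pd.DataFrame({"gi_z": z, "p_value": p, "p_adjusted": p_adj, "classification": labels})


def cluster_cs_rates(women_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster caesarean count, births, and rate.

    Clusters appear once per distinct ``cluster_id`` among the women;
    a cluster with zero recorded births cannot appear by construction,
    but zero-birth rows arising from joins are excluded with a warning.
    """
    if "cluster_id" not in women_table.columns:
        raise ValueError("women table lacks cluster_id")
    grouped = women_table.groupby("cluster_id", sort=True)["caesarean"].agg(cs_count="sum", births="count")
    zero = grouped["births"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} cluster(s) with zero births")
        grouped = grouped.loc[~zero]
    grouped["cs_rate"] = grouped["cs_count"] / grouped["births"]
    return grouped.reset_index()
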