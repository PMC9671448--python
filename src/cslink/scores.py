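"""PCA-based service availability and readiness scores for facilities.

Facility service environment is summarised by principal components of
binary/ordinal service indicators: a general-readiness set (6 dimensions:
communication equipment, external supervision, client opinion/feedback,
quality assurance, emergency transport, client latrine), an obstetric-care
availability set (7 items) and an obstetric-care readiness set (9 items).
Because indicators are mixed binary/ordinal, PCA is performed on the
correlation matrix (columns standardised), and the first two components of
each set are retained as facility scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENERAL_INDICATORS = [
    "communication_equipment",
    "external_supervision",
    "client_opinion_feedback",
    "quality_assurance",
    "emergency_transport",
    "client_latrine",
]
AVAILABILITY_INDICATORS = [f"avail_item_{i}" for i in range(1, 8)]
READINESS_INDICATORS = [f"ready_item_{i}" for i in range(1, 10)]

INDICATOR_SETS: dict[str, list[str]] = {
    "general": GENERAL_INDICATORS,
    "availability": AVAILABILITY_INDICATORS,
    "readiness": READINESS_INDICATORS,
}


@dataclass
class ScoreResult:
    """PCA decomposition of an indicator matrix.

    Attributes
    ----------
    loadings : pandas.DataFrame
        Indicator x component loading matrix (orthonormal columns).
    scores : pandas.DataFrame
        Facility x component scores (standardised data @ loadings).
    explained_variance_ratio : numpy.ndarray
        Proportion of total (correlation-scale) variance per retained
        component, in decreasing order.
    dropped_columns : list of str
        Indicator columns dropped for having zero variance.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_columns: list = field(default_factory=list)


def pca_scores(m: pd.DataFrame, n_components: int) -> ScoreResult:
    """Correlation-matrix PCA of a facility indicator matrix.

    Columns are centred and scaled to unit variance; the correlation
    matrix is eigendecomposed; scores are the standardised data projected
    on the eigenvectors.  The sign of each loading vector is fixed so its
    largest-magnitude element is positive, making results reproducible.

    Parameters
    ----------
    m : pandas.DataFrame
        Rows = facilities (index used as facility ids), columns =
        indicators.  Constant columns are dropped with a warning.
    n_components : int
        Number of leading components to retain; must not exceed the
        number of non-degenerate columns.
    """
    if len(m) < 2:
        raise ValueError("PCA requires at least 2 facilities")
    values = m.to_numpy(dtype=float)
    col_sd = values.std(axis=0, ddof=1)
    degenerate = col_sd == 0
    dropped = list(m.columns[degenerate])
    if dropped:
        warnings.warn(f"dropping constant indicator columns: {dropped}")
        m = m.loc[:, ~degenerate]
        values = values[:, ~degenerate]
        col_sd = col_sd[~degenerate]
    p = values.shape[1]
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} non-degenerate columns")

    z = (values - values.mean(axis=0)) / col_sd
    corr = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:n_components]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # reproducible sign: largest-magnitude loading element positive
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(eigvec, index=m.columns, columns=comp_names)
    scores = pd.DataFrame(z @ eigvec, index=m.index, columns=comp_names)
    return ScoreResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=np.clip(eigval, 0, None) / p,
        dropped_columns=dropped,
    )


def score_audit_tables(facilities: pd.DataFrame, indicator_sets: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Loadings and explained-variance proportions for every indicator
    set, stacked into one long table for audit output."""
    indicator_sets = indicator_sets or INDICATOR_SETS
    rows = []
    for set_name, cols in indicator_sets.items():
        block = facilities.set_index("facility_id")[cols]
        n_nondegen = int((block.to_numpy(dtype=float).std(axis=0, ddof=1) > 0).sum())
        if n_nondegen == 0:
            continue
        result = pca_scores(block, n_components=min(2, n_nondegen))
        for comp in result.loadings.columns:
            j = int(comp[2:]) - 1
            for indicator, loading in result.loadings[comp].items():
                rows.append(
                    {
                        "indicator_set": set_name,
                        "component": comp,
                        "indicator": indicator,
                        "loading": loading,
                        "explained_variance_ratio": result.explained_variance_ratio[j],
                    }
                )
    return pd.DataFrame(rows)


def build_score_set(
    facilities: pd.DataFrame,
    indicator_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Append the six PCA score columns to a facility table.

    For each indicator set (general readiness, obstetric availability,
    obstetric readiness) the first two principal components are computed
    across the supplied facilities and attached as
    ``score_<set>_pc1`` / ``score_<set>_pc2``.

    Raises a schema error naming the first missing indicator column.
    """
    indicator_sets = indicator_sets or INDICATOR_SETS
    out = facilities.copy()
    for set_name, cols in indicator_sets.items():
        missing = [c for c in cols if c not in facilities.columns]
        if missing:
            raise KeyError(f"facility table lacks indicator column {missing[0]!r} (set {set_name!r})")
        block = facilities.set_index("facility_id")[cols]
        n_nondegen = int((block.to_numpy(dtype=float).std(axis=0, ddof=1) > 0).sum())
        if n_nondegen == 0:
            # no variation at all: centred data are identically zero
            warnings.warn(f"indicator set {set_name!r} is constant across facilities; scores set to 0")
            out[f"score_{set_name}_pc1"] = 0.0
            out[f"score_{set_name}_pc2"] = 0.0
            continue
        result = pca_scores(block, n_components=min(2, n_nondegen))
        for i in (1, 2):
            comp = f"PC{i}"
            out[f"score_{set_name}_pc{i}"] = (
                result.scores[comp].to_numpy() if comp in result.scores.columns else 0.0
            )
    return out
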