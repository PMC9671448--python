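"""Euclidean buffer geolinkage of survey clusters to caesarean facilities.

Survey clusters carry projected planar coordinates (kilometres); each
cluster is joined to its nearest caesarean-providing facility by straight-
line distance.  A buffer radius flags clusters within reach of a facility;
clusters beyond the buffer keep their nearest-facility distance, which is
what enters the regression model as the continuous access covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: Default buffer radius (km).  A documented convention for linking DHS
#: clusters to facilities, not an estimate from data.
DEFAULT_BUFFER_KM = 25.0


@dataclass
class PointSet:
    """A labelled set of planar points (kilometres)."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != len(set(self.ids.tolist())):
            raise ValueError("point ids must be unique")
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x, y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id_col: str, x_col: str = "x", y_col: str = "y") -> "PointSet":
        return cls(frame[id_col].to_numpy(), frame[x_col].to_numpy(), frame[y_col].to_numpy())


class NoLinkableFacilityError(ValueError):
    """Raised when no facility carries the caesarean-provision flag."""


def euclidean_distance_matrix(a: PointSet, b: PointSet) -> np.ndarray:
    """Pairwise Euclidean distances (km) between two point sets.

    Entry ``(i, j)`` is the straight-line distance from ``a[i]`` to
    ``b[j]``; symmetric with a zero diagonal when ``a is b``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    return cdist(a.coords, b.coords)


def link_nearest_cs_facility(
    clusters: PointSet,
    facilities: pd.DataFrame,
    buffer_km: float = DEFAULT_BUFFER_KM,
) -> pd.DataFrame:
    """Assign each cluster its nearest caesarean-providing facility.

    Parameters
    ----------
    clusters : PointSet
        Cluster locations; ``ids`` become ``cluster_id`` in the output.
    facilities : pandas.DataFrame
        Must contain ``facility_id``, ``x``, ``y`` and a boolean/0-1
        ``provides_caesarean`` column.
    buffer_km : float
        Radius for the ``within_buffer`` flag.  The nearest distance is
        kept for all clusters regardless of the buffer.

    Returns
    -------
    pandas.DataFrame
        Columns ``cluster_id``, ``nearest_cs_facility_id``,
        ``distance_km``, ``within_buffer``.  Ties in distance are broken
        by the smallest facility id, so results are order-independent.
    """
    flagged = facilities.loc[facilities["provides_caesarean"].astype(bool)]
    if flagged.empty:
        raise NoLinkableFacilityError("no linkable facility: no facility provides caesarean sections")
    # sort by id so that argmin's first-hit tie-break selects the smallest id
    flagged = flagged.sort_values("facility_id", kind="stable").reset_index(drop=True)
    fac_points = PointSet.from_frame(flagged, "facility_id")
    dist = euclidean_distance_matrix(clusters, fac_points)
    nearest = dist.argmin(axis=1)
    distance_km = dist[np.arange(len(clusters)), nearest]
    return pd.DataFrame(
        {
            "cluster_id": clusters.ids,
            "nearest_cs_facility_id": fac_points.ids[nearest],
            "distance_km": distance_km,
            "within_buffer": distance_km <= buffer_km,
        }
    )


def attach_region_and_scores(
    linked: pd.DataFrame,
    cluster_table: pd.DataFrame,
    scored_facilities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join region ids (and, optionally, nearest-facility score columns)
    onto the linkage table."""
    out = linked.merge(cluster_table[["cluster_id", "region_id"]], on="cluster_id", how="left")
    if scored_facilities is not None:
        score_cols = [c for c in scored_facilities.columns if c.startswith("score_")]
        out = out.merge(
            scored_facilities[["facility_id", *score_cols]],
            left_on="nearest_cs_facility_id",
            right_on="facility_id",
            how="left",
        ).drop(columns="facility_id")
    return out


def region_distance_summary(linked: pd.DataFrame) -> pd.DataFrame:
    """Mean nearest-facility distance per region, plus the national mean.

    Regions with no clusters are simply absent (a warning is emitted when
    the region column contains missing values)."""
    if linked.empty:
        raise ValueError("linked table is empty")
    if "region_id" not in linked.columns:
        raise ValueError("linked table lacks region_id; call attach_region_and_scores first")
    if linked["region_id"].isna().any():
        warnings.warn("clusters with missing region_id omitted from summary")
        linked = linked.dropna(subset=["region_id"])
    per_region = (
        linked.groupby("region_id", sort=True)["distance_km"].mean().rename("mean_distance_km").reset_index()
    )
    national = pd.DataFrame({"region_id": ["national"], "mean_distance_km": [linked["distance_km"].mean()]})
    return pd.concat([per_region, national], ignore_index=True)
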