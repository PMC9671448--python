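"""Variance partitioning for three-level logistic mixed models.

Intra-class correlation coefficients (ICC) quantify the share of total
outcome variance attributable to the cluster and region levels.  On the
latent-response scale of a logistic model the level-1 residual follows a
standard logistic distribution with variance pi^2/3, so the three-level
ICCs are

    ICC_C = sigma_C^2 / (pi^2/3 + sigma_C^2 + sigma_R^2)
    ICC_R = sigma_R^2 / (pi^2/3 + sigma_C^2 + sigma_R^2)

An ``explicit`` mode replaces pi^2/3 with a supplied level-1 residual
variance.  The proportional change in variance (PCV) measures how much of
a level's variance a richer model explains relative to a reference model
(the empty model):  PCV = (V_ref - V_model) / V_ref.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Variance of the standard logistic distribution, the latent-scale
#: level-1 residual variance of a logit model.
LOGISTIC_VARIANCE = math.pi**2 / 3.0


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of a three-level random-intercept model.

    Parameters
    ----------
    sigma2_C : float
        Between-cluster (level 2) intercept variance.
    sigma2_R : float
        Between-region (level 3) intercept variance.
    sigma2_e : float, optional
        Level-1 residual variance; only needed for ``explicit`` ICC mode.
    """

    sigma2_C: float
    sigma2_R: float
    sigma2_e: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_C", "sigma2_R"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.sigma2_e is not None and self.sigma2_e < 0:
            raise ValueError(f"sigma2_e must be >= 0, got {self.sigma2_e}")


def icc_three_level(
    vc: VarianceComponents, residual_mode: str = "latent_logistic"
) -> tuple[float, float]:
    """Cluster- and region-level ICCs of a three-level logistic model.

    Parameters
    ----------
    vc : VarianceComponents
        The intercept variance components.
    residual_mode : {"latent_logistic", "explicit"}
        ``latent_logistic`` uses pi^2/3 as the level-1 variance (ignores
        ``vc.sigma2_e``); ``explicit`` requires ``vc.sigma2_e``.

    Returns
    -------
    (ICC_C, ICC_R) : tuple of float
        Proportions in [0, 1).
    """
    if residual_mode == "latent_logistic":
        sigma2_e = LOGISTIC_VARIANCE
    elif residual_mode == "explicit":
        if vc.sigma2_e is None:
            raise ValueError("explicit residual_mode requires sigma2_e")
        sigma2_e = vc.sigma2_e
    else:
        raise ValueError(f"unknown residual_mode {residual_mode!r}")

    denom = sigma2_e + vc.sigma2_C + vc.sigma2_R
    if denom == 0:
        raise ValueError("total variance is zero; ICC undefined")
    return vc.sigma2_C / denom, vc.sigma2_R / denom


def pcv(v_reference: float, v_model: float) -> float:
    """Proportional change in variance relative to a reference model.

    ``(v_reference - v_model) / v_reference``; negative when the richer
    model's variance grew.
    """
    if v_reference <= 0:
        raise ValueError("reference variance must be > 0 for PCV")
    return (v_reference - v_model) / v_reference


def build_variance_table(ladder_results: list[dict]) -> pd.DataFrame:
    """Assemble the per-model variance/ICC/PCV/DIC ladder table.

    Parameters
    ----------
    ladder_results : list of dict
        One entry per model in ladder order (Model 0 first).  Each dict
        must provide ``model`` (label), ``sigma2_C``, ``sigma2_R`` and
        ``dic``; it may provide ``slope_variances`` (mapping covariate ->
        (cluster variance, region variance)).

    Returns
    -------
    pandas.DataFrame
        One row per model with variances, ICC_C/ICC_R (percent), PCV
        columns referenced to the first model (the empty model; its PCV
        cells hold NaN and are formatted as "Reference" at presentation),
        and DIC.  Full precision is kept; rounding is a display concern.
    """
    if not ladder_results:
        raise ValueError("empty ladder")
    order = [entry.get("model_index", i) for i, entry in enumerate(ladder_results)]
    if order != sorted(order):
        raise ValueError("ladder must be supplied in model order (Model 0 first)")

    ref = ladder_results[0]
    rows = []
    for i, entry in enumerate(ladder_results):
        vc = VarianceComponents(entry["sigma2_C"], entry["sigma2_R"])
        icc_c, icc_r = icc_three_level(vc, "latent_logistic")
        row = {
            "model": entry.get("model", f"Model {i}"),
            "sigma2_C": vc.sigma2_C,
            "sigma2_R": vc.sigma2_R,
            "ICC_C_pct": 100.0 * icc_c,
            "ICC_R_pct": 100.0 * icc_r,
            "PCV_C_pct": np.nan if i == 0 else 100.0 * pcv(ref["sigma2_C"], vc.sigma2_C),
            "PCV_R_pct": np.nan if i == 0 else 100.0 * pcv(ref["sigma2_R"], vc.sigma2_R),
            "DIC": entry.get("dic", np.nan),
        }
        for cov, (s2c, s2r) in (entry.get("slope_variances") or {}).items():
            row[f"slope_var_{cov}_cluster"] = s2c
            row[f"slope_var_{cov}_region"] = s2r
        rows.append(row)
    return pd.DataFrame(rows)


def format_variance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy: percentages rounded to 2 decimals, PCV of the
    reference model printed as ``"Reference"``."""
    out = table.copy()
    for col in ("ICC_C_pct", "ICC_R_pct", "PCV_C_pct", "PCV_R_pct"):
        out[col] = out[col].round(2)
    out["PCV_C_pct"] = out["PCV_C_pct"].astype(object)
    out["PCV_R_pct"] = out["PCV_R_pct"].astype(object)
    out.loc[out.index[0], ["PCV_C_pct", "PCV_R_pct"]] = "Reference"
    return out
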