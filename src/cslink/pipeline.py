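"""End-to-end orchestration: simulate -> link -> score -> fit -> spatial.

A :class:`PipelineConfig` drives the stages; every stage writes its
tables under the output directory, and a JSON manifest records the
configuration hash, the global seed, per-stage seeds and timings so a
run is reproducible from the manifest alone.  All randomness flows from
one global seed: stage k uses ``numpy.random.SeedSequence([seed, k])``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cslink import io as cio
from cslink.hierarchical import McmcConfig, ModelSpec, PriorSpec, model_ladder
from cslink.linkage import PointSet, attach_region_and_scores, link_nearest_cs_facility, region_distance_summary
from cslink.scores import build_score_set, score_audit_tables
from cslink.simulate import LEVEL1_COVARIATES, SimulationConfig, simulate_population
from cslink.spatial import (
    build_distance_band_weights,
    cluster_cs_rates,
    fdr_classify,
    getis_ord_gi_star,
    global_morans_i,
    incremental_spatial_autocorrelation,
)
from cslink.svc import SNVCModel, TransformSpec, moran_eigenvectors, transform_counts
from cslink.variance import format_variance_table

logger = logging.getLogger("cslink")

STAGES = ["simulate", "link", "score", "fit", "hotspots", "svc"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "cslink_output"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    women_csv: str | None = None
    clusters_csv: str | None = None
    facilities_csv: str | None = None
    buffer_km: float = 25.0
    level1_covariates: list = field(default_factory=lambda: list(LEVEL1_COVARIATES))
    random_slopes: list = field(default_factory=list)
    level2_covariate: str = "distance_scaled"
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig.test_scale())
    priors: PriorSpec = field(default_factory=PriorSpec)
    transform_mode: str = "log_gaussian"
    svc_covariates: list | None = None
    eigen_retention: float = 0.25
    isa_bands: int = 10

    def stage_seed(self, stage: str) -> int:
        k = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0] % (2**31))

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            for key in ("clusters_per_region", "women_per_cluster", "spatial_extent"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "priors" in raw and isinstance(raw["priors"], dict):
            raw["priors"] = PriorSpec(**raw["priors"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything a run produces, with provenance."""

    descriptive: pd.DataFrame
    region_distances: pd.DataFrame | None
    posterior_summaries: dict
    variance_table: pd.DataFrame | None
    hotspot_table: pd.DataFrame | None
    hotspot_geojson: dict | None
    svc_table: pd.DataFrame | None
    svc_geojson: dict | None
    manifest: dict


def descriptive_summary(
    women: pd.DataFrame,
    clusters: pd.DataFrame,
    facilities: pd.DataFrame | None = None,
    region_population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Caesarean rates overall / by residence / by region, and hospitals
    per million population.

    Without an explicit ``region_population`` table (columns region_id,
    population) the sampled births stand in for population exposure;
    regions with zero population are flagged with a NaN ratio.
    """
    rows = [{"group": "national", "births": len(women), "cs_rate_pct": 100.0 * women["caesarean"].mean()}]
    merged = women.merge(clusters[["cluster_id", "urban"]], on="cluster_id", how="left") if "urban" in clusters else women
    if "urban" in merged:
        for flag, label in ((True, "urban"), (False, "rural")):
            sub = merged[merged["urban"] == flag]
            if len(sub):
                rows.append({"group": label, "births": len(sub), "cs_rate_pct": 100.0 * sub["caesarean"].mean()})
    for region, sub in women.groupby("region_id"):
        rows.append({"group": f"region_{region}", "births": len(sub), "cs_rate_pct": 100.0 * sub["caesarean"].mean()})
    out = pd.DataFrame(rows)

    if facilities is not None and "region_id" in facilities.columns:
        hosp = facilities.groupby("region_id").size().rename("hospitals")
        if region_population is not None:
            pop = region_population.set_index("region_id")["population"]
        else:
            pop = women.groupby("region_id").size().rename("population")
        ratio = (1e6 * hosp / pop.reindex(hosp.index)).rename("hospitals_per_million")
        ratio = ratio.replace([np.inf, -np.inf], np.nan)
        out = out.merge(
            ratio.reset_index().assign(group=lambda d: "region_" + d["region_id"].astype(str))[
                ["group", "hospitals_per_million"]
            ],
            on="group",
            how="left",
        )
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the enabled stages in order and persist all outputs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "timings_s": {},
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
    }

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["failed_stage"] = name
            cio.write_json(manifest, out_dir / "manifest.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, manifest["timings_s"][name])
        return result

    # ---------------- simulate or load
    if "simulate" in config.stages:
        def _simulate():
            sim_config = SimulationConfig(**{**asdict(config.simulation), "seed": config.stage_seed("simulate")})
            ds = simulate_population(sim_config)
            cio.write_table(ds.women_table, out_dir / "women.csv")
            cio.write_table(ds.cluster_table, out_dir / "clusters.csv")
            cio.write_table(ds.facility_table, out_dir / "facilities.csv")
            cio.write_geojson(cio.points_to_geojson(ds.cluster_table[["cluster_id", "region_id", "x", "y"]]), out_dir / "clusters.geojson")
            cio.write_geojson(
                cio.points_to_geojson(ds.facility_table[["facility_id", "provides_caesarean", "x", "y"]]),
                out_dir / "facilities.geojson",
            )
            truth = {
                "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(sim_config).items() if k != "covariate_model"},
                "u_cluster": ds.truth["u_cluster"],
                "v_region": ds.truth["v_region"],
            }
            cio.write_json(truth, out_dir / "truth.json")
            return ds

        dataset = _run_stage("simulate", _simulate)
        women, clusters, facilities = dataset.women_table, dataset.cluster_table, dataset.facility_table
    else:
        if not (config.women_csv and config.clusters_csv and config.facilities_csv):
            raise ValueError("simulate stage disabled but input CSV paths are not all set")
        women = cio.read_table(config.women_csv)
        clusters = cio.read_table(config.clusters_csv)
        facilities = cio.read_table(config.facilities_csv)

    descriptive = descriptive_summary(women, clusters, facilities)
    cio.write_table(descriptive, out_dir / "descriptive_summary.csv")

    # ---------------- geolinkage + facility scores
    linked = region_distances = None
    if "link" in config.stages:
        def _link():
            points = PointSet.from_frame(clusters, "cluster_id")
            table = link_nearest_cs_facility(points, facilities, buffer_km=config.buffer_km)
            return attach_region_and_scores(table, clusters)

        linked = _run_stage("link", _link)
        region_distances = region_distance_summary(linked)
        cio.write_table(region_distances, out_dir / "region_distances.csv")

    if "score" in config.stages:
        def _score():
            scored = build_score_set(facilities)
            cio.write_table(scored, out_dir / "facility_scores.csv")
            cio.write_table(score_audit_tables(facilities), out_dir / "facility_score_loadings.csv")
            if linked is not None:
                merged = attach_region_and_scores(linked.drop(columns="region_id"), clusters, scored)
                cio.write_table(merged, out_dir / "linked_clusters.csv")
                return merged
            return scored

        scored_result = _run_stage("score", _score)
        if linked is not None:
            linked = scored_result
    if linked is not None:
        cio.write_table(linked, out_dir / "linked_clusters.csv")

    # ---------------- hierarchical model ladder
    posterior_summaries: dict = {}
    variance_table = None
    if "fit" in config.stages:
        def _fit():
            spec = ModelSpec(
                level1_covariates=list(config.level1_covariates),
                level2_covariate=config.level2_covariate,
                random_slopes=list(config.random_slopes),
            )
            mcmc = McmcConfig(**{**asdict(config.mcmc), "seed": config.stage_seed("fit")})
            results, table = model_ladder(women, spec, config.priors, mcmc)
            return results, table

        results, variance_table = _run_stage("fit", _fit)
        for i, res in enumerate(results):
            summary = res.summary()
            posterior_summaries[f"model_{i}"] = summary
            cio.write_table(summary, out_dir / f"posterior_model{i}.csv")
        cio.write_table(format_variance_table(variance_table), out_dir / "variance_table.csv")
        # persist the final model's chain (one row per retained draw)
        cio.write_table(results[-1].chain.scalar_draws(), out_dir / "chain_final_model.csv")
        cio.write_json(
            {
                "seed": results[-1].mcmc.seed,
                "n_iter": results[-1].mcmc.n_iter,
                "burn_in": results[-1].mcmc.burn_in,
                "thin": results[-1].mcmc.thin,
                "count_mode": results[-1].mcmc.count_mode,
                "acceptance": {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in results[-1].chain.acceptance.items()
                },
            },
            out_dir / "chain_manifest.json",
        )

    # ---------------- hotspot pipeline
    hotspot_table = hotspot_geojson = None
    if "hotspots" in config.stages:
        def _hotspots():
            rates = cluster_cs_rates(women)
            rates = rates.merge(clusters[["cluster_id", "x", "y"]], on="cluster_id")
            coords = rates[["x", "y"]].to_numpy()
            values = rates["cs_rate"].to_numpy()
            isa_table, peak = incremental_spatial_autocorrelation(values, coords, n_bands=config.isa_bands)
            cio.write_table(isa_table, out_dir / "incremental_autocorrelation.csv")
            moran = global_morans_i(values, build_distance_band_weights(coords, peak))
            gi = getis_ord_gi_star(values, build_distance_band_weights(coords, peak, include_self=True))
            classified = fdr_classify(gi["gi_z"].to_numpy())
            table = pd.concat([rates.reset_index(drop=True), classified.drop(columns="gi_z"), gi], axis=1)
            table["moran_I"] = moran.I
            table["moran_z"] = moran.z
            table["peak_band_km"] = peak
            return table

        hotspot_table = _run_stage("hotspots", _hotspots)
        cio.write_table(hotspot_table, out_dir / "hotspots.csv")
        hotspot_geojson = cio.points_to_geojson(
            hotspot_table[["cluster_id", "cs_rate", "gi_z", "p_adjusted", "classification", "x", "y"]]
        )
        cio.write_geojson(hotspot_geojson, out_dir / "hotspots.geojson")

    # ---------------- SNVC spatial regression
    svc_table = svc_geojson = None
    if "svc" in config.stages:
        def _svc():
            rates = cluster_cs_rates(women)
            agg = women.groupby("cluster_id")[config.level1_covariates].mean()
            rates = rates.merge(agg, on="cluster_id").merge(clusters[["cluster_id", "x", "y", "distance_scaled"]], on="cluster_id")
            coords = rates[["x", "y"]].to_numpy()
            transform = transform_counts(
                rates["cs_count"].to_numpy(), rates["births"].to_numpy(), TransformSpec(mode=config.transform_mode)
            )
            design = rates[config.level1_covariates + ["distance_scaled"]].copy()
            design["log_births"] = np.log(rates["births"].to_numpy())  # exposure covariate
            constant = [c for c in design.columns if design[c].std(ddof=0) < 1e-12]
            if constant:  # e.g. log_births under a balanced design; collinear with the intercept
                design = design.drop(columns=constant)
            basis = moran_eigenvectors(coords, config.eigen_retention)
            svc_covs = config.svc_covariates if config.svc_covariates is not None else ["intercept"]
            fit = SNVCModel(transform.values, design, basis).fit(svc_covariates=svc_covs)
            return fit, coords

        fit, coords = _run_stage("svc", _svc)
        svc_table = fit.summary()
        cio.write_table(svc_table, out_dir / "svc_coefficients.csv")
        svc_geojson = fit.surface_geojson(coords)
        cio.write_geojson(svc_geojson, out_dir / "svc_surfaces.geojson")

    manifest["tables"] = sorted(p.name for p in out_dir.iterdir())
    cio.write_json(manifest, out_dir / "manifest.json")
    return ReportBundle(
        descriptive=descriptive,
        region_distances=region_distances,
        posterior_summaries=posterior_summaries,
        variance_table=variance_table,
        hotspot_table=hotspot_table,
        hotspot_geojson=hotspot_geojson,
        svc_table=svc_table,
        svc_geojson=svc_geojson,
        manifest=manifest,
    )
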