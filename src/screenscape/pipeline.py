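"""Pipeline orchestration, file formats and run manifests.

Every stage reads and writes plain-text formats: neighborhoods as GeoJSON
polygon features (id, population, deprivation properties), everything else
as CSV with documented headers, configuration as YAML.  ``run_all`` chains
simulate → geocode → rates → hotspots → ehsa → access → model from a single
config and records a manifest (config hash, per-stage row counts, warnings)
so a rerun with the same config is verifiably identical.  Coordinates are
planar metres throughout, so real projected data (e.g. Swiss LV95) can be
dropped in unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import shape as shapely_shape

from . import access as access_mod
from . import determinants, emerging, geocoding, hotspots, rates, synthetic

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "run_all",
    "write_neighborhoods_geojson",
    "read_neighborhoods_geojson",
    "write_csv",
    "read_invitations_csv",
]

log = logging.getLogger("screenscape")

FLOAT_FMT = "%.6f"  # writers keep 6 decimals; reports round to 1


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclasses.dataclass
class RunConfig:
    """Single-file configuration of the full pipeline.

    ``simulate`` toggles the synthetic stage; when off, the input paths must
    point at real-format files.  Every random stage derives its seed from
    ``rng_seed``.
    """

    out_dir: str = "run"
    rng_seed: int = 1
    simulate: bool = True
    # synthetic stage
    n_neighborhoods: int = 400
    n_women: int = 50000
    period_start: int = 2004
    n_periods: int = 9
    planted: str = "default"   # default | full | none
    # geocoding
    geocode_threshold: float = 0.80
    # rates
    sebs_k: int = 8
    # hotspots
    hotspot_k: int = 16
    n_perm: int = 999
    # ehsa
    spatial_k: int = 8
    temporal_window: int = 1
    fdr_alpha: float = 0.05
    trend_alpha: float = 0.05
    run_threshold: float = 0.90
    historical_threshold: float = 0.50
    # access
    access_radius: float = 5000.0
    # model
    model_n_evals: int = 16
    model_enabled: bool = True
    # real-data input paths (used when simulate is false)
    invitations_path: str | None = None
    neighborhoods_path: str | None = None
    centers_path: str | None = None
    network_nodes_path: str | None = None
    network_edges_path: str | None = None
    registry_path: str | None = None

    def validate(self) -> None:
        if self.n_periods < 2:
            raise ConfigError("n_periods must be at least 2")
        if self.period_start % 2 != 0:
            raise ConfigError("period_start must be an even year")
        if not self.simulate:
            missing = [f for f in ("invitations_path", "neighborhoods_path",
                                   "centers_path", "network_nodes_path",
                                   "network_edges_path", "registry_path")
                       if getattr(self, f) is None
                       or not Path(getattr(self, f)).exists()]
            if missing:
                raise ConfigError(f"missing input paths: {missing}")

    @property
    def period_labels(self) -> tuple:
        return tuple(range(self.period_start,
                           self.period_start + 2 * self.n_periods, 2))


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_counts: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canon = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ------------------------------------------------------------------ formats

def write_neighborhoods_geojson(neighborhoods: pd.DataFrame, path) -> None:
    feats = []
    for _, row in neighborhoods.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(row["polygon"])),
            "properties": {"neighborhood_id": int(row["neighborhood_id"]),
                           "population": int(row["population"]),
                           "deprivation": round(float(row["deprivation"]), 6)},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_neighborhoods_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError("invalid polygon geometry in feature "
                             f"{feat['properties'].get('neighborhood_id')}")
        props = feat["properties"]
        rows.append({"neighborhood_id": props["neighborhood_id"],
                     "polygon": geom, "x": geom.centroid.x,
                     "y": geom.centroid.y,
                     "population": props.get("population", 0),
                     "deprivation": props.get("deprivation", np.nan)})
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path, float_format: str = FLOAT_FMT) -> None:
    df.to_csv(path, index=False, float_format=float_format)


def read_invitations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"postal_code": str})
    bad = ~df["participated"].isin((0, 1))
    if bad.any():
        raise ValueError("participated must be 0/1; offending rows: "
                         f"{df.index[bad][:10].tolist()}")
    return df


# ------------------------------------------------------------------ run_all

def _simulate_stage(config: RunConfig, out: Path, manifest: RunManifest):
    if config.planted == "default":
        spec = synthetic.default_spec(rng_seed=config.rng_seed,
                                      n_neighborhoods=config.n_neighborhoods,
                                      n_women=config.n_women)
    elif config.planted == "full":
        spec = synthetic.full_pattern_spec(rng_seed=config.rng_seed,
                                           n_neighborhoods=config.n_neighborhoods,
                                           n_women=config.n_women)
    else:
        spec = synthetic.CantonSpec(n_neighborhoods=config.n_neighborhoods,
                                    n_women=config.n_women,
                                    rng_seed=config.rng_seed)
    spec = dataclasses.replace(spec, period_labels=config.period_labels,
                               access_radius=config.access_radius)
    canton = synthetic.simulate(spec)
    write_neighborhoods_geojson(canton.neighborhoods, out / "neighborhoods.geojson")
    write_csv(canton.centers, out / "centers.csv")
    write_csv(canton.network.nodes, out / "network_nodes.csv")
    write_csv(canton.network.edges, out / "network_edges.csv")
    write_csv(canton.registry, out / "registry.csv")
    inv = canton.invitations.drop(columns=["x", "y", "neighborhood_id", "period"])
    inv.insert(0, "invitation_id", np.arange(len(inv)))
    write_csv(inv, out / "invitations.csv")
    write_csv(canton.truth, out / "truth.csv")
    manifest.stage_counts["simulate"] = {
        "neighborhoods": len(canton.neighborhoods),
        "women": len(canton.women), "invitations": len(inv),
        "registry": len(canton.registry)}
    return canton


def run_all(config: RunConfig) -> RunManifest:
    """Execute the pipeline end to end and write all stage outputs.

    Stage order: simulate (optional) → geocode → rates → hotspots → ehsa →
    access → model.  Aborts with the failing stage named; the partial
    manifest is still written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), version=_version())
    save_config(config, out / "config.yaml")
    stage = "preflight"
    try:
        if config.simulate:
            stage = "simulate"
            _simulate_stage(config, out, manifest)
        inv_path = out / "invitations.csv" if config.simulate else config.invitations_path
        nb_path = out / "neighborhoods.geojson" if config.simulate else config.neighborhoods_path

        stage = "geocode"
        invitations = read_invitations_csv(inv_path)
        registry = geocoding.Registry(pd.read_csv(
            (out / "registry.csv") if config.simulate else config.registry_path,
            dtype={"postal_code": str, "street_number": str}))
        geocoded = geocoding.geocode_table(invitations, registry,
                                           threshold=config.geocode_threshold)
        n_failed = int((geocoded["method"] == "failed").sum())
        geocoded = geocoded[geocoded["method"] != "failed"]
        write_csv(geocoded, out / "geocoded.csv")
        manifest.stage_counts["geocode"] = {
            "rows_in": len(invitations), "matched": len(geocoded),
            "failed": n_failed}
        if n_failed:
            manifest.warnings.append(f"{n_failed} addresses failed to geocode")

        stage = "rates"
        neighborhoods = read_neighborhoods_geojson(nb_path)
        panel, stats = rates.build_panel(geocoded, neighborhoods,
                                         config.period_labels,
                                         k=config.sebs_k,
                                         rng_seed=config.rng_seed)
        write_csv(panel, out / "panel.csv")
        manifest.stage_counts["rates"] = {**stats, "cells": len(panel)}

        stage = "hotspots"
        cent = neighborhoods[["neighborhood_id", "x", "y"]]
        gi = hotspots.hotspot_analysis(panel, cent, k=config.hotspot_k,
                                       n_perm=config.n_perm,
                                       rng_seed=config.rng_seed)
        write_csv(gi, out / "gi.csv")
        manifest.stage_counts["hotspots"] = {"rows": len(gi)}

        stage = "ehsa"
        res = emerging.ehsa(panel, cent, spatial_k=config.spatial_k,
                            temporal_window=config.temporal_window,
                            alpha=config.fdr_alpha,
                            alpha_trend=config.trend_alpha,
                            run_threshold=config.run_threshold,
                            historical_threshold=config.historical_threshold)
        write_csv(res["locations"], out / "ehsa.csv")
        write_csv(res["category_period_means"], out / "ehsa_category_period.csv")
        counts = res["locations"]["category"].value_counts().to_dict()
        manifest.stage_counts["ehsa"] = {"locations": len(res["locations"]),
                                         "cube_bins": res["cube"].capacity,
                                         "categories": counts}

        stage = "access"
        network = access_mod.StreetNetwork(
            nodes=pd.read_csv((out / "network_nodes.csv") if config.simulate
                              else config.network_nodes_path),
            edges=pd.read_csv((out / "network_edges.csv") if config.simulate
                              else config.network_edges_path))
        centers = pd.read_csv((out / "centers.csv") if config.simulate
                              else config.centers_path)
        acc = access_mod.access_panel(cent, centers, network,
                                      config.period_labels,
                                      radius=config.access_radius)
        write_csv(acc, out / "access.csv")
        manifest.stage_counts["access"] = {"rows": len(acc)}

        if config.model_enabled:
            stage = "model"
            geocoded2 = geocoded.copy()
            geocoded2["period"] = rates.assign_period(
                geocoded2["invitation_year"], config.period_labels)
            feats = determinants.build_features(panel, acc, neighborhoods,
                                                geocoded2)
            model, report = determinants.tune_fit(
                feats, n_evals=config.model_n_evals, rng_seed=config.rng_seed)
            expl = determinants.shap_explain(model, feats)
            write_csv(expl["values"], out / "shap_values.csv")
            expl["importance"].rename("mean_abs_shap").to_csv(out / "importance.csv")
            (out / "metrics.json").write_text(json.dumps({
                "test_r2": report.test_r2, "test_rmse": report.test_rmse,
                "cv_rmse": report.cv_rmse, "best_params": report.best_params,
                "n_train": report.n_train, "n_test": report.n_test}, indent=2))
            manifest.stage_counts["model"] = {
                "rows": len(feats), "test_r2": round(report.test_r2, 4),
                "test_rmse": round(report.test_rmse, 4)}
    except Exception as exc:
        manifest.warnings.append(f"aborted in stage {stage}: {exc}")
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    manifest.write(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__
    return __version__
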