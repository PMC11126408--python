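"""End-to-end pipeline: MSPA → connectivity → resistance → corridors → circuits.

``run_all`` executes every stage on a scene (synthetic or loaded rasters) and
returns a bundle of intermediate grids and result tables; ``summary_tables``
extracts the five reporting tables (GI structure, patch importance, corridor
statistics, hub centrality, improvement areas).  With an output directory the
bundle is also written to disk (CSV tables, ASCII/GeoTIFF rasters, GeoJSON
corridors, and a run manifest with the configuration hash and seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuits import (
    barrier_scan,
    hub_centrality,
    improvement_area_table,
    pinchpoint_map,
)
from .corridors import (
    build_cost_graph,
    corridor_network,
    corridor_table,
    corridors_to_geojson,
    cost_distance,
)
from .grid import Grid, slope_percent, write_raster
from .mspa import class_area_table, classify, gi_mask
from .patches import (
    delta_importance,
    extract_patches,
    importance_table,
    pairwise_distances,
    PatchGraph,
    rank_and_select_hubs,
    threshold_sweep,
)
from .resistance import ResistanceFactorTable, base_resistance, slope_correct
from .synthetic import SceneParams, SyntheticScene, generate_scene

log = logging.getLogger("ginet")

DEFAULT_SWEEP = (500.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0, 7000.0)


@dataclass
class PipelineConfig:
    """Run settings; the defaults reproduce the standard analysis parameters
    (edge width 1 px, 8-connectivity, 2000 m threshold, 10 hubs, 60 m search
    radius)."""

    edge_width_px: int = 1
    connectivity: int = 8
    theta_m: float = 2000.0
    sweep_thresholds: tuple = DEFAULT_SWEEP
    run_sweep: bool = False
    n_sweep_probes: int = 6
    top_k_hubs: int = 10
    ranking_key: str = "dIIC"
    p_half: float = 0.5
    factors: ResistanceFactorTable = field(default_factory=ResistanceFactorTable)
    prune_through_hub: bool = True
    prune_triangle: bool = True
    pinch_quantile: float = 0.05
    swath_cutoff: float = 0.05
    barrier_radius_m: float = 60.0
    seed: int = 0
    stop_after: str | None = None  # stage name, e.g. "connectivity"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_thresholds"] = list(self.sweep_thresholds)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["factors"] = ResistanceFactorTable(**d["factors"])
        d["sweep_thresholds"] = tuple(d["sweep_thresholds"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_STAGES = ("mspa", "connectivity", "resistance", "corridors", "circuit", "report")


def run_all(
    config: PipelineConfig,
    scene: SyntheticScene | None = None,
    landuse: Grid | None = None,
    dem: Grid | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the pipeline and return the result bundle.

    Provide either a synthetic *scene* or *landuse* + *dem* grids; with
    neither, a default scene is generated from ``config.seed``.  Any stage
    failure aborts with the stage name and cause.
    """
    if scene is None and landuse is None:
        scene = generate_scene(SceneParams(seed=config.seed))
    if scene is not None:
        landuse, dem = scene.landuse, scene.dem
    if landuse is None or dem is None:
        raise ValueError("need landuse and dem grids (or a scene)")

    bundle: dict = {"config": config, "landuse": landuse, "dem": dem, "scene": scene}
    stop = config.stop_after
    try:
        for stage in _STAGES:
            t0 = time.perf_counter()
            _run_stage(stage, bundle, config)
            log.info("stage %-12s %6.2f s", stage, time.perf_counter() - t0)
            if stop == stage:
                break
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        _write_bundle(bundle, Path(outdir), config)
    return bundle


def _run_stage(stage: str, b: dict, cfg: PipelineConfig) -> None:
    if stage == "mspa":
        b["gi_mask"] = gi_mask(b["landuse"])
        b["mspa"] = classify(b["gi_mask"], cfg.edge_width_px, cfg.connectivity)
        b["structure"] = class_area_table(b["mspa"])
    elif stage == "connectivity":
        patches = extract_patches(b["mspa"])
        if not patches:
            raise ValueError("no core or bridge patches in the scene")
        b["patches"] = patches
        cell = b["landuse"].cell_size
        A_L = b["landuse"].values.size * b["landuse"].cell_area_ha
        d = pairwise_distances(patches, cell)
        b["distances"] = d
        if cfg.run_sweep:
            probes = [p.id for p in patches[: cfg.n_sweep_probes]]
            b["sweep"] = threshold_sweep(
                patches, A_L, list(cfg.sweep_thresholds), probes, cell, d=d,
                p_half=cfg.p_half,
            )
        graph = PatchGraph(patches=patches, A_L=A_L, d=d, theta=cfg.theta_m,
                           p_half=cfg.p_half)
        records = delta_importance(graph)
        k = min(cfg.top_k_hubs, len(records))
        b["hubs"] = rank_and_select_hubs(records, k=k, key=cfg.ranking_key)
        b["importance"] = importance_table(b["hubs"])
    elif stage == "resistance":
        slope = slope_percent(b["dem"])
        base = base_resistance(
            b["landuse"], b["mspa"], b["patches"], b["hubs"].levels,
            hubs=b["hubs"], table=cfg.factors,
        )
        b["slope"] = slope
        b["resistance_base"] = base
        b["resistance"] = slope_correct(base, slope)
    elif stage == "corridors":
        by_id = {p.id: p for p in b["patches"]}
        hub_patches = [by_id[h] for h in b["hubs"].hub_ids]
        b["hub_patches"] = hub_patches
        b["cost_graph"] = build_cost_graph(b["resistance"])
        b["cost_distances"] = {}
        b["corridors"] = corridor_network(
            hub_patches, b["resistance"],
            prune_through_hub=cfg.prune_through_hub,
            prune_triangle=cfg.prune_triangle,
            graph=b["cost_graph"], cost_distances=b["cost_distances"],
        )
        b["corridor_table"], b["corridor_summary"] = corridor_table(b["corridors"])
    elif stage == "circuit":
        if len(b["corridors"]) >= 1 and len(b["hub_patches"]) >= 2:
            b["centrality"] = hub_centrality(
                b["corridors"], [p.id for p in b["hub_patches"]]
            )
            b["pinchpoints"] = pinchpoint_map(
                b["resistance"], b["hub_patches"], b["corridors"],
                mspa_cls=b["mspa"], quantile=cfg.pinch_quantile,
                swath_cutoff=cfg.swath_cutoff,
                cost_distances=b["cost_distances"], graph=b["cost_graph"],
            )
            b["barriers"] = barrier_scan(
                b["resistance"], b["hub_patches"], b["corridors"],
                search_radius_m=cfg.barrier_radius_m,
                swath_cutoff=cfg.swath_cutoff,
                cost_distances=b["cost_distances"], graph=b["cost_graph"],
                seed=cfg.seed,
            )
            b["improvement"] = improvement_area_table(b["barriers"])
        else:
            b["centrality"] = pd.DataFrame(columns=["hub", "centrality", "level"])
            b["pinchpoints"] = None
            b["barriers"] = None
            b["improvement"] = pd.DataFrame(
                columns=["level", "region_count", "area_ha", "pct_of_improvement_area"]
            )
    elif stage == "report":
        b["tables"] = summary_tables(b)


def summary_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """The five reporting tables; every percentage column is recomputed from
    its area column and checked for self-consistency within rounding."""
    tables = {
        "gi_structure": bundle["structure"].table.reset_index(),
        "importance": bundle["importance"],
        "corridor": bundle["corridor_table"],
        "centrality": bundle["centrality"],
        "improvement": bundle["improvement"],
    }
    _check_percentages(tables)
    return tables


def _check_percentages(tables: dict[str, pd.DataFrame]) -> None:
    gs = tables["gi_structure"]
    if len(gs):
        total = gs["area_ha"].sum()
        if total > 0:
            recomputed = 100.0 * gs["area_ha"] / total
            if not np.allclose(recomputed, gs["pct_of_gi"], atol=0.51):
                raise AssertionError("gi_structure percentages inconsistent with areas")
    imp = tables["improvement"]
    if len(imp):
        total = imp["area_ha"].sum()
        recomputed = 100.0 * imp["area_ha"] / total
        if not np.allclose(recomputed, imp["pct_of_improvement_area"], atol=0.51):
            raise AssertionError("improvement percentages inconsistent with areas")


def _write_bundle(b: dict, outdir: Path, cfg: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rasters = {
        "landuse": b.get("landuse"),
        "dem": b.get("dem"),
        "mspa": b.get("mspa"),
        "slope": b.get("slope"),
        "resistance": b.get("resistance"),
    }
    if b.get("pinchpoints") is not None:
        rasters["current"] = b["pinchpoints"].current
    if b.get("barriers") is not None:
        rasters["barrier_is"] = b["barriers"].improvement
        rasters["barrier_class"] = b["barriers"].classes
    for name, grid in rasters.items():
        if grid is not None:
            write_raster(grid, outdir / f"{name}.asc", format="ascii")
    for name in ("gi_structure", "importance", "corridor", "centrality", "improvement"):
        if name in b.get("tables", {}):
            b["tables"][name].to_csv(outdir / f"{name}.csv", index=False)
    if "sweep" in b:
        b["sweep"].to_csv(outdir / "threshold_sweep.csv", index=False)
    if b.get("corridors"):
        corridors_to_geojson(b["corridors"], b["landuse"], outdir / "corridors.geojson")
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    manifest["config"]["factors"] = dataclasses.asdict(cfg.factors)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
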