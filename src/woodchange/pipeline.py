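"""End-to-end orchestration of the four analysis stages on a synthetic world:

1. harmonize + screen candidate source maps against validation samples,
2. fuse the retained sources into an accuracy-weighted ensemble and rebuild
   the multi-epoch cover series,
3. cluster coarse-cell trajectories into change archetypes,
4. overlay species ranges on cover and archetypes.

Every stage seed is derived deterministically from the config seed, so a
re-run with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import raster_io
from .archetypes import (
    build_trajectory_matrix,
    select_cluster_count,
    summarize_archetypes,
    train_som,
)
from .change import (
    AreaAccount,
    change_map,
    ecoregion_trajectory,
)
from .config import PipelineConfig
from .ensemble import SourceMap, ensemble_cover
from .errors import WoodchangeError
from .grids import (
    CoverTimeSeries,
    Grid,
    apply_persistent_nonwoodland_mask,
    block_aggregate,
)
from .megafauna import (
    composition_table,
    median_richness_per_archetype,
    richness,
    richness_cover_correlation,
    trajectory_table,
)
from .synth import (
    SourceSpec,
    SyntheticWorld,
    default_templates,
    generate_observer_samples,
    generate_source_maps,
    generate_species_ranges,
    generate_truth_series,
)
from .validation import accuracy_tables_to_csv, screen_maps, threshold_sweep

log = logging.getLogger("woodchange.pipeline")

STAGES = ("simulate", "validate", "ensemble", "change", "archetypes", "megafauna")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds, deterministic in the config seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint32)
    return {stage: int(s) for stage, s in zip(STAGES, state)}


class StageFailure(WoodchangeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def simulate_world(config: PipelineConfig) -> SyntheticWorld:
    seeds = derive_stage_seeds(config.seed)
    grid = Grid(0.0, 0.0, config.cell_size, config.n_rows, config.n_cols, "synthetic")
    templates = default_templates(config.template_noise_sd, len(config.epochs))
    series, arch_labels, eco_labels = generate_truth_series(
        templates,
        grid,
        config.epochs,
        spatial_corr_len=config.spatial_corr_len,
        seed=seeds["simulate"],
        coarse_factor=config.coarse_factor,
        n_ecoregions=config.n_ecoregions,
    )
    specs = [SourceSpec(**s) for s in config.sources]
    latest = config.epochs[-1]
    sources = generate_source_maps(series, specs, latest, seed=seeds["simulate"] + 1)
    samples = generate_observer_samples(
        series.map_for(latest),
        n=config.n_validation_samples,
        min_dist=config.validation_min_dist_cells * config.cell_size,
        obs_noise_sd=config.observer_noise_sd,
        seed=seeds["simulate"] + 2,
    )
    coarse_truth = block_aggregate(series.map_for(latest), config.coarse_factor)
    species = generate_species_ranges(
        coarse_truth,
        config.n_threatened,
        config.n_nonthreatened,
        cover_affinity=config.cover_affinity,
        seed=seeds["simulate"] + 3,
        threatened_names=config.threatened_names or None,
        nonthreatened_names=config.nonthreatened_names or None,
    )
    return SyntheticWorld(
        seed=config.seed,
        truth_series=series,
        archetype_labels=arch_labels,
        ecoregion_labels=eco_labels,
        sources=sources,
        validation=samples,
        species=species,
        coarse_factor=config.coarse_factor,
        templates=list(templates),
    )


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict[str, Any]
    summary: dict[str, Any]


def _timed(stage: str, func, *args, **kwargs):
    start = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    log.info("stage %s finished in %.2f s", stage, time.perf_counter() - start)
    return result


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages, writing every intermediate artifact plus a
    manifest and summary into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    latest = config.epochs[-1]

    # ----- stage 1a: synthetic world -------------------------------------
    world = _timed("simulate", simulate_world, config)
    world.save(outdir / "world")

    # ----- stage 1b: validation + screening ------------------------------
    def _validate():
        tables = [
            threshold_sweep(
                src.harmonized, world.validation, config.threshold_sweep, src.name
            )
            for src in world.sources
        ]
        retained = screen_maps(tables, config.oa_min, config.ua_min)
        return tables, retained

    tables, retained = _timed("validate", _validate)
    accuracy_tables_to_csv(tables, outdir / "accuracy_tables.csv")
    summary["screening"] = {
        "n_candidates": len(tables),
        "retained": [
            {"source": r.source, "best_threshold": r.best_threshold,
             "oa": r.oa, "ua": r.ua}
            for r in retained
        ],
    }
    if not retained:
        raise StageFailure("validate", WoodchangeError(
            "no source map passed screening; lower the floors or fix the sources"
        ))

    # ----- stage 1c: ensemble --------------------------------------------
    def _ensemble():
        by_name = {s.name: s for s in world.sources}
        members = [
            SourceMap(r.source, by_name[r.source].harmonized, r.ua, r.best_threshold)
            for r in retained
        ]
        ens = ensemble_cover(members, config.ensemble_mode)
        check = threshold_sweep(
            ens.cover, world.validation, config.threshold_sweep, "ensemble"
        )
        return ens, check

    ens, ens_check = _timed("ensemble", _ensemble)
    raster_io.write_geotiff(outdir / "ensemble_cover.tif", ens.cover)
    accuracy_tables_to_csv([ens_check], outdir / "ensemble_accuracy.csv")
    (outdir / "ensemble_provenance.json").write_text(json.dumps({
        "normalization_mode": ens.normalization_mode,
        "n_sources": ens.n_sources,
        "weights": ens.weights,
    }, indent=2))
    best_m = ens_check.best_matrix
    summary["ensemble"] = {
        "mode": ens.normalization_mode,
        "n_sources": ens.n_sources,
        "best_threshold": ens_check.best_threshold,
        "oa": None if best_m is None else best_m.oa,
        "ua": None if best_m is None else best_m.ua,
    }

    # ----- stage 2: series + change ---------------------------------------
    def _change():
        # the ensemble replaces the contemporary epoch; historical epochs
        # come straight from the (already harmonized) reconstruction series
        maps = [
            ens.cover.copy() if epoch == latest else truth_map.copy()
            for epoch, truth_map in zip(world.truth_series.epochs, world.truth_series.maps)
        ]
        series = CoverTimeSeries(list(world.truth_series.epochs), maps)
        series = apply_persistent_nonwoodland_mask(series, config.nonwoodland_cutoff)
        account = AreaAccount.from_series(
            series, config.area_mode, config.area_threshold_pct
        )
        full = change_map(series, config.epochs[0], latest)
        recent_start = 1995 if 1995 in config.epochs else config.epochs[-2]
        recent = change_map(series, recent_start, latest)
        eco = ecoregion_trajectory(series, world.ecoregion_labels)
        return series, account, full, recent, eco

    series, account, full_change, recent_change, eco = _timed("change", _change)
    account.to_csv(outdir / "area_account.csv")
    eco.to_csv(outdir / "ecoregion_trajectories.csv")
    import tifffile

    for tag, cm in (("full", full_change), ("recent", recent_change)):
        # change maps are plain float TIFFs (points, NaN nodata)
        arr = cm.values.astype(np.float32)
        path = outdir / f"change_{tag}_{cm.epoch_pair[0]}_{cm.epoch_pair[1]}.tif"
        tifffile.imwrite(path, arr, description=json.dumps({
            "woodchange": 1, "kind": "change_points",
            "epoch_pair": list(cm.epoch_pair), "crs_id": cm.grid.crs_id,
        }))
    summary["change"] = {
        "net_change": account.net_change,
        "net_change_pct": account.net_change_pct,
        "accounting_mode": account.accounting_mode,
    }

    # ----- stage 3: archetypes --------------------------------------------
    def _archetypes():
        seeds = derive_stage_seeds(config.seed)
        matrix = build_trajectory_matrix(
            series, config.coarse_factor, nonwoodland_cutoff=config.nonwoodland_cutoff
        )
        model = train_som(
            matrix, config.som_k, config.som_params, seed=seeds["archetypes"],
            log_every_pass=True,
        )
        diagnostics = select_cluster_count(
            matrix, config.som_k_range, config.som_params, seeds=(seeds["archetypes"],)
        )
        summary_table = summarize_archetypes(model, matrix)
        labels = matrix.labels_to_raster(model.assignments)
        return matrix, model, diagnostics, summary_table, labels

    matrix, model, diagnostics, arch_summary, arch_labels = _timed(
        "archetypes", _archetypes
    )
    raster_io.write_label_geotiff(outdir / "archetype_assignments.tif", arch_labels, matrix.grid)
    model.codebook_frame().to_csv(outdir / "som_codebook.csv", index=False)
    diagnostics.to_csv(outdir / "som_diagnostics.csv", index=False)
    if model.training_log is not None:
        model.training_log.to_csv(outdir / "som_training_log.csv", index=False)
    arch_summary.to_csv(outdir / "archetype_summary.csv")
    summary["archetypes"] = {
        "k": model.k,
        "quantization_error": model.quantization_error,
        "n_cells": matrix.n_rows,
    }

    # ----- stage 4: megafauna ---------------------------------------------
    def _megafauna():
        coarse_maps = [block_aggregate(m, config.coarse_factor) for m in series.maps]
        coarse_series = CoverTimeSeries(list(series.epochs), coarse_maps)
        coarse_cover = coarse_maps[-1]
        results: dict[str, Any] = {}
        for group in ("all", "threatened", "non_threatened"):
            rich = richness(world.species, group)
            corr = richness_cover_correlation(rich, coarse_cover)
            results[group] = {"r": corr.r, "p": corr.p, "n": corr.n}
            if group == "all":
                medians = median_richness_per_archetype(rich, arch_labels)
                results["median_richness_per_archetype"] = medians
        traj = trajectory_table(world.species, coarse_series)
        comp = composition_table(world.species, arch_labels)
        return results, traj, comp

    mega, traj, comp = _timed("megafauna", _megafauna)
    traj.to_csv(outdir / "range_cover_trajectories.csv", index=False)
    comp.to_csv(outdir / "range_archetype_composition.csv", index=False)
    summary["megafauna"] = mega

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": derive_stage_seeds(config.seed),
        "stages": list(STAGES),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return PipelineResult(outdir, manifest, summary)
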