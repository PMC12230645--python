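"""Synthetic worlds with known truth for every downstream stage.

Generates (a) spatially autocorrelated true fractional-cover surfaces per
epoch whose per-cell trajectories follow archetype templates arranged in
contiguous patches, (b) derived source maps at native resolutions with known
omission/commission error, (c) two-observer validation samples with bounded
noise, (d) ecoregion partitions, and (e) species ranges placed either in
proportion to cover ("threatened") or uniformly ("non-threatened").

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, PlacementError
from .grids import (
    BinaryMap,
    CategoricalMap,
    CoverTimeSeries,
    FractionalCoverMap,
    Grid,
    binarize_fractional,
    block_aggregate,
    nearest_resample,
)
from .megafauna import SpeciesRange
from .validation import ValidationSet

__all__ = [
    "DEFAULT_EPOCHS",
    "ArchetypeTemplate",
    "SourceSpec",
    "SyntheticWorld",
    "default_templates",
    "min_template_separation",
    "generate_truth_series",
    "generate_source_maps",
    "generate_observer_samples",
    "generate_species_ranges",
]

# Epoch years mirroring the reconstruction series the pipeline targets.
DEFAULT_EPOCHS = (1880, 1930, 1975, 1985, 1995, 2010, 2020)


@dataclass(frozen=True)
class ArchetypeTemplate:
    """A named trajectory prototype with per-epoch spread."""

    name: str
    trajectory: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectory", tuple(float(v) for v in self.trajectory))
        object.__setattr__(self, "sd", tuple(float(v) for v in self.sd))
        if len(self.trajectory) != len(self.sd):
            raise ConfigurationError("trajectory and sd must have the same length")
        if any(not 0 <= v <= 1 for v in self.trajectory):
            raise ConfigurationError("trajectory values must lie in [0, 1]")
        if any(s < 0 for s in self.sd):
            raise ConfigurationError("sd values must be non-negative")


def default_templates(noise_sd: float = 0.05, n_epochs: int = len(DEFAULT_EPOCHS)):
    """Six trajectory templates: three levels of continuous decline and three
    decline-stabilize-recover ("forest transition") shapes.

    Values are generator defaults chosen for clear mutual separation; the
    spread is a constant per-epoch ``noise_sd`` for all templates.
    """
    shapes = {
        "strongholds": (0.98, 0.95, 0.92, 0.90, 0.88, 0.86, 0.84),
        "sustained_loss": (0.86, 0.70, 0.55, 0.52, 0.50, 0.46, 0.42),
        "moderate_loss": (0.62, 0.50, 0.44, 0.42, 0.40, 0.38, 0.32),
        "steep_loss_recovery": (0.88, 0.72, 0.30, 0.22, 0.20, 0.30, 0.16),
        "broad_loss_recovery": (0.42, 0.28, 0.12, 0.10, 0.08, 0.14, 0.07),
        "low_level_recovery": (0.11, 0.10, 0.08, 0.07, 0.07, 0.10, 0.08),
    }
    templates = []
    for name, traj in shapes.items():
        if len(traj) != n_epochs:
            traj = tuple(np.interp(
                np.linspace(0, 1, n_epochs), np.linspace(0, 1, len(traj)), traj
            ))
        templates.append(ArchetypeTemplate(name, traj, (noise_sd,) * n_epochs))
    return templates


def min_template_separation(templates: Sequence[ArchetypeTemplate]) -> float:
    """Smallest pairwise L2 distance between template trajectories."""
    best = np.inf
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            d = np.linalg.norm(
                np.subtract(templates[i].trajectory, templates[j].trajectory)
            )
            best = min(best, d)
    return float(best)


@dataclass(frozen=True)
class SourceSpec:
    """Recipe for one derived source map.

    ``native_factor`` relates the source's native grid to the analysis grid:
    binary/categorical sources are finer (native cell = analysis cell /
    factor, later block-aggregated up), fractional sources are coarser
    (native cell = analysis cell x factor, later nearest-resampled down);
    factor 1 means the analysis grid itself.
    """

    name: str
    native_factor: int = 1
    representation: Literal["categorical", "binary", "fractional"] = "binary"
    omission_rate: float = 0.0
    commission_rate: float = 0.0
    bias: float = 0.0
    threshold_pct: float = 20.0

    def __post_init__(self) -> None:
        if not (0 <= self.omission_rate < 1 and 0 <= self.commission_rate < 1):
            raise ConfigurationError("omission/commission rates must be in [0, 1)")
        if not abs(self.bias) < 1:
            raise ConfigurationError("|bias| must be < 1")
        if self.native_factor < 1:
            raise ConfigurationError("native_factor must be a positive integer")
        if self.representation not in ("categorical", "binary", "fractional"):
            raise ConfigurationError(f"unknown representation {self.representation!r}")


@dataclass
class GeneratedSource:
    """A generated source map plus its realized confusion against truth."""

    spec: SourceSpec
    native_map: BinaryMap | CategoricalMap | FractionalCoverMap
    harmonized: FractionalCoverMap  # on the analysis grid, fractional
    confusion: dict[str, int] | None  # tp/fp/fn/tn at native resolution

    @property
    def name(self) -> str:
        return self.spec.name


def _smoothed_noise(rng: np.random.Generator, shape, corr_len: int) -> np.ndarray:
    """Unit-variance spatially autocorrelated field via moving-average
    smoothing of white noise."""
    white = rng.standard_normal(shape)
    if corr_len <= 1:
        return white
    smooth = ndimage.uniform_filter(white, size=corr_len, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # degenerate 1x1 fields
        return np.zeros(shape)
    return smooth / sd


def _voronoi_patch_labels(
    rng: np.random.Generator, shape: tuple[int, int], n_templates: int, patches_per_template: int
) -> np.ndarray:
    """Contiguous patches: nearest-seed (Voronoi) partition of the grid with
    seeds assigned to templates round-robin, so every template is present."""
    n_seeds = n_templates * patches_per_template
    rows = rng.uniform(0, shape[0], n_seeds)
    cols = rng.uniform(0, shape[1], n_seeds)
    seed_template = np.arange(n_seeds) % n_templates
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr[..., None] - rows) ** 2 + (cc[..., None] - cols) ** 2
    nearest = np.argmin(d2, axis=-1)
    return seed_template[nearest]


def _ecoregion_blocks(shape: tuple[int, int], n_regions: int) -> np.ndarray:
    """Label the grid with ~n_regions rectangular blocks (row-major ids)."""
    n_down = max(1, int(np.floor(np.sqrt(n_regions))))
    while n_regions % n_down:
        n_down -= 1
    n_across = n_regions // n_down
    row_edges = np.linspace(0, shape[0], n_down + 1).astype(int)
    col_edges = np.linspace(0, shape[1], n_across + 1).astype(int)
    labels = np.zeros(shape, dtype=np.int64)
    rid = 0
    for i in range(n_down):
        for j in range(n_across):
            labels[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]] = rid
            rid += 1
    return labels


def generate_truth_series(
    templates: Sequence[ArchetypeTemplate],
    grid: Grid,
    epochs: Sequence[int] = DEFAULT_EPOCHS,
    spatial_corr_len: int = 5,
    seed: int = 0,
    coarse_factor: int = 10,
    patches_per_template: int = 3,
    n_ecoregions: int = 8,
) -> tuple[CoverTimeSeries, np.ndarray, np.ndarray]:
    """True cover surfaces with archetype-structured trajectories.

    Template membership is decided per coarse cell (``coarse_factor`` fine
    cells per side) so that later re-aggregation sees homogeneous blocks.
    Per fine cell and epoch, cover = template trajectory value + spatially
    smoothed noise scaled by the template's per-epoch sd, clipped to [0, 1].

    Returns ``(series, archetype_labels, ecoregion_labels)`` where the
    archetype labels live on the coarse grid and the ecoregion labels on the
    fine grid.
    """
    if not templates:
        raise ConfigurationError("at least one archetype template is required")
    epochs = [int(e) for e in epochs]
    n_epochs = len(epochs)
    for t in templates:
        if len(t.trajectory) != n_epochs:
            raise ConfigurationError(
                f"template {t.name!r} has {len(t.trajectory)} epochs, expected {n_epochs}"
            )
    if spatial_corr_len < 0:
        raise ConfigurationError("spatial correlation length must be >= 0")
    rng = np.random.default_rng(seed)

    coarse_shape = (-(-grid.n_rows // coarse_factor), -(-grid.n_cols // coarse_factor))
    coarse_labels = _voronoi_patch_labels(
        rng, coarse_shape, len(templates), patches_per_template
    )
    fine_labels = np.kron(coarse_labels, np.ones((coarse_factor, coarse_factor), dtype=np.int64))
    fine_labels = fine_labels[: grid.n_rows, : grid.n_cols]

    traj = np.array([t.trajectory for t in templates])  # (n_templates, n_epochs)
    sds = np.array([t.sd for t in templates])
    maps = []
    for e in range(n_epochs):
        base = traj[fine_labels, e]
        sd_field = sds[fine_labels, e]
        if np.any(sd_field > 0):
            noise = _smoothed_noise(rng, grid.shape, spatial_corr_len)
        else:
            noise = np.zeros(grid.shape)
        values = np.clip(base + sd_field * noise, 0.0, 1.0)
        maps.append(FractionalCoverMap(grid, values, np.zeros(grid.shape, bool), epochs[e]))

    series = CoverTimeSeries(epochs, maps)
    ecoregions = _ecoregion_blocks(grid.shape, n_ecoregions)
    return series, coarse_labels, ecoregions


def _flip_binary(
    rng: np.random.Generator, truth: np.ndarray, omission: float, commission: float
) -> np.ndarray:
    """Flip woodland->other w.p. omission and other->woodland w.p. commission."""
    u = rng.random(truth.shape)
    flipped = truth.copy()
    flipped[truth & (u < omission)] = False
    flipped[~truth & (u < commission)] = True
    return flipped


def generate_source_maps(
    truth: CoverTimeSeries,
    specs: Sequence[SourceSpec],
    epoch: int,
    seed: int = 0,
) -> list[GeneratedSource]:
    """Derive noisy source maps from the truth for one epoch.

    Binary/categorical sources: truth is refined to the native (finer) grid,
    thresholded at the spec's threshold, and cells are flipped independently
    at the omission/commission rates; the realized confusion against the
    thresholded truth at native resolution is recorded. Harmonization
    block-aggregates back to the analysis grid.

    Fractional sources: truth is block-aggregated to the native (coarser)
    grid and the additive bias applied (clipped to [0, 1]); harmonization
    nearest-resamples back to the analysis grid.
    """
    truth_map = truth.map_for(epoch)
    rng = np.random.default_rng(seed)
    out: list[GeneratedSource] = []
    for spec in specs:
        child = np.random.default_rng(rng.integers(0, 2**63 - 1))
        if spec.representation == "fractional":
            native = (
                block_aggregate(truth_map, spec.native_factor)
                if spec.native_factor > 1
                else truth_map.copy()
            )
            biased = np.clip(native.values + spec.bias, 0.0, 1.0)
            biased[native.nodata_mask] = np.nan
            native = FractionalCoverMap(native.grid, biased, native.nodata_mask, epoch)
            harmonized = nearest_resample(native, truth_map.grid)
            out.append(GeneratedSource(spec, native, harmonized, None))
            continue

        native_grid = (
            truth_map.grid.refine(spec.native_factor)
            if spec.native_factor > 1
            else truth_map.grid
        )
        truth_native = (
            nearest_resample(truth_map, native_grid)
            if spec.native_factor > 1
            else truth_map
        )
        true_bin = binarize_fractional(truth_native, spec.threshold_pct)
        noisy = _flip_binary(
            child, true_bin.values, spec.omission_rate, spec.commission_rate
        )
        noisy[true_bin.nodata_mask] = False
        ok = ~true_bin.nodata_mask
        confusion = {
            "tp": int(np.sum(true_bin.values[ok] & noisy[ok])),
            "fp": int(np.sum(~true_bin.values[ok] & noisy[ok])),
            "fn": int(np.sum(true_bin.values[ok] & ~noisy[ok])),
            "tn": int(np.sum(~true_bin.values[ok] & ~noisy[ok])),
        }
        if spec.representation == "binary":
            native: BinaryMap | CategoricalMap = BinaryMap(
                native_grid, noisy, true_bin.nodata_mask.copy(), epoch
            )
            harmon_src = native
        else:  # categorical: woodland code 1, other code 0
            native = CategoricalMap(
                native_grid,
                noisy.astype(np.int64),
                {0: "other", 1: "woodland"},
                true_bin.nodata_mask.copy(),
                epoch,
            )
            harmon_src = BinaryMap(native_grid, noisy, true_bin.nodata_mask.copy(), epoch)
        harmonized = (
            block_aggregate(harmon_src, spec.native_factor)
            if spec.native_factor > 1
            else harmon_src.as_fractional()
        )
        out.append(GeneratedSource(spec, native, harmonized, confusion))
    return out


def generate_observer_samples(
    truth: FractionalCoverMap,
    n: int,
    min_dist: float,
    obs_noise_sd: float = 0.0,
    seed: int = 0,
    max_attempts_per_point: int = 1000,
) -> ValidationSet:
    """Spatially constrained validation samples with two observers.

    Cells are drawn uniformly (rejecting nodata cells and any candidate
    closer than ``min_dist`` to an accepted point, measured between cell
    centers). Each observer reports truth + independent N(0, obs_noise_sd)
    noise, truncated to [0, 1) and snapped to the containing 10% interval.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    xs_acc: list[float] = []
    ys_acc: list[float] = []
    fracs: list[float] = []
    max_attempts = max_attempts_per_point * n
    attempts = 0
    while len(xs_acc) < n and attempts < max_attempts:
        attempts += 1
        row = int(rng.integers(0, grid.n_rows))
        col = int(rng.integers(0, grid.n_cols))
        if truth.nodata_mask[row, col]:
            continue
        x, y = grid.cell_center(row, col)
        if xs_acc:
            d2 = (np.array(xs_acc) - x) ** 2 + (np.array(ys_acc) - y) ** 2
            if d2.min() < min_dist**2:
                continue
        xs_acc.append(x)
        ys_acc.append(y)
        fracs.append(float(truth.values[row, col]))
    if len(xs_acc) < n:
        raise PlacementError(
            f"could only place {len(xs_acc)} of {n} samples at min distance "
            f"{min_dist} after {max_attempts} attempts"
        )

    frac_arr = np.array(fracs)
    bins = []
    for _ in range(2):
        noisy = frac_arr + rng.normal(0.0, obs_noise_sd, size=n) if obs_noise_sd > 0 else frac_arr
        noisy = np.clip(noisy, 0.0, np.nextafter(1.0, 0.0))
        bins.append((np.floor(noisy * 10).astype(np.int64) * 10))
    return ValidationSet(np.array(xs_acc), np.array(ys_acc), bins[0], bins[1])


def _grow_patch(
    rng: np.random.Generator,
    weights: np.ndarray,
    size: int,
) -> np.ndarray:
    """Grow one 4-connected patch of ``size`` cells; the seed and each
    frontier pick are drawn with probability proportional to ``weights``."""
    shape = weights.shape
    flat_w = weights.ravel().astype(np.float64)
    total = flat_w.sum()
    if total <= 0:
        flat_w = np.ones_like(flat_w)
        total = flat_w.sum()
    start = int(rng.choice(flat_w.size, p=flat_w / total))
    patch = np.zeros(shape, dtype=bool)
    patch.flat[start] = True
    frontier: dict[int, float] = {}

    def add_neighbors(idx: int) -> None:
        r, c = divmod(idx, shape[1])
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                j = rr * shape[1] + cc
                if not patch.flat[j]:
                    frontier[j] = flat_w[j]

    add_neighbors(start)
    while patch.sum() < size and frontier:
        keys = np.fromiter(frontier.keys(), dtype=np.int64)
        w = np.fromiter(frontier.values(), dtype=np.float64)
        if w.sum() <= 0:
            w = np.ones_like(w)
        pick = int(rng.choice(keys.size, p=w / w.sum()))
        idx = int(keys[pick])
        del frontier[idx]
        patch.flat[idx] = True
        add_neighbors(idx)
    return patch


def generate_species_ranges(
    truth: FractionalCoverMap,
    n_threatened: int,
    n_nonthreatened: int,
    cover_affinity: float = 4.0,
    seed: int = 0,
    range_size_frac: tuple[float, float] = (0.05, 0.20),
    threatened_names: Sequence[str] | None = None,
    nonthreatened_names: Sequence[str] | None = None,
) -> list[SpeciesRange]:
    """Connected species ranges on the coarse grid.

    Threatened ranges are grown with cell weights exp(affinity * cover), so
    they concentrate where cover is high; non-threatened ranges use uniform
    weights. ``cover_affinity = 0`` makes the two groups distributionally
    identical. Range sizes are drawn uniformly from ``range_size_frac`` of
    the grid's cells.
    """
    if n_threatened < 0 or n_nonthreatened < 0:
        raise ConfigurationError("species counts must be >= 0")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    n_cells = grid.n_rows * grid.n_cols
    cover = np.where(truth.nodata_mask, 0.0, truth.values)
    affine_w = np.exp(cover_affinity * cover)
    uniform_w = np.ones(grid.shape)

    lo = max(1, int(range_size_frac[0] * n_cells))
    hi = max(lo, int(range_size_frac[1] * n_cells))

    ranges: list[SpeciesRange] = []
    for group, count, weights, names in (
        ("threatened", n_threatened, affine_w, threatened_names),
        ("non_threatened", n_nonthreatened, uniform_w, nonthreatened_names),
    ):
        for i in range(count):
            size = int(rng.integers(lo, hi + 1))
            patch = _grow_patch(rng, weights, size)
            name = (
                names[i]
                if names is not None and i < len(names)
                else f"{group}_{i:02d}"
            )
            ranges.append(SpeciesRange(name, grid, patch, group == "threatened"))
    return ranges


@dataclass
class SyntheticWorld:
    """Everything a downstream stage needs, with generation provenance."""

    seed: int
    truth_series: CoverTimeSeries
    archetype_labels: np.ndarray  # coarse grid
    ecoregion_labels: np.ndarray  # fine grid
    sources: list[GeneratedSource]
    validation: ValidationSet
    species: list[SpeciesRange]
    coarse_factor: int
    templates: list[ArchetypeTemplate] = field(default_factory=list)

    @property
    def grid(self) -> Grid:
        return self.truth_series.grid

    @property
    def coarse_grid(self) -> Grid:
        return self.grid.coarsen(self.coarse_factor)

    def save(self, outdir: str | Path) -> Path:
        """Serialize to GeoTIFFs + CSVs + a JSON manifest (reconstructable)."""
        from . import raster_io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for epoch, amap in zip(self.truth_series.epochs, self.truth_series.maps):
            raster_io.write_geotiff(outdir / f"truth_{epoch}.tif", amap)
        raster_io.write_label_geotiff(
            outdir / "archetype_labels.tif", self.archetype_labels, self.coarse_grid
        )
        raster_io.write_label_geotiff(
            outdir / "ecoregion_labels.tif", self.ecoregion_labels, self.grid
        )
        for src in self.sources:
            raster_io.write_geotiff(outdir / f"source_{src.name}_harmonized.tif", src.harmonized)
        for sp in self.species:
            raster_io.write_label_geotiff(
                outdir / f"range_{sp.species_id}.tif",
                sp.presence.astype(np.int64),
                sp.grid,
            )
        self.validation.to_csv(outdir / "validation_samples.csv")
        manifest = {
            "seed": self.seed,
            "epochs": list(self.truth_series.epochs),
            "coarse_factor": self.coarse_factor,
            "templates": [
                {"name": t.name, "trajectory": list(t.trajectory), "sd": list(t.sd)}
                for t in self.templates
            ],
            "sources": [
                {
                    "name": s.spec.name,
                    "native_factor": s.spec.native_factor,
                    "representation": s.spec.representation,
                    "omission_rate": s.spec.omission_rate,
                    "commission_rate": s.spec.commission_rate,
                    "bias": s.spec.bias,
                    "threshold_pct": s.spec.threshold_pct,
                    "confusion": s.confusion,
                }
                for s in self.sources
            ],
            "species": [
                {"species_id": sp.species_id, "threatened": sp.threatened}
                for sp in self.species
            ],
        }
        (outdir / "world_manifest.json").write_text(json.dumps(manifest, indent=2))
        species_df = pd.DataFrame(manifest["species"])
        species_df.to_csv(outdir / "species.csv", index=False)
        return outdir
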