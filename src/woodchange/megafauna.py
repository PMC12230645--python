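"""Species-range overlays: richness, richness-cover correlation by threat
group, per-range cover trajectories, and archetype composition of ranges."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, GridMismatchError, UndefinedResultError
from .grids import CoverTimeSeries, FractionalCoverMap, Grid

__all__ = [
    "SpeciesRange",
    "RichnessMap",
    "CorrelationResult",
    "rasterize_range",
    "richness",
    "richness_cover_correlation",
    "range_cover_trajectory",
    "archetype_composition",
    "median_richness_per_archetype",
    "THREATENED_SPECIES",
    "NON_THREATENED_SPECIES",
]

# Default threat grouping (configurable everywhere it is used).
THREATENED_SPECIES = (
    "elephant", "dhole", "tiger", "gaur", "leopard", "sloth_bear", "sambar",
)
NON_THREATENED_SPECIES = (
    "nilgai", "chital", "chinkara", "blackbuck", "muntjac", "gray_wolf",
    "striped_hyaena",
)

Group = Literal["all", "threatened", "non_threatened"]


@dataclass
class SpeciesRange:
    """Presence/absence mask for one species on the coarse grid."""

    species_id: str
    grid: Grid
    presence: np.ndarray
    threatened: bool

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != self.grid.shape:
            raise GridMismatchError(
                f"presence mask shape {self.presence.shape} != grid shape {self.grid.shape}"
            )
        if not self.presence.any():
            raise ConfigurationError(
                f"species range {self.species_id!r} has no presence cells"
            )

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())


@dataclass
class RichnessMap:
    """Per-cell species count for one threat group."""

    grid: Grid
    values: np.ndarray
    group: Group = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("richness shape != grid shape")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    group: str


def rasterize_range(
    geometry,
    coarse_grid: Grid,
    species_id: str,
    threatened: bool,
    rule: Literal["center", "any_overlap"] = "center",
) -> SpeciesRange:
    """Rasterize a polygon range to presence/absence on the coarse grid.

    With the default ``center`` rule a cell is present iff its center falls
    inside the geometry; ``any_overlap`` marks every cell whose square
    intersects the geometry.
    """
    import shapely

    xs, ys = coarse_grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    if rule == "center":
        presence = shapely.contains_xy(geometry, xx.ravel(), yy.ravel()).reshape(
            coarse_grid.shape
        )
    elif rule == "any_overlap":
        half = coarse_grid.cell_size / 2.0
        cells = shapely.box(
            xx.ravel() - half, yy.ravel() - half, xx.ravel() + half, yy.ravel() + half
        )
        presence = shapely.intersects(geometry, cells).reshape(coarse_grid.shape)
    else:
        raise ConfigurationError(f"unknown rasterization rule {rule!r}")
    if not presence.any():
        raise ConfigurationError(
            f"geometry for species {species_id!r} does not cover any grid cell"
        )
    return SpeciesRange(species_id, coarse_grid, presence, threatened)


def richness(ranges: Sequence[SpeciesRange], group: Group = "all") -> RichnessMap:
    """Per-cell count of present species in the requested threat group."""
    if not ranges:
        raise ConfigurationError("richness requires at least one species range")
    grid = ranges[0].grid
    for r in ranges:
        if r.grid != grid:
            raise GridMismatchError("all species ranges must share one grid")
    if group == "threatened":
        members = [r for r in ranges if r.threatened]
    elif group == "non_threatened":
        members = [r for r in ranges if not r.threatened]
    elif group == "all":
        members = list(ranges)
    else:
        raise ConfigurationError(f"unknown group {group!r}")
    counts = np.zeros(grid.shape, dtype=np.int64)
    for r in members:
        counts += r.presence
    return RichnessMap(grid, counts, group)


def richness_cover_correlation(
    rich: RichnessMap,
    cover: FractionalCoverMap,
    extra_mask: np.ndarray | None = None,
) -> CorrelationResult:
    """Pearson correlation between cell cover and species richness.

    The domain is every cell valid in both layers (and outside
    ``extra_mask`` when given, e.g. the persistent non-woodland mask);
    richness 0 cells are informative and included. Two-sided p-value from
    the t transform.
    """
    if rich.grid != cover.grid:
        raise GridMismatchError("richness and cover grids differ")
    ok = ~cover.nodata_mask
    if extra_mask is not None:
        ok &= ~np.asarray(extra_mask, dtype=bool)
    xs = cover.values[ok]
    ys = rich.values[ok].astype(np.float64)
    if xs.size < 3:
        raise ConfigurationError(f"need at least 3 paired cells, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedResultError(
            "correlation undefined: zero variance in cover or richness"
        )
    res = stats.pearsonr(xs, ys)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(xs.size), rich.group)


def range_cover_trajectory(
    species_range: SpeciesRange, series: CoverTimeSeries
) -> pd.Series:
    """Mean cover over the range's presence cells, per epoch."""
    if series.grid != species_range.grid:
        raise GridMismatchError("range and series grids differ")
    means = []
    for m in series.maps:
        sel = species_range.presence & ~m.nodata_mask
        means.append(float(m.values[sel].mean()) if sel.any() else np.nan)
    return pd.Series(means, index=list(series.epochs), name=species_range.species_id)


def archetype_composition(
    species_range: SpeciesRange, labels: np.ndarray, nodata: int = -1
) -> dict[int, float]:
    """Share of the range's presence cells in each archetype; shares sum to 1.

    Cells labeled ``nodata`` are excluded from the denominator.
    """
    labels = np.asarray(labels)
    if labels.shape != species_range.grid.shape:
        raise GridMismatchError("archetype label raster shape != range grid shape")
    sel = species_range.presence & (labels != nodata)
    inside = labels[sel]
    if inside.size == 0:
        return {}
    values, counts = np.unique(inside, return_counts=True)
    return {int(v): float(c) / inside.size for v, c in zip(values, counts)}


def median_richness_per_archetype(
    rich: RichnessMap, labels: np.ndarray, nodata: int = -1
) -> dict[int, float]:
    """Median cell richness per archetype. Archetypes with no cells are
    simply absent from the result (never reported as 0). Even-count medians
    use the midpoint convention."""
    labels = np.asarray(labels)
    if labels.shape != rich.grid.shape:
        raise GridMismatchError("archetype label raster shape != richness grid shape")
    out: dict[int, float] = {}
    for a in np.unique(labels):
        if a == nodata:
            continue
        vals = rich.values[labels == a]
        if vals.size:
            out[int(a)] = float(np.median(vals))
    return out


def composition_table(
    ranges: Sequence[SpeciesRange], labels: np.ndarray, nodata: int = -1
) -> pd.DataFrame:
    """Tidy (species, archetype, share) table over all ranges."""
    rows = []
    for r in ranges:
        for arch, share in archetype_composition(r, labels, nodata).items():
            rows.append({"species": r.species_id, "archetype": arch, "share": share})
    return pd.DataFrame(rows, columns=["species", "archetype", "share"])


def trajectory_table(ranges: Sequence[SpeciesRange], series: CoverTimeSeries) -> pd.DataFrame:
    """Tidy (species, epoch, mean_cover) table over all ranges."""
    rows = []
    for r in ranges:
        traj = range_cover_trajectory(r, series)
        for epoch, val in traj.items():
            rows.append({"species": r.species_id, "epoch": int(epoch), "mean_cover": val})
    return pd.DataFrame(rows, columns=["species", "epoch", "mean_cover"])
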