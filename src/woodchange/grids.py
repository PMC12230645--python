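"""Core raster data model and harmonization operators.

All layers live on axis-aligned grids of square cells. Cell (0, 0) is the
top-left cell, storage is row-major, and the center of cell (row, col) is at
``origin + (index + 0.5) * cell_size`` on each axis. Fractions are stored in
[0, 1]; thresholds cross the API boundary in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, GridMismatchError, NotSupportedError

__all__ = [
    "Grid",
    "FractionalCoverMap",
    "BinaryMap",
    "CategoricalMap",
    "CoverTimeSeries",
    "reclassify_categorical",
    "binarize_fractional",
    "block_aggregate",
    "nearest_resample",
    "apply_persistent_nonwoodland_mask",
]


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster layer: origin, square cell size, and shape.

    Parameters
    ----------
    origin_x, origin_y
        Map coordinates of the grid's top-left corner.
    cell_size
        Edge length of the (square) cells, in map units.
    n_rows, n_cols
        Grid shape.
    crs_id
        Opaque identifier of the coordinate reference system. Grids with
        different ``crs_id`` never interoperate (reprojection is out of
        scope).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError(
                f"grid shape must be at least 1x1, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid's bounding box."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y + (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as (xs of shape (n_cols,), ys of shape (n_rows,))."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def cell_containing(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; may be out of range."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((y - self.origin_y) / self.cell_size))
        return row, col

    def contains_point(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.extent
        return (x0 <= x < x1) and (y0 <= y < y1)

    def is_nested_with(self, other: "Grid", rel_tol: float = 1e-9) -> bool:
        """True iff cell sizes differ by an integer factor and origins coincide."""
        if self.crs_id != other.crs_id:
            return False
        if not (
            np.isclose(self.origin_x, other.origin_x, rtol=0, atol=rel_tol * self.cell_size)
            and np.isclose(self.origin_y, other.origin_y, rtol=0, atol=rel_tol * self.cell_size)
        ):
            return False
        big, small = max(self.cell_size, other.cell_size), min(self.cell_size, other.cell_size)
        ratio = big / small
        return abs(ratio - round(ratio)) <= rel_tol * ratio

    def coarsen(self, factor: int) -> "Grid":
        """Grid with cells ``factor`` times larger (shape rounded up)."""
        if factor < 1:
            raise ConfigurationError(f"factor must be >= 1, got {factor}")
        return Grid(
            self.origin_x,
            self.origin_y,
            self.cell_size * factor,
            -(-self.n_rows // factor),
            -(-self.n_cols // factor),
            self.crs_id,
        )

    def refine(self, factor: int) -> "Grid":
        """Grid with cells ``factor`` times smaller."""
        if factor < 1:
            raise ConfigurationError(f"factor must be >= 1, got {factor}")
        return Grid(
            self.origin_x,
            self.origin_y,
            self.cell_size / factor,
            self.n_rows * factor,
            self.n_cols * factor,
            self.crs_id,
        )


def _check_layer(grid: Grid, values: np.ndarray, nodata_mask: np.ndarray) -> None:
    if values.shape != grid.shape:
        raise GridMismatchError(f"values shape {values.shape} != grid shape {grid.shape}")
    if nodata_mask.shape != grid.shape:
        raise GridMismatchError(f"nodata mask shape {nodata_mask.shape} != grid shape {grid.shape}")


@dataclass
class FractionalCoverMap:
    """One epoch's woodland cover fraction per cell, in [0, 1]."""

    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _check_layer(self.grid, self.values, self.nodata_mask)
        valid = self.values[~self.nodata_mask]
        if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) > 1):
            raise ConfigurationError("fractional cover values must lie in [0, 1]")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy(self) -> "FractionalCoverMap":
        return FractionalCoverMap(
            self.grid, self.values.copy(), self.nodata_mask.copy(), self.epoch_year
        )


@dataclass
class BinaryMap:
    """Woodland (True) vs other (False) per cell."""

    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _check_layer(self.grid, self.values, self.nodata_mask)

    def as_fractional(self) -> FractionalCoverMap:
        vals = self.values.astype(np.float64)
        vals[self.nodata_mask] = np.nan
        return FractionalCoverMap(self.grid, vals, self.nodata_mask.copy(), self.epoch_year)


@dataclass
class CategoricalMap:
    """Integer class codes per cell with a legend mapping code -> name."""

    grid: Grid
    values: np.ndarray
    class_legend: Mapping[int, str]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _check_layer(self.grid, self.values, self.nodata_mask)
        present = np.unique(self.values[~self.nodata_mask])
        unknown = [int(c) for c in present if int(c) not in self.class_legend]
        if unknown:
            raise ConfigurationError(f"codes {unknown} present in map but missing from legend")


@dataclass
class CoverTimeSeries:
    """Co-registered fractional cover maps over strictly increasing epochs."""

    epochs: Sequence[int]
    maps: Sequence[FractionalCoverMap]
    persistent_nonwoodland_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = list(int(e) for e in self.epochs)
        self.maps = list(self.maps)
        if len(self.epochs) != len(self.maps):
            raise ConfigurationError(
                f"{len(self.epochs)} epochs but {len(self.maps)} maps"
            )
        if any(b <= a for a, b in zip(self.epochs, self.epochs[1:])):
            raise ConfigurationError(f"epochs must be strictly increasing, got {self.epochs}")
        g = self.grid
        for m in self.maps:
            if m.grid != g:
                raise GridMismatchError("all maps in a series must share one grid")
        if self.persistent_nonwoodland_mask is not None:
            self.persistent_nonwoodland_mask = np.asarray(
                self.persistent_nonwoodland_mask, dtype=bool
            )
            if self.persistent_nonwoodland_mask.shape != g.shape:
                raise GridMismatchError("persistent non-woodland mask shape != grid shape")

    @property
    def grid(self) -> Grid:
        return self.maps[0].grid

    def map_for(self, year: int) -> FractionalCoverMap:
        try:
            return self.maps[self.epochs.index(int(year))]
        except ValueError:
            raise ConfigurationError(
                f"epoch {year} not in series; available epochs: {self.epochs}"
            ) from None

    def excluded_mask(self) -> np.ndarray:
        """Cells to drop from downstream statistics: persistent non-woodland
        plus cells nodata in every epoch."""
        all_nodata = np.logical_and.reduce([m.nodata_mask for m in self.maps])
        if self.persistent_nonwoodland_mask is None:
            return all_nodata
        return all_nodata | self.persistent_nonwoodland_mask

    def stack(self) -> np.ndarray:
        """(n_epochs, n_rows, n_cols) float array with NaN at nodata."""
        out = np.stack([m.values for m in self.maps]).astype(np.float64)
        for i, m in enumerate(self.maps):
            out[i][m.nodata_mask] = np.nan
        return out


# ---------------------------------------------------------------------------
# Harmonization operators
# ---------------------------------------------------------------------------


def reclassify_categorical(cmap: CategoricalMap, woodland_codes: set[int]) -> BinaryMap:
    """Collapse a multi-class map to woodland vs other.

    A cell is woodland iff its class code is in ``woodland_codes``; nodata is
    preserved. Codes absent from the map's legend are a configuration error.
    """
    unknown = set(int(c) for c in woodland_codes) - set(cmap.class_legend)
    if unknown:
        raise ConfigurationError(
            f"woodland codes {sorted(unknown)} are not in the map legend "
            f"{sorted(cmap.class_legend)}"
        )
    values = np.isin(cmap.values, list(woodland_codes))
    values[cmap.nodata_mask] = False
    return BinaryMap(cmap.grid, values, cmap.nodata_mask.copy(), cmap.epoch_year)


def binarize_fractional(fmap: FractionalCoverMap, threshold_pct: float) -> BinaryMap:
    """Threshold a fractional map: woodland iff fraction >= threshold_pct/100.

    The boundary is inclusive: a cell exactly at the threshold is woodland.
    """
    if not 0 < threshold_pct <= 100:
        raise ConfigurationError(
            f"threshold_pct must be in (0, 100], got {threshold_pct}"
        )
    values = fmap.values >= threshold_pct / 100.0
    values = np.where(fmap.nodata_mask, False, values)
    return BinaryMap(fmap.grid, values, fmap.nodata_mask.copy(), fmap.epoch_year)


def _pad_to_multiple(values: np.ndarray, mask: np.ndarray, factor: int):
    """Pad bottom/right with nodata so both dims divide by ``factor``."""
    n_rows, n_cols = values.shape
    pr = (-n_rows) % factor
    pc = (-n_cols) % factor
    if pr == 0 and pc == 0:
        return values, mask
    values = np.pad(values, ((0, pr), (0, pc)), constant_values=np.nan)
    mask = np.pad(mask, ((0, pr), (0, pc)), constant_values=True)
    return values, mask


def block_aggregate(
    amap: BinaryMap | FractionalCoverMap, factor: int
) -> FractionalCoverMap:
    """Mean cover over factor x factor blocks (binary counted as 1/0).

    Blocks with at least one valid fine cell take the mean over the valid
    cells; all-nodata blocks stay nodata. Dimensions not divisible by
    ``factor`` are padded with nodata at the bottom/right edge.
    """
    if factor < 1:
        raise ConfigurationError(f"aggregation factor must be >= 1, got {factor}")
    if isinstance(amap, BinaryMap):
        fine = amap.values.astype(np.float64)
    else:
        fine = amap.values.astype(np.float64).copy()
    fine = np.where(amap.nodata_mask, np.nan, fine)
    fine, mask = _pad_to_multiple(fine, amap.nodata_mask, factor)
    r, c = fine.shape
    blocks = fine.reshape(r // factor, factor, c // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN blocks
        coarse = np.nanmean(blocks, axis=(1, 3))
    coarse_mask = mask.reshape(r // factor, factor, c // factor, factor).all(axis=(1, 3))
    coarse[coarse_mask] = np.nan
    grid = amap.grid.coarsen(factor)
    return FractionalCoverMap(grid, coarse, coarse_mask, amap.epoch_year)


def nearest_resample(fmap: FractionalCoverMap, target: Grid) -> FractionalCoverMap:
    """Resample to ``target``: each target cell takes the value of the source
    cell containing the target cell's center. Nodata propagates; target cells
    whose center falls outside the source extent are nodata."""
    src = fmap.grid
    if src.crs_id != target.crs_id:
        raise NotSupportedError(
            "nearest_resample requires both grids in the same CRS; "
            "reprojection is not supported"
        )
    xs, ys = target.cell_centers()
    cols = np.floor((xs - src.origin_x) / src.cell_size).astype(np.int64)
    rows = np.floor((ys - src.origin_y) / src.cell_size).astype(np.int64)
    col_ok = (cols >= 0) & (cols < src.n_cols)
    row_ok = (rows >= 0) & (rows < src.n_rows)
    if not col_ok.any() or not row_ok.any():
        warnings.warn(
            "target grid is disjoint from the source extent; result is all nodata",
            stacklevel=2,
        )
    rows_c = np.clip(rows, 0, src.n_rows - 1)
    cols_c = np.clip(cols, 0, src.n_cols - 1)
    values = fmap.values[np.ix_(rows_c, cols_c)].copy()
    mask = fmap.nodata_mask[np.ix_(rows_c, cols_c)].copy()
    outside = ~row_ok[:, None] | ~col_ok[None, :]
    values[outside] = np.nan
    mask |= outside
    values[mask] = np.nan
    return FractionalCoverMap(target, values, mask, fmap.epoch_year)


def apply_persistent_nonwoodland_mask(
    series: CoverTimeSeries, cutoff: float = 0.05
) -> CoverTimeSeries:
    """Mask cells whose cover is <= ``cutoff`` in every epoch.

    Epochs where a cell is nodata do not veto the mask; cells with no valid
    epoch at all are left to the nodata machinery. Idempotent.
    """
    stack = series.stack()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        low = np.less_equal(stack, cutoff) | np.isnan(stack)
    any_valid = ~np.isnan(stack).all(axis=0)
    mask = low.all(axis=0) & any_valid
    return CoverTimeSeries(
        list(series.epochs), [m.copy() for m in series.maps], mask
    )
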