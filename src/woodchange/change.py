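"""Multi-epoch change maps, area accounting, and ecoregion trajectories.

"Absolute percentage change" means the percentage-point difference
``(cover_y2 - cover_y1) * 100``, not relative change; a labeled relative
variant is available separately. Area accounting offers two modes because
either could underlie headline area figures: ``fractional_sum`` integrates
the cover fraction over cells, ``binary_threshold`` counts cells at or above
a cutoff (default 20%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError
from .grids import CoverTimeSeries, FractionalCoverMap, Grid

__all__ = [
    "ChangeMap",
    "AreaAccount",
    "EcoregionTrajectory",
    "change_map",
    "relative_change_map",
    "woodland_area",
    "period_change_table",
    "ecoregion_trajectory",
]

AreaMode = Literal["fractional_sum", "binary_threshold"]
DEFAULT_AREA_THRESHOLD_PCT = 20.0


@dataclass
class ChangeMap:
    """Per-cell cover change in percentage points between two epochs."""

    grid: Grid
    values: np.ndarray
    epoch_pair: tuple[int, int]
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("change values shape != grid shape")
        valid = self.values[~self.nodata_mask]
        if valid.size and (valid.min() < -100 - 1e-9 or valid.max() > 100 + 1e-9):
            raise ConfigurationError("change values must lie in [-100, 100] points")


def change_map(series: CoverTimeSeries, y1: int, y2: int) -> ChangeMap:
    """Pixel-wise cover change (cover_y2 - cover_y1) * 100, in points.

    Persistent non-woodland cells and cells nodata in either epoch are
    nodata in the result.
    """
    m1, m2 = series.map_for(y1), series.map_for(y2)
    mask = m1.nodata_mask | m2.nodata_mask
    if series.persistent_nonwoodland_mask is not None:
        mask = mask | series.persistent_nonwoodland_mask
    values = (m2.values - m1.values) * 100.0
    values[mask] = np.nan
    return ChangeMap(series.grid, values, (int(y1), int(y2)), mask)


def relative_change_map(series: CoverTimeSeries, y1: int, y2: int) -> ChangeMap:
    """Relative change 100 * (cover_y2 - cover_y1) / cover_y1 (percent of the
    starting cover); cells with zero starting cover are nodata. Offered as a
    clearly labeled alternative to the percentage-point ``change_map``."""
    m1, m2 = series.map_for(y1), series.map_for(y2)
    mask = m1.nodata_mask | m2.nodata_mask | (m1.values == 0)
    if series.persistent_nonwoodland_mask is not None:
        mask = mask | series.persistent_nonwoodland_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 100.0 * (m2.values - m1.values) / m1.values
    values[mask] = np.nan
    cm = ChangeMap.__new__(ChangeMap)  # skip the [-100, 100] bound check
    cm.grid, cm.values, cm.epoch_pair, cm.nodata_mask = (
        series.grid,
        values,
        (int(y1), int(y2)),
        mask,
    )
    return cm


def woodland_area(
    fmap: FractionalCoverMap,
    mode: AreaMode = "fractional_sum",
    threshold_pct: float = DEFAULT_AREA_THRESHOLD_PCT,
    extra_mask: np.ndarray | None = None,
) -> float:
    """Woodland area of one map in squared map units.

    ``fractional_sum``: sum of fraction x cell area over valid cells.
    ``binary_threshold``: count of cells with fraction >= threshold x cell
    area. Cells under ``extra_mask`` (e.g. persistent non-woodland) are
    excluded in both modes.
    """
    ok = ~fmap.nodata_mask
    if extra_mask is not None:
        ok &= ~np.asarray(extra_mask, dtype=bool)
    if mode == "fractional_sum":
        return float(fmap.values[ok].sum() * fmap.grid.cell_area)
    if mode == "binary_threshold":
        return float((fmap.values[ok] >= threshold_pct / 100.0).sum() * fmap.grid.cell_area)
    raise ConfigurationError(f"unknown area accounting mode {mode!r}")


@dataclass
class AreaAccount:
    """Woodland area per epoch plus net change per consecutive period.

    Period net changes telescope exactly to the full-series net change.
    Percent values are relative to the period's starting area.
    """

    epochs: list[int]
    areas: list[float]
    accounting_mode: str = "fractional_sum"
    area_unit: str = "map_units^2"

    def __post_init__(self) -> None:
        if len(self.epochs) != len(self.areas):
            raise ConfigurationError("epochs and areas must have equal length")
        if len(self.epochs) < 2:
            raise ConfigurationError("an area account needs at least two epochs")

    @classmethod
    def from_series(
        cls,
        series: CoverTimeSeries,
        mode: AreaMode = "fractional_sum",
        threshold_pct: float = DEFAULT_AREA_THRESHOLD_PCT,
        area_unit: str = "map_units^2",
    ) -> "AreaAccount":
        mask = series.excluded_mask()
        areas = [
            woodland_area(m, mode, threshold_pct, extra_mask=mask) for m in series.maps
        ]
        return cls(list(series.epochs), areas, mode, area_unit)

    @property
    def period_changes(self) -> list[tuple[int, int, float]]:
        """[(start_epoch, end_epoch, net_change), ...] for consecutive pairs."""
        return [
            (self.epochs[i], self.epochs[i + 1], self.areas[i + 1] - self.areas[i])
            for i in range(len(self.epochs) - 1)
        ]

    @property
    def net_change(self) -> float:
        """Full-series net change: area(last epoch) - area(first epoch)."""
        return self.areas[-1] - self.areas[0]

    @property
    def net_change_pct(self) -> float:
        """Full-series net change as a percent of the starting area."""
        return 100.0 * self.net_change / self.areas[0]

    def change_between(self, y1: int, y2: int) -> float:
        """Net area change between two (not necessarily adjacent) epochs."""
        return self.area_at(y2) - self.area_at(y1)

    def change_between_pct(self, y1: int, y2: int) -> float:
        return 100.0 * self.change_between(y1, y2) / self.area_at(y1)

    def area_at(self, year: int) -> float:
        try:
            return self.areas[self.epochs.index(int(year))]
        except ValueError:
            raise ConfigurationError(
                f"epoch {year} not in account; available: {self.epochs}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": "epoch_area",
                "start": e,
                "end": e,
                "value": a,
                "unit": self.area_unit,
            }
            for e, a in zip(self.epochs, self.areas)
        ]
        for y1, y2, delta in self.period_changes:
            rows.append(
                {"kind": "period_net_change", "start": y1, "end": y2, "value": delta,
                 "unit": self.area_unit}
            )
            rows.append(
                {"kind": "period_net_change_pct", "start": y1, "end": y2,
                 "value": 100.0 * delta / self.area_at(y1), "unit": "percent_of_start"}
            )
        rows.append(
            {"kind": "net_change", "start": self.epochs[0], "end": self.epochs[-1],
             "value": self.net_change, "unit": self.area_unit}
        )
        rows.append(
            {"kind": "net_change_pct", "start": self.epochs[0], "end": self.epochs[-1],
             "value": self.net_change_pct, "unit": "percent_of_start"}
        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def period_change_table(
    series: CoverTimeSeries,
    mode: AreaMode = "fractional_sum",
    threshold_pct: float = DEFAULT_AREA_THRESHOLD_PCT,
) -> AreaAccount:
    """Area per epoch and net change per consecutive period for a series."""
    return AreaAccount.from_series(series, mode, threshold_pct)


@dataclass
class EcoregionTrajectory:
    """Per (ecoregion, epoch): mean cover, population SD, and woodland area."""

    table: pd.DataFrame  # columns: ecoregion, epoch, mean_cover, sd_cover, area, unit

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def ecoregion_trajectory(
    series: CoverTimeSeries,
    ecoregion_labels: np.ndarray,
    area_unit: str = "map_units^2",
) -> EcoregionTrajectory:
    """Mean and population SD of unmasked cell cover per ecoregion and epoch,
    plus fractional-sum woodland area."""
    labels = np.asarray(ecoregion_labels)
    if labels.shape != series.grid.shape:
        raise GridMismatchError(
            f"ecoregion label shape {labels.shape} != series grid shape {series.grid.shape}"
        )
    excluded = series.excluded_mask()
    cell_area = series.grid.cell_area
    rows = []
    for region in np.unique(labels):
        in_region = labels == region
        for epoch, m in zip(series.epochs, series.maps):
            sel = in_region & ~m.nodata_mask & ~excluded
            vals = m.values[sel]
            rows.append(
                {
                    "ecoregion": int(region),
                    "epoch": int(epoch),
                    "mean_cover": float(vals.mean()) if vals.size else np.nan,
                    "sd_cover": float(vals.std()) if vals.size else np.nan,
                    "area": float(vals.sum() * cell_area),
                    "n_cells": int(vals.size),
                    "unit": area_unit,
                }
            )
    return EcoregionTrajectory(pd.DataFrame(rows))
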