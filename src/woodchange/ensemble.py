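"""Accuracy-weighted consensus cover maps.

Two normalization modes are provided because the combination formula as
printed divides the accuracy-weighted sum by the number of sources ``n``
(shrinking the average toward 0 when accuracies are below 1), while the
surrounding description asks for an average weighted by user's accuracy,
which corresponds to dividing by the sum of the weights:

* ``as_printed``:          WLE = sum_i(UA_i * WL_i) / n
* ``weight_normalized``:   WLE = sum_i(UA_i * WL_i) / sum_i(UA_i)

Cells where some sources are nodata use only the valid sources there, with
the denominator (n or sum of UA) restricted accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, GridMismatchError
from .grids import FractionalCoverMap

__all__ = ["SourceMap", "EnsembleMap", "ensemble_cover"]

Mode = Literal["as_printed", "weight_normalized"]


@dataclass
class SourceMap:
    """A screened source: its harmonized cover plus the accuracy weight."""

    name: str
    cover: FractionalCoverMap
    ua_weight: float
    best_threshold: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ua_weight <= 1:
            raise ConfigurationError(
                f"ua_weight must be in (0, 1], got {self.ua_weight} for {self.name!r}"
            )


@dataclass
class EnsembleMap:
    cover: FractionalCoverMap
    n_sources: int
    normalization_mode: Mode
    weights: dict[str, float]


def ensemble_cover(sources: Sequence[SourceMap], mode: Mode = "as_printed") -> EnsembleMap:
    """Combine co-registered sources into one consensus fractional map."""
    if not sources:
        raise ConfigurationError("ensemble requires at least one source map")
    if mode not in ("as_printed", "weight_normalized"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    grid = sources[0].cover.grid
    for s in sources[1:]:
        if s.cover.grid != grid:
            raise GridMismatchError(
                f"source {s.name!r} is not on the ensemble grid"
            )

    weighted_sum = np.zeros(grid.shape)
    n_valid = np.zeros(grid.shape)
    ua_sum = np.zeros(grid.shape)
    for s in sources:
        valid = ~s.cover.nodata_mask
        weighted_sum += np.where(valid, s.ua_weight * s.cover.values, 0.0)
        n_valid += valid
        ua_sum += np.where(valid, s.ua_weight, 0.0)

    denom = n_valid if mode == "as_printed" else ua_sum
    nodata = n_valid == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(nodata, np.nan, weighted_sum / np.where(nodata, 1.0, denom))
    fmap = FractionalCoverMap(grid, values, nodata, sources[0].cover.epoch_year)
    return EnsembleMap(
        cover=fmap,
        n_sources=len(sources),
        normalization_mode=mode,
        weights={s.name: s.ua_weight for s in sources},
    )
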