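"""Reference-sample fusion, error-matrix accuracy assessment, threshold
sweeps, and accuracy-based screening of candidate cover maps.

Observers report woody cover as 10%-wide intervals identified by their lower
bound (0, 10, ..., 90). An interval enters arithmetic as its midpoint, the
two observers are averaged, and the average is rounded to the nearest 5%
(ties round half up), giving a fused reference fraction on the 5% lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError
from .grids import FractionalCoverMap

__all__ = [
    "VALID_BINS",
    "fuse_observers",
    "ValidationSet",
    "ErrorMatrix",
    "error_matrix",
    "AccuracyTable",
    "threshold_sweep",
    "screen_maps",
    "DEFAULT_SWEEP",
    "DEFAULT_OA_MIN",
    "DEFAULT_UA_MIN",
]

VALID_BINS = tuple(range(0, 100, 10))
DEFAULT_SWEEP = tuple(range(15, 23))
DEFAULT_OA_MIN = 0.70
DEFAULT_UA_MIN = 0.90


def _bin_midpoint(bin_lower: int) -> int:
    if bin_lower not in VALID_BINS:
        raise ConfigurationError(
            f"observer interval must be one of {VALID_BINS}, got {bin_lower!r}"
        )
    return bin_lower + 5


def fuse_observers(a_interval: int, b_interval: int) -> int:
    """Fuse two observers' 10%-interval estimates into a percent on the 5% grid.

    Each interval is represented by its midpoint; the midpoints are averaged
    and rounded to the nearest 5%, ties rounding half up. Exact integer
    arithmetic, no floating point.
    """
    mid_a = _bin_midpoint(int(a_interval))
    mid_b = _bin_midpoint(int(b_interval))
    # average = (mid_a + mid_b) / 2; nearest multiple of 5 with half-up ties
    return 5 * ((mid_a + mid_b + 5) // 10)


@dataclass
class ValidationSet:
    """Point validation samples: locations plus two observers' interval
    estimates and the fused reference fraction (percent, multiple of 5)."""

    x: np.ndarray
    y: np.ndarray
    observer_a_bin: np.ndarray
    observer_b_bin: np.ndarray
    fused_pct: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.observer_a_bin = np.asarray(self.observer_a_bin, dtype=np.int64)
        self.observer_b_bin = np.asarray(self.observer_b_bin, dtype=np.int64)
        n = len(self.x)
        if not (len(self.y) == len(self.observer_a_bin) == len(self.observer_b_bin) == n):
            raise ConfigurationError("validation set columns have unequal lengths")
        if self.fused_pct is None:
            self.fused_pct = np.array(
                [fuse_observers(a, b) for a, b in zip(self.observer_a_bin, self.observer_b_bin)],
                dtype=np.int64,
            )
        else:
            self.fused_pct = np.asarray(self.fused_pct, dtype=np.int64)
        bad = set(np.unique(self.observer_a_bin)) | set(np.unique(self.observer_b_bin))
        if n and not bad <= set(VALID_BINS):
            raise ConfigurationError(f"invalid observer bins: {sorted(bad - set(VALID_BINS))}")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "observer_a_bin": self.observer_a_bin,
                "observer_b_bin": self.observer_b_bin,
                "fused_pct": self.fused_pct,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValidationSet":
        df = pd.read_csv(path)
        return cls(
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            df["observer_a_bin"].to_numpy(),
            df["observer_b_bin"].to_numpy(),
            df["fused_pct"].to_numpy() if "fused_pct" in df else None,
        )


@dataclass(frozen=True)
class ErrorMatrix:
    """2x2 confusion counts for woodland vs other, with derived accuracies.

    ``users_accuracy_woodland`` and ``producers_accuracy_woodland`` are
    ``None`` when their denominator is zero (no predicted / no reference
    woodland), which is distinct from an accuracy of 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def overall_accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def users_accuracy_woodland(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def producers_accuracy_woodland(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    # short aliases used throughout
    @property
    def oa(self) -> float:
        return self.overall_accuracy

    @property
    def ua(self) -> float | None:
        return self.users_accuracy_woodland

    @property
    def pa(self) -> float | None:
        return self.producers_accuracy_woodland


def error_matrix(reference: np.ndarray, predicted: np.ndarray) -> ErrorMatrix:
    """Confusion counts of predicted vs reference boolean woodland labels."""
    reference = np.asarray(reference, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if reference.shape != predicted.shape:
        raise ConfigurationError(
            f"reference and predicted lengths differ: {reference.shape} vs {predicted.shape}"
        )
    if reference.size == 0:
        raise ConfigurationError("error_matrix requires at least one sample")
    tp = int(np.sum(reference & predicted))
    fp = int(np.sum(~reference & predicted))
    fn = int(np.sum(reference & ~predicted))
    tn = int(np.sum(~reference & ~predicted))
    return ErrorMatrix(tp, fp, fn, tn)


@dataclass
class AccuracyTable:
    """Per-threshold error matrices for one source plus the best threshold.

    ``best_threshold`` maximizes user's accuracy over thresholds where UA is
    defined; ties break to the smallest threshold. ``None`` when UA is
    undefined everywhere.
    """

    source: str
    matrices: dict[int, ErrorMatrix]

    @property
    def best_threshold(self) -> int | None:
        best_t, best_ua = None, -1.0
        for t in sorted(self.matrices):
            ua = self.matrices[t].ua
            if ua is not None and ua > best_ua:
                best_t, best_ua = t, ua
        return best_t

    @property
    def best_matrix(self) -> ErrorMatrix | None:
        t = self.best_threshold
        return None if t is None else self.matrices[t]

    def to_frame(self) -> pd.DataFrame:
        best = self.best_threshold
        rows = []
        for t in sorted(self.matrices):
            m = self.matrices[t]
            rows.append(
                {
                    "source": self.source,
                    "threshold": t,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "tn": m.tn,
                    "oa": m.oa,
                    "ua": np.nan if m.ua is None else m.ua,
                    "pa": np.nan if m.pa is None else m.pa,
                    "is_best": t == best,
                }
            )
        return pd.DataFrame(rows)


def sample_map_fractions(fmap: FractionalCoverMap, samples: ValidationSet) -> np.ndarray:
    """Map fraction at each sample point (value of the containing cell)."""
    grid = fmap.grid
    cols = np.floor((samples.x - grid.origin_x) / grid.cell_size).astype(np.int64)
    rows = np.floor((samples.y - grid.origin_y) / grid.cell_size).astype(np.int64)
    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if not inside.all():
        raise GridMismatchError(
            f"{int((~inside).sum())} validation samples fall outside the map extent"
        )
    vals = fmap.values[rows, cols].astype(np.float64)
    vals[fmap.nodata_mask[rows, cols]] = np.nan
    return vals


def threshold_sweep(
    fmap: FractionalCoverMap,
    samples: ValidationSet,
    thresholds: Iterable[int] = DEFAULT_SWEEP,
    source: str = "map",
) -> AccuracyTable:
    """Accuracy of a fractional map against the fused reference across a
    threshold sweep.

    At each threshold ``t`` both the fused reference percentages and the map
    fractions are binarized with the same inclusive rule (woodland iff
    value >= t), then cross-tabulated. Samples landing on nodata cells are
    dropped.
    """
    thresholds = [int(t) for t in thresholds]
    if not thresholds:
        raise ConfigurationError("threshold sweep must contain at least one threshold")
    map_frac = sample_map_fractions(fmap, samples)
    ok = ~np.isnan(map_frac)
    ref_pct = samples.fused_pct[ok]
    map_frac = map_frac[ok]
    if map_frac.size == 0:
        raise ConfigurationError("no validation samples fall on valid map cells")
    matrices = {}
    for t in thresholds:
        reference = ref_pct >= t
        predicted = map_frac >= t / 100.0
        matrices[t] = error_matrix(reference, predicted)
    return AccuracyTable(source=source, matrices=matrices)


@dataclass(frozen=True)
class ScreenedSource:
    """A source that passed screening, with the weight it carries forward."""

    source: str
    best_threshold: int
    oa: float
    ua: float


def screen_maps(
    tables: Sequence[AccuracyTable],
    oa_min: float = DEFAULT_OA_MIN,
    ua_min: float = DEFAULT_UA_MIN,
) -> list[ScreenedSource]:
    """Retain sources whose best-threshold accuracies clear both floors.

    A source is kept iff, at its best threshold, overall accuracy >= oa_min
    AND woodland user's accuracy >= ua_min. Sources with no defined UA at
    any threshold are excluded.
    """
    retained = []
    for table in tables:
        m = table.best_matrix
        if m is None or m.ua is None:
            continue
        if m.oa >= oa_min and m.ua >= ua_min:
            retained.append(
                ScreenedSource(table.source, table.best_threshold, m.oa, m.ua)
            )
    return retained


def accuracy_tables_to_csv(tables: Sequence[AccuracyTable], path: str | Path) -> Path:
    path = Path(path)
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(path, index=False)
    return path
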