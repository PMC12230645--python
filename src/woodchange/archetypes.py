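"""Trajectory clustering with a self-organizing map (SOM).

Per-cell cover trajectories at the coarse grid are clustered with an online
Kohonen network on a one-dimensional chain of ``k`` nodes: prototypes are
initialized from ``k`` distinct data rows, and at every training step the
best-matching node and its chain neighbors (Gaussian neighborhood whose
radius decays linearly to zero) move toward the presented sample by a
linearly decaying learning rate. Final hard assignments use plain nearest
prototype distance, decoupled from the training neighborhood; best-matching
ties break to the lowest node index.

The inner training loop is optionally JIT-compiled with numba when it is
importable; the pure-Python fallback is identical step for step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError
from .grids import CoverTimeSeries, Grid, block_aggregate
from .metrics import pairwise_distances, silhouette_score

__all__ = [
    "SomParams",
    "TrajectoryMatrix",
    "ArchetypeModel",
    "ArchetypeSummary",
    "build_trajectory_matrix",
    "train_som",
    "select_cluster_count",
    "summarize_archetypes",
]


# --- training loop (numba-compatible; no numpy RNG inside) -----------------


def _som_loop(X, codebook, order, alphas, radii):  # pragma: no cover - thin
    n_nodes, n_dim = codebook.shape
    for t in range(order.shape[0]):
        x = X[order[t]]
        # best-matching unit; ties to lowest index
        best, best_d = 0, np.inf
        for j in range(n_nodes):
            d = 0.0
            for m in range(n_dim):
                diff = x[m] - codebook[j, m]
                d += diff * diff
            if d < best_d:
                best, best_d = j, d
        alpha = alphas[t]
        sigma = radii[t]
        if sigma <= 0.0:
            for m in range(n_dim):
                codebook[best, m] += alpha * (x[m] - codebook[best, m])
        else:
            denom = 2.0 * sigma * sigma
            for j in range(n_nodes):
                h = np.exp(-((j - best) * (j - best)) / denom)
                for m in range(n_dim):
                    codebook[j, m] += alpha * h * (x[m] - codebook[j, m])


try:  # optional acceleration; results are bit-identical either way
    from numba import njit

    _som_loop = njit(cache=True)(_som_loop)
except Exception:  # numba absent or broken: keep the pure-Python loop
    pass


@dataclass(frozen=True)
class SomParams:
    """SOM hyperparameters; all logged with every trained model.

    The neighborhood radius decays linearly from ``radius_start`` to
    ``radius_end`` over the first ``radius_anneal_frac`` of the training
    steps and stays at ``radius_end`` afterwards, leaving a best-matching-
    unit-only fine-tuning phase. The default radius is deliberately small:
    with prototypes initialized from spread-out data rows, a wide
    neighborhood (the textbook k/2) demonstrably collapses well-separated
    trajectory clusters onto fewer nodes, whereas a mild one preserves them
    while still ordering the chain.
    """

    n_presentations: int = 100  # passes over the data
    learning_rate_start: float = 0.05
    learning_rate_end: float = 0.01
    radius_start: float = 0.5
    radius_end: float = 0.0
    radius_anneal_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.n_presentations < 1:
            raise ConfigurationError("n_presentations must be >= 1")
        if not 0 < self.learning_rate_start <= 1 or not 0 <= self.learning_rate_end <= 1:
            raise ConfigurationError("learning rates must lie in (0, 1]")
        if self.radius_start < 0 or self.radius_end < 0:
            raise ConfigurationError("radii must be non-negative")
        if not 0 < self.radius_anneal_frac <= 1:
            raise ConfigurationError("radius_anneal_frac must lie in (0, 1]")


@dataclass
class TrajectoryMatrix:
    """Per-coarse-cell cover trajectories, one row per retained cell."""

    values: np.ndarray  # (n_cells, n_epochs)
    epochs: list[int]
    grid: Grid  # coarse grid
    cell_index: np.ndarray  # flat indices into the coarse grid, per row

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_index = np.asarray(self.cell_index, dtype=np.int64)
        if self.values.ndim != 2:
            raise ConfigurationError("trajectory matrix must be 2-D")
        if self.values.shape[0] != self.cell_index.size:
            raise ConfigurationError("row count != cell index count")
        if np.isnan(self.values).any():
            raise ConfigurationError("trajectory matrix contains NaN rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def labels_to_raster(self, labels: np.ndarray, nodata: int = -1) -> np.ndarray:
        """Scatter per-row labels back onto the coarse grid."""
        out = np.full(self.grid.n_rows * self.grid.n_cols, nodata, dtype=np.int64)
        out[self.cell_index] = labels
        return out.reshape(self.grid.shape)


def build_trajectory_matrix(
    series: CoverTimeSeries,
    factor: int = 10,
    apply_mask: bool = True,
    nonwoodland_cutoff: float = 0.05,
) -> TrajectoryMatrix:
    """Aggregate the series to the coarse grid and stack per-cell trajectories.

    With ``apply_mask`` (default) coarse cells whose aggregated cover is at
    or below ``nonwoodland_cutoff`` in every epoch are dropped, i.e. the
    persistent non-woodland rule re-applied at the coarse scale; cells with
    any nodata epoch are dropped too.
    """
    coarse_maps = [block_aggregate(m, factor) for m in series.maps]
    grid = coarse_maps[0].grid
    stack = np.stack([m.values for m in coarse_maps])  # (epochs, rows, cols)
    nod = np.stack([m.nodata_mask for m in coarse_maps])
    flat = stack.reshape(len(series.epochs), -1).T  # (cells, epochs)
    ok = ~nod.reshape(len(series.epochs), -1).T.any(axis=1)
    if apply_mask:
        with np.errstate(invalid="ignore"):
            persistent_low = np.nan_to_num(flat, nan=0.0) <= nonwoodland_cutoff
        ok &= ~persistent_low.all(axis=1)
    idx = np.flatnonzero(ok)
    return TrajectoryMatrix(flat[idx], list(series.epochs), grid, idx)


@dataclass
class ArchetypeModel:
    """Trained SOM: prototype trajectories, assignments, and provenance."""

    k: int
    codebook: np.ndarray  # (k, n_epochs)
    assignments: np.ndarray  # per-row node index
    quantization_error: float
    params: SomParams
    seed: int
    epochs: list[int]
    training_log: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _assign(np.asarray(X, dtype=np.float64), self.codebook)

    def codebook_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codebook, columns=[str(e) for e in self.epochs])
        df.insert(0, "node", np.arange(self.k))
        return df


def _init_codebook(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Prototypes from k data rows: a seeded random start followed by greedy
    farthest-point picks (max-min distance), so every well-separated group
    contributes a prototype; the rows are then laid along the chain in order
    of their first-principal-component score so that chain neighbors are
    data-space neighbors."""
    n_rows = X.shape[0]
    chosen = [int(rng.integers(0, n_rows))]
    d = np.linalg.norm(X - X[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
    codebook = X[chosen].copy()
    if k > 1:
        centered = codebook - codebook.mean(axis=0)
        vt = np.linalg.svd(centered, full_matrices=False)[2]
        codebook = codebook[np.argsort(centered @ vt[0], kind="stable")]
    return codebook


def _assign(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    d = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)  # argmin ties -> lowest index


def _quantization_error(X: np.ndarray, codebook: np.ndarray, assignments: np.ndarray) -> float:
    return float(np.linalg.norm(X - codebook[assignments], axis=1).mean())


def train_som(
    X: TrajectoryMatrix | np.ndarray,
    k: int,
    params: SomParams = SomParams(),
    seed: int = 0,
    k_bounds: tuple[int, int] = (3, 10),
    enforce_k_bounds: bool = True,
    log_every_pass: bool = False,
) -> ArchetypeModel:
    """Train the 1-D-chain SOM; deterministic under a fixed seed.

    ``k`` outside ``k_bounds`` raises unless ``enforce_k_bounds`` is off
    (tests exercise degenerate ks through that switch).
    """
    epochs: list[int] = []
    if isinstance(X, TrajectoryMatrix):
        epochs = list(X.epochs)
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ConfigurationError("training data must be 2-D")
    if np.isnan(X).any():
        raise ConfigurationError("training data contains NaN")
    n_rows = X.shape[0]
    if enforce_k_bounds and not k_bounds[0] <= k <= k_bounds[1]:
        raise ConfigurationError(f"k must be in [{k_bounds[0]}, {k_bounds[1]}], got {k}")
    if k < 1 or k > n_rows:
        raise ConfigurationError(f"k={k} must be in [1, n_rows={n_rows}]")

    rng = np.random.default_rng(seed)
    codebook = _init_codebook(X, k, rng)
    init_qe = _quantization_error(X, codebook, _assign(X, codebook))

    n_steps = params.n_presentations * n_rows
    order = np.concatenate(
        [rng.permutation(n_rows) for _ in range(params.n_presentations)]
    ).astype(np.int64)
    frac = np.arange(n_steps, dtype=np.float64) / max(n_steps - 1, 1)
    alphas = params.learning_rate_start + frac * (
        params.learning_rate_end - params.learning_rate_start
    )
    r0, r1 = params.radius_start, params.radius_end
    radii = np.maximum(r0 + (frac / params.radius_anneal_frac) * (r1 - r0), r1)

    log_rows = []
    if log_every_pass:
        for p in range(params.n_presentations):
            sl = slice(p * n_rows, (p + 1) * n_rows)
            _som_loop(X, codebook, order[sl], alphas[sl], radii[sl])
            qe = _quantization_error(X, codebook, _assign(X, codebook))
            log_rows.append({"pass": p, "quantization_error": qe})
    else:
        _som_loop(X, codebook, order, alphas, radii)

    assignments = _assign(X, codebook)
    qe = _quantization_error(X, codebook, assignments)
    model = ArchetypeModel(
        k=k,
        codebook=codebook,
        assignments=assignments,
        quantization_error=qe,
        params=params,
        seed=seed,
        epochs=epochs,
        training_log=pd.DataFrame(log_rows) if log_rows else None,
    )
    model.initial_quantization_error = init_qe  # type: ignore[attr-defined]
    return model


def select_cluster_count(
    X: TrajectoryMatrix | np.ndarray,
    k_range: Sequence[int] = range(3, 11),
    params: SomParams = SomParams(),
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Diagnostics per (k, seed): quantization error, mean silhouette, and
    empty-node count.

    The choice of k is reported, never applied automatically — the
    downstream default stays a config value.
    """
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ConfigurationError("k_range must not be empty")
    data = X.values if isinstance(X, TrajectoryMatrix) else np.asarray(X, dtype=np.float64)
    D = pairwise_distances(data)
    rows = []
    for seed in seeds:
        for k in k_range:
            model = train_som(X, k, params, seed=seed, enforce_k_bounds=False)
            occupied = np.unique(model.assignments)
            sil = (
                silhouette_score(model.assignments, D=D)
                if len(occupied) >= 2
                else np.nan
            )
            rows.append(
                {
                    "k": k,
                    "seed": int(seed),
                    "quantization_error": model.quantization_error,
                    "silhouette": sil,
                    "n_empty": int(k - len(occupied)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ArchetypeSummary:
    """Per-cluster extent, share, mean +- SD trajectory, and net area change."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def summarize_archetypes(
    model: ArchetypeModel,
    X: TrajectoryMatrix,
    area_unit: str = "map_units^2",
) -> ArchetypeSummary:
    """Per-cluster cell count, area, share of total, mean and population SD
    trajectory per epoch, and net fractional woodland-area change over the
    series (coarse-cell fractional accounting)."""
    if len(model.assignments) != X.n_rows:
        raise GridMismatchError("model assignments do not align with matrix rows")
    cell_area = X.grid.cell_area
    total = X.n_rows
    rows = []
    for node in range(model.k):
        sel = model.assignments == node
        n = int(sel.sum())
        if n == 0:
            continue
        sub = X.values[sel]
        area_start = float(sub[:, 0].sum() * cell_area)
        area_end = float(sub[:, -1].sum() * cell_area)
        for j, epoch in enumerate(X.epochs):
            rows.append(
                {
                    "archetype": node,
                    "epoch": int(epoch),
                    "n_cells": n,
                    "extent_area": n * cell_area,
                    "share_pct": 100.0 * n / total,
                    "mean_cover": float(sub[:, j].mean()),
                    "sd_cover": float(sub[:, j].std()),
                    "net_area_change": area_end - area_start,
                    "unit": area_unit,
                }
            )
    return ArchetypeSummary(pd.DataFrame(rows))
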