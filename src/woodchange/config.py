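"""Pipeline configuration: a single validated, YAML-loadable object whose
defaults reproduce the reference analysis settings (threshold sweep 15-22%,
screening floors OA 0.70 / UA 0.90, 10x10 coarse aggregation, k = 6
archetypes, 5% persistent non-woodland cutoff)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .archetypes import SomParams
from .errors import ConfigurationError
from .synth import DEFAULT_EPOCHS

_VALID_ENSEMBLE_MODES = ("as_printed", "weight_normalized")
_VALID_AREA_MODES = ("fractional_sum", "binary_threshold")


@dataclass
class PipelineConfig:
    # world geometry
    epochs: tuple[int, ...] = DEFAULT_EPOCHS
    cell_size: float = 300.0
    n_rows: int = 200
    n_cols: int = 200
    coarse_factor: int = 10
    n_ecoregions: int = 8
    spatial_corr_len: int = 5
    template_noise_sd: float = 0.05

    # sources (name, native_factor, representation, omission, commission, bias)
    sources: tuple[dict, ...] = (
        {"name": "fine_binary", "native_factor": 2, "representation": "binary",
         "omission_rate": 0.03, "commission_rate": 0.02},
        {"name": "fine_categorical", "native_factor": 2, "representation": "categorical",
         "omission_rate": 0.05, "commission_rate": 0.03},
        {"name": "same_grid_binary", "native_factor": 1, "representation": "binary",
         "omission_rate": 0.04, "commission_rate": 0.02},
        {"name": "coarse_fractional", "native_factor": 2, "representation": "fractional",
         "bias": 0.02},
        {"name": "noisy_binary", "native_factor": 1, "representation": "binary",
         "omission_rate": 0.30, "commission_rate": 0.25},
    )

    # validation
    n_validation_samples: int = 600
    validation_min_dist_cells: float = 2.0  # in analysis cells
    observer_noise_sd: float = 0.02
    threshold_sweep: tuple[int, ...] = tuple(range(15, 23))
    oa_min: float = 0.70
    ua_min: float = 0.90

    # ensemble / change
    ensemble_mode: str = "as_printed"
    area_mode: str = "fractional_sum"
    area_threshold_pct: float = 20.0
    nonwoodland_cutoff: float = 0.05

    # archetypes
    som_k: int = 6
    som_k_range: tuple[int, ...] = tuple(range(3, 11))
    som_params: SomParams = field(default_factory=SomParams)

    # megafauna
    n_threatened: int = 7
    n_nonthreatened: int = 7
    cover_affinity: float = 4.0
    threatened_names: tuple[str, ...] = ()
    nonthreatened_names: tuple[str, ...] = ()

    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.epochs) < 2:
            raise ConfigurationError("config needs at least two epochs")
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ConfigurationError("epochs must be strictly increasing")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid shape must be positive")
        if self.coarse_factor < 1:
            raise ConfigurationError("coarse_factor must be >= 1")
        if not self.threshold_sweep:
            raise ConfigurationError("threshold_sweep must not be empty")
        if any(not 0 < t <= 100 for t in self.threshold_sweep):
            raise ConfigurationError("sweep thresholds must lie in (0, 100]")
        if not 0 <= self.oa_min <= 1:
            raise ConfigurationError(f"oa_min must lie in [0, 1], got {self.oa_min}")
        if not 0 <= self.ua_min <= 1:
            raise ConfigurationError(f"ua_min must lie in [0, 1], got {self.ua_min}")
        if self.ensemble_mode not in _VALID_ENSEMBLE_MODES:
            raise ConfigurationError(
                f"ensemble_mode must be one of {_VALID_ENSEMBLE_MODES}"
            )
        if self.area_mode not in _VALID_AREA_MODES:
            raise ConfigurationError(f"area_mode must be one of {_VALID_AREA_MODES}")
        if not 0 <= self.nonwoodland_cutoff < 1:
            raise ConfigurationError("nonwoodland_cutoff must lie in [0, 1)")
        if self.som_k < 1:
            raise ConfigurationError("som_k must be >= 1")
        if isinstance(self.som_params, dict):
            self.som_params = SomParams(**self.som_params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["som_params"] = asdict(self.som_params)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("epochs", "threshold_sweep", "som_k_range",
                    "threatened_names", "nonthreatened_names"):
            if key in data and isinstance(data[key], Sequence):
                data[key] = tuple(data[key])
        if "sources" in data:
            data["sources"] = tuple(dict(s) for s in data["sources"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
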