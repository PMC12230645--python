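"""Single-band GeoTIFF read/write for the map types.

Backed by :mod:`tifffile`. Georeferencing is written with the standard
GeoTIFF ``ModelPixelScale`` and ``ModelTiepoint`` tags; everything tifffile
cannot express natively (CRS identifier, epoch year, class legend, nodata
value) goes into a JSON document in the ``ImageDescription`` tag, so files
round-trip losslessly through this module and stay readable by generic TIFF
tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError
from .grids import BinaryMap, CategoricalMap, FractionalCoverMap, Grid

__all__ = ["write_geotiff", "read_geotiff"]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

_KIND_FRACTIONAL = "fractional"
_KIND_BINARY = "binary"
_KIND_CATEGORICAL = "categorical"
_KIND_LABELS = "labels"


def _metadata(kind: str, amap, grid: Grid, nodata) -> dict:
    meta = {
        "woodchange": 1,
        "kind": kind,
        "crs_id": grid.crs_id,
        "nodata": nodata,
        "epoch_year": getattr(amap, "epoch_year", None),
    }
    if kind == _KIND_CATEGORICAL:
        meta["class_legend"] = {str(k): v for k, v in amap.class_legend.items()}
    return meta


def write_geotiff(path: str | Path, amap: FractionalCoverMap | BinaryMap | CategoricalMap) -> Path:
    """Write a map as a single-band striped GeoTIFF. Returns the path."""
    path = Path(path)
    grid = amap.grid
    if isinstance(amap, FractionalCoverMap):
        kind, nodata = _KIND_FRACTIONAL, float("nan")
        data = np.where(amap.nodata_mask, np.nan, amap.values).astype(np.float32)
    elif isinstance(amap, BinaryMap):
        kind, nodata = _KIND_BINARY, 255
        data = amap.values.astype(np.uint8)
        data[amap.nodata_mask] = 255
    elif isinstance(amap, CategoricalMap):
        kind, nodata = _KIND_CATEGORICAL, int(np.iinfo(np.int32).min)
        data = amap.values.astype(np.int32)
        data[amap.nodata_mask] = nodata
    else:
        raise ConfigurationError(f"cannot write object of type {type(amap).__name__}")

    meta = _metadata(kind, amap, grid, None if isinstance(nodata, float) else nodata)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
    ]
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=extratags,
        photometric="minisblack",
    )
    return path


def write_label_geotiff(path: str | Path, labels: np.ndarray, grid: Grid, nodata: int = -1) -> Path:
    """Write an integer label raster (e.g. ecoregions, archetype ids)."""
    path = Path(path)
    data = np.asarray(labels, dtype=np.int32)
    if data.shape != grid.shape:
        raise ConfigurationError(f"label shape {data.shape} != grid shape {grid.shape}")
    meta = {
        "woodchange": 1,
        "kind": _KIND_LABELS,
        "crs_id": grid.crs_id,
        "nodata": int(nodata),
        "epoch_year": None,
    }
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
    ]
    tifffile.imwrite(path, data, description=json.dumps(meta), extratags=extratags,
                     photometric="minisblack")
    return path


def _grid_from_tags(page, shape: tuple[int, int], crs_id: str) -> Grid:
    tags = page.tags
    try:
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
    except KeyError as exc:
        raise ConfigurationError("TIFF lacks GeoTIFF georeferencing tags") from exc
    return Grid(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        cell_size=float(scale[0]),
        n_rows=shape[0],
        n_cols=shape[1],
        crs_id=crs_id,
    )


def read_geotiff(path: str | Path):
    """Read a file written by this module back into the matching map type.

    Label rasters come back as ``(ndarray, Grid)``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
        if meta.get("woodchange") != 1:
            raise ConfigurationError(f"{path} was not written by woodchange")
        grid = _grid_from_tags(page, data.shape, meta.get("crs_id", "local"))

    kind = meta.get("kind")
    epoch = meta.get("epoch_year")
    if kind == _KIND_FRACTIONAL:
        values = data.astype(np.float64)
        return FractionalCoverMap(grid, values, np.isnan(values), epoch)
    if kind == _KIND_BINARY:
        mask = data == 255
        return BinaryMap(grid, (data == 1) & ~mask, mask, epoch)
    if kind == _KIND_CATEGORICAL:
        nodata = meta.get("nodata")
        mask = data == nodata
        legend = {int(k): v for k, v in meta.get("class_legend", {}).items()}
        values = data.astype(np.int64)
        values[mask] = next(iter(legend), 0)
        return CategoricalMap(grid, values, legend, mask, epoch)
    if kind == _KIND_LABELS:
        return np.asarray(data, dtype=np.int64), grid
    raise ConfigurationError(f"unknown map kind {kind!r} in {path}")
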