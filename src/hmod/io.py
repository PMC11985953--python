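"""File I/O: rasters as single-band TIFF + JSON grid sidecar, vectors as
GeoJSON, tables as CSV, registry/config as YAML.

A raster ``foo.tif`` is written as float32 (continuous) or int32
(categorical) with nodata encoded in the sidecar ``foo.tif.json`` together
with the grid geometry (shape, pixel size, top-left origin, CRS tag).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import CategoricalLayer, GridSpec, Layer

_FLOAT_NODATA = -9999.0


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _grid_meta(grid: GridSpec) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "pixel_size": grid.pixel_size,
        "origin_x": grid.origin_x,
        "origin_y": grid.origin_y,
        "crs_tag": grid.crs_tag,
    }


def _grid_from_meta(meta: dict) -> GridSpec:
    return GridSpec(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        pixel_size=float(meta["pixel_size"]),
        origin_x=float(meta["origin_x"]),
        origin_y=float(meta["origin_y"]),
        crs_tag=meta.get("crs_tag", "local"),
    )


def write_layer(layer: Layer, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = layer.values.astype(np.float32)
    vals = np.where(np.isfinite(vals), vals, np.float32(_FLOAT_NODATA))
    tifffile.imwrite(path, vals)
    meta = {
        "grid": _grid_meta(layer.grid),
        "nodata": _FLOAT_NODATA,
        "kind": layer.kind,
        "code": layer.code,
        "scope": layer.scope,
        "year": layer.year,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_layer(path) -> Layer:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    vals = tifffile.imread(path).astype(np.float64)
    vals[vals == meta["nodata"]] = np.nan
    return Layer(
        _grid_from_meta(meta["grid"]), vals,
        kind=meta.get("kind", "raw"),
        code=meta.get("code", ""),
        scope=meta.get("scope", "threat"),
        year=meta.get("year", "current"),
    )


def write_categorical(layer: CategoricalLayer, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, layer.values.astype(np.int32))
    meta = {
        "grid": _grid_meta(layer.grid),
        "nodata": int(layer.nodata),
        "labels": {str(k): v for k, v in layer.labels.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_categorical(path) -> CategoricalLayer:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    vals = tifffile.imread(path).astype(np.int64)
    labels = {int(k): v for k, v in meta.get("labels", {}).items()}
    return CategoricalLayer(_grid_from_meta(meta["grid"]), vals,
                            nodata=int(meta["nodata"]), labels=labels)


def write_geojson(data: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data))


def read_geojson(path) -> dict:
    return json.loads(Path(path).read_text())
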