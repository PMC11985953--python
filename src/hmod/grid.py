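"""Grid geometry and in-memory raster layers.

All layers in the toolkit live on a :class:`GridSpec`: a regular north-up
grid defined by its top-left corner, pixel size in metres and shape.
Continuous layers (footprints ``F`` and modification values ``H``) are held
as float64 arrays with NaN marking nodata; categorical layers use integer
arrays with an explicit nodata code.  Nodata is always flagged, never
encoded as 0, and propagates through arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


class AlignmentError(ValueError):
    """Raised when layers on different grids are combined."""


@dataclass(frozen=True)
class GridSpec:
    """Regular raster grid: shape, resolution and top-left origin.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; both >= 1.
    pixel_size:
        Pixel edge length in metres (> 0).  Pixel area in km^2 is
        ``(pixel_size / 1000) ** 2``.
    origin_x, origin_y:
        Map coordinates (metres) of the grid's top-left corner.
    crs_tag:
        Opaque coordinate-system label carried through I/O.
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2

    @property
    def width(self) -> float:
        return self.n_cols * self.pixel_size

    @property
    def height(self) -> float:
        return self.n_rows * self.pixel_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of shape ``shape``."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing map point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        r, c = self.index_of(x, y)
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols


def check_aligned(*grids: GridSpec) -> GridSpec:
    """Verify all grids are identical; return the shared grid."""
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise AlignmentError(f"grid mismatch: {g} != {first}")
    return first


@dataclass
class Layer:
    """Continuous raster layer (footprint or modification surface).

    ``values`` is float64 with NaN as nodata.  ``kind`` distinguishes
    footprint ("F"), modification ("H") and unconstrained rasters ("raw");
    F and H layers validate to [0, 1] on construction.
    """

    grid: GridSpec
    values: np.ndarray
    kind: str = "F"  # "F" | "H" | "raw"
    code: str = ""  # threat or threat-class taxonomy code
    scope: str = "threat"  # "threat" | "threat_class" | "cumulative"
    year: int | str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"layer shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind in ("F", "H"):
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError(
                    f"{self.kind} layer '{self.code}' has values outside [0, 1]: "
                    f"range [{finite.min():.6g}, {finite.max():.6g}]"
                )

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def with_values(self, values: np.ndarray, **meta) -> "Layer":
        out = replace(self, values=np.asarray(values, dtype=np.float64))
        for k, v in meta.items():
            setattr(out, k, v)
        out.__post_init__()
        return out

    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass
class CategoricalLayer:
    """Integer-coded raster (land cover, zones, classes, patch ids)."""

    grid: GridSpec
    values: np.ndarray
    nodata: int = -1
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical layer requires an integer array")
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"layer shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def classes(self) -> np.ndarray:
        v = self.values[self.values != self.nodata]
        return np.unique(v)


def footprint(grid: GridSpec, values: np.ndarray, code: str = "",
              year: int | str = "current") -> Layer:
    return Layer(grid, values, kind="F", code=code, year=year)


def modification(grid: GridSpec, values: np.ndarray, code: str = "",
                 scope: str = "threat", year: int | str = "current") -> Layer:
    return Layer(grid, values, kind="H", code=code, scope=scope, year=year)


def zeros(grid: GridSpec, kind: str = "F", **meta) -> Layer:
    return Layer(grid, np.zeros(grid.shape), kind=kind, **meta)


def aggregate_fraction(fine: CategoricalLayer, coarse_grid: GridSpec,
                       target_classes: Iterable[int]) -> Layer:
    """Exact proportion of fine cells in ``target_classes`` per coarse cell.

    The fine grid must nest evenly inside the coarse grid (same origin,
    integer resolution ratio), mirroring aggregation of 10/30 m class
    rasters to 90/300 m output pixels.
    """
    ratio = coarse_grid.pixel_size / fine.grid.pixel_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise AlignmentError(
            f"fine pixel size {fine.grid.pixel_size} does not nest in "
            f"coarse pixel size {coarse_grid.pixel_size}"
        )
    r = int(round(ratio))
    if (fine.grid.n_rows != coarse_grid.n_rows * r
            or fine.grid.n_cols != coarse_grid.n_cols * r
            or fine.grid.origin_x != coarse_grid.origin_x
            or fine.grid.origin_y != coarse_grid.origin_y):
        raise AlignmentError("fine grid does not tile the coarse grid evenly")
    target = np.isin(fine.values, np.asarray(list(target_classes)))
    valid = fine.values != fine.nodata
    blocks_t = target.reshape(coarse_grid.n_rows, r, coarse_grid.n_cols, r)
    blocks_v = valid.reshape(coarse_grid.n_rows, r, coarse_grid.n_cols, r)
    n_target = blocks_t.sum(axis=(1, 3)).astype(np.float64)
    n_valid = blocks_v.sum(axis=(1, 3)).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_target / np.maximum(n_valid, 1), np.nan)
    return footprint(coarse_grid, frac)


def block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean-aggregate a 2-D array by an integer factor (NaN-aware)."""
    n_r, n_c = values.shape
    if n_r % factor or n_c % factor:
        raise AlignmentError("array shape must be divisible by the block factor")
    b = values.reshape(n_r // factor, factor, n_c // factor, factor)
    with np.errstate(invalid="ignore"):
        return np.nanmean(b, axis=(1, 3))


def distance_to_true(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Euclidean distance (metres, center-to-center) to the nearest True pixel."""
    from scipy import ndimage

    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=pixel_size)
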