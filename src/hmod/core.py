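"""Aggregation and classification mathematics of the modification framework.

Per-threat modification is the product of footprint and intensity,
``H_t = F_t * I_t``.  Threats combine with the *increasive mean* (fuzzy
sum), ``H = 1 - prod(1 - H_t)``, which stays in [0, 1], exceeds the maximum
and the arithmetic mean of its inputs, and stays below their plain sum —
the right behaviour for partially dependent pressure layers.  Road types,
whose footprints are physically disjoint strips, are instead summed and
capped at 1.

Classification uses five modification classes with default breakpoints
0.01 / 0.1 / 0.4 / 0.7 (very low, low, moderate, high, very high); bins
are half-open [lo, hi) with the top bin closed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import AlignmentError, CategoricalLayer, Layer, check_aligned, modification
from .registry import IntensitySpec

CLASS_NAMES = ("very low", "low", "moderate", "high", "very high")


@dataclass(frozen=True)
class ClassThresholds:
    """Breakpoints separating the five modification classes."""

    breaks: tuple[float, ...] = (0.01, 0.1, 0.4, 0.7)

    def __post_init__(self) -> None:
        b = self.breaks
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError("need 4 strictly increasing breakpoints")

    @property
    def edges(self) -> np.ndarray:
        return np.array([0.0, *self.breaks, 1.0])


def modification_from_footprint(F: Layer, I: IntensitySpec | float | np.ndarray,
                                ) -> Layer:
    """H = F x I per pixel; nodata propagates.

    ``I`` may be a scalar intensity, an :class:`IntensitySpec` (its best
    estimate is used) or a co-registered intensity raster in [0, 1].
    """
    if isinstance(I, IntensitySpec):
        ival: float | np.ndarray = I.best
    elif isinstance(I, Layer):
        check_aligned(F.grid, I.grid)
        ival = I.values
    else:
        ival = np.asarray(I, dtype=np.float64)
        if ival.ndim == 2:
            if ival.shape != F.grid.shape:
                raise AlignmentError("intensity raster not co-registered with F")
        elif ival.ndim != 0:
            raise ValueError("intensity must be scalar or a 2-D raster")
    finite = np.asarray(ival)[np.isfinite(np.asarray(ival))] if np.ndim(ival) else np.asarray([ival])
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("intensity values must lie in [0, 1]")
    return modification(F.grid, F.values * ival, code=F.code or "", year=F.year)


def _stack(layers: Sequence[Layer]) -> np.ndarray:
    if not layers:
        raise ValueError("need at least one layer")
    check_aligned(*[l.grid for l in layers])
    return np.stack([l.values for l in layers])


def increasive_mean(layers: Sequence[Layer]) -> Layer:
    """Fuzzy-sum aggregation: H = 1 - prod(1 - H_t); nodata propagates."""
    stack = _stack(layers)
    vals = 1.0 - np.prod(1.0 - stack, axis=0)
    # guard tiny negative round-off
    vals = np.clip(vals, 0.0, 1.0)
    vals[np.any(~np.isfinite(stack), axis=0)] = np.nan
    return modification(layers[0].grid, vals, scope="cumulative",
                        year=layers[0].year)


def add_capped(layers: Sequence[Layer]) -> Layer:
    """Per-pixel sum clipped at 1.0 (physically disjoint strips, e.g. roads)."""
    stack = _stack(layers)
    vals = np.minimum(np.sum(stack, axis=0), 1.0)
    vals[np.any(~np.isfinite(stack), axis=0)] = np.nan
    return modification(layers[0].grid, vals, year=layers[0].year)


def combine_agriculture(H_ac: Layer, H_ap: Layer, H_ag: Layer) -> Layer:
    """Pixel-wise maximum of cropland, plantation and pasture H.

    The three agricultural footprints can overlap spatially (mixed-resolution
    sources), so the class layer takes the max rather than the fuzzy sum.
    """
    stack = _stack([H_ac, H_ap, H_ag])
    vals = np.max(stack, axis=0)
    vals[np.any(~np.isfinite(stack), axis=0)] = np.nan
    return modification(H_ac.grid, vals, code="2", scope="threat_class",
                        year=H_ac.year)


def dominant_threat(stack: Sequence[Layer]) -> CategoricalLayer:
    """Per-pixel arg-max threat class where any H > 0.

    Pixels where every layer is exactly 0 are nodata.  Ties break to the
    lowest taxonomy code (layers are sorted by code before the arg-max).
    """
    codes = [l.code for l in stack]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate class codes in dominant-threat stack")
    order = sorted(range(len(stack)), key=lambda i: _code_key(codes[i]))
    layers = [stack[i] for i in order]
    arr = _stack(layers)
    grid = layers[0].grid
    amax = np.nanargmax(np.where(np.isfinite(arr), arr, -np.inf), axis=0)
    best = np.take_along_axis(arr, amax[None], axis=0)[0]
    out = amax.astype(np.int64)
    nodata = -1
    out[~(best > 0.0)] = nodata
    out[np.any(~np.isfinite(arr), axis=0)] = nodata
    labels = {i: layers[i].code for i in range(len(layers))}
    return CategoricalLayer(grid, out, nodata=nodata, labels=labels)


def _code_key(code: str) -> tuple:
    try:
        return tuple(int(p) for p in str(code).split("."))
    except ValueError:
        return (float("inf"), str(code))


def classify_modification(H: Layer, thresholds: ClassThresholds | None = None,
                          ) -> tuple[CategoricalLayer, pd.DataFrame]:
    """Bin H into the five modification classes and tabulate class areas.

    Returns the class layer (codes 0..4) and a table with per-class pixel
    counts, area in km^2 and area fraction over valid pixels (sums to 1).
    """
    t = thresholds or ClassThresholds()
    edges = t.edges
    vals = H.values
    valid = np.isfinite(vals)
    # np.digitize with right=False gives half-open [lo, hi); fold the top
    # edge back so H == 1.0 lands in the closed top bin.
    cls = np.digitize(vals, edges[1:-1], right=False)
    cls = cls.astype(np.int64)
    cls[~valid] = -1
    layer = CategoricalLayer(H.grid, cls, nodata=-1,
                             labels=dict(enumerate(CLASS_NAMES)))
    n_valid = int(valid.sum())
    counts = [int(np.sum(cls == k)) for k in range(5)]
    area = H.grid.pixel_area_km2
    table = pd.DataFrame({
        "class_code": range(5),
        "class_name": CLASS_NAMES,
        "lower": edges[:-1],
        "upper": edges[1:],
        "n_pixels": counts,
        "area_km2": [c * area for c in counts],
        "fraction": [c / n_valid if n_valid else np.nan for c in counts],
    })
    return layer, table


def zonal_summary(H: Layer, zones: CategoricalLayer) -> pd.DataFrame:
    """Per-zone mean, population SD and area of valid H pixels."""
    check_aligned(H.grid, zones.grid)
    rows = []
    area = H.grid.pixel_area_km2
    for z in zones.classes():
        sel = (zones.values == z) & np.isfinite(H.values)
        n = int(sel.sum())
        vals = H.values[sel]
        rows.append({
            "zone": int(z),
            "mean": float(vals.mean()) if n else np.nan,
            "sd": float(vals.std()) if n else np.nan,  # population SD
            "n_pixels": n,
            "area_km2": n * area,
        })
    return pd.DataFrame(rows)


def threat_count(stack: Sequence[Layer], tau: float = 0.0) -> CategoricalLayer:
    """Per-pixel count of footprint layers with F > tau."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    arr = _stack(stack)
    counts = np.sum(np.where(np.isfinite(arr), arr > tau, False), axis=0)
    out = counts.astype(np.int64)
    out[np.all(~np.isfinite(arr), axis=0)] = -1
    return CategoricalLayer(stack[0].grid, out, nodata=-1)
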