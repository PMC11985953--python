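"""Timber-harvest (biological resource use) footprint.

A pixel counts as harvested when it lost forest in or before the mapping
year, its canopy stood at least 10 m tall in the 2000 baseline (guarding
against commission errors in the loss product), and the loss year does not
coincide with a wildfire burn year (fire losses are not harvest).  Loss is
cumulative: regrowth is ignored, so the footprint can only grow with the
mapping year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import CategoricalLayer, GridSpec, Layer, aggregate_fraction, check_aligned, footprint

log = logging.getLogger(__name__)


@dataclass
class ForestStack:
    """Co-registered forest-loss year, 2000 canopy height and burn year.

    ``loss_year`` and ``burn_year`` use 0 for "never"; heights in metres.
    """

    loss_year: CategoricalLayer
    height_2000: Layer
    burn_year: CategoricalLayer

    def __post_init__(self) -> None:
        check_aligned(self.loss_year.grid, self.height_2000.grid,
                      self.burn_year.grid)
        ly = self.loss_year.values
        valid = (ly != self.loss_year.nodata) & (ly != 0)
        if valid.any() and ((ly[valid] < 1990) | (ly[valid] > 2030)).any():
            raise ValueError("loss years must lie in [1990, 2030] (0 = none)")
        h = self.height_2000.values
        if np.nanmin(h) < 0:
            raise ValueError("canopy height must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return self.loss_year.grid


def harvest_footprint(stack: ForestStack, map_year: int,
                      min_height: float = 10.0,
                      burn_tolerance_years: int = 0,
                      out_grid: GridSpec | None = None) -> Layer:
    """Binary harvest footprint for ``map_year``, optionally aggregated.

    F = 1 where 0 < loss_year <= map_year, height_2000 >= min_height and
    |burn_year - loss_year| > burn_tolerance_years (or never burned);
    else 0.  When ``out_grid`` is coarser than the stack, the indicator is
    aggregated to the exact fraction of fine pixels harvested.
    """
    ly = stack.loss_year.values
    by = stack.burn_year.values
    h = stack.height_2000.values
    lost = (ly > 0) & (ly <= map_year)
    tall = h >= min_height
    fire = (by > 0) & (np.abs(by - ly) <= burn_tolerance_years)
    harvested = lost & tall & ~fire
    if not lost.any():
        log.warning("no forest loss at or before %d; footprint is zero",
                    map_year)
    vals = harvested.astype(np.float64)
    vals[~np.isfinite(h)] = np.nan
    vals[ly == stack.loss_year.nodata] = np.nan
    if out_grid is not None and out_grid != stack.grid:
        indicator = CategoricalLayer(
            stack.grid, harvested.astype(np.int64), nodata=-9)
        agg = aggregate_fraction(indicator, out_grid, [1])
        agg.code, agg.year = "5.3", map_year
        return agg
    return footprint(stack.grid, vals, code="5.3", year=map_year)
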