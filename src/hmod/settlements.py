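"""Footprint builders for built-up (threat class 1) and agriculture (class 2).

Multi-source built-up and cropland fractions are fused with the weighted
fuzzy sum ``F = 1 - prod(1 - f_i * w_i)``, where each source weight w_i
reflects its classification accuracy (built-up defaults 0.9/0.8/0.8;
cropland 0.9/0.5/0.3/0.5).  Built-up is partitioned into residential,
commercial/industrial and tourism/recreation threats by land-use polygon
overlay.  Pasture footprints are patch means of square-root-transformed
livestock density, broadcast over 8-connected land-cover patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import (CategoricalLayer, GridSpec, Layer, check_aligned,
                   distance_to_true, footprint)
from .infrastructure import rasterize_lengths
from .vectors import LinearFeatureSet, PolygonSet

log = logging.getLogger(__name__)

#: rotation class -> cropland intensity (single / double / triple cropping)
ROTATION_INTENSITY = {1: 0.39, 2: 0.53, 3: 0.67}

#: per-continent 99th-percentile cropland elevation cut-offs (m) from the
#: global product; optional alternative to percentiles computed per region
GLOBAL_ELEVATION_CUTOFFS = {
    "africa": 2575.0,
    "euro_asia_oceania": 2319.0,
    "north_america": 2365.0,
    "south_america": 3407.0,
}

#: default source weights
BUILTUP_WEIGHTS = {"WC": 0.9, "GHSL": 0.8, "GISA": 0.8}
CROPLAND_WEIGHTS = {"GCD": 0.9, "GCP": 0.5, "GCI": 0.3, "CCI": 0.5}

LIVESTOCK_DENSITY_CAP = 1000.0  # animal units / km^2


@dataclass
class WeightedSource:
    """A fractional-cover source layer with an accuracy weight in [0, 1]."""

    fraction: Layer
    weight: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight for '{self.label}' must lie in [0, 1]")


def fuse_weighted_sources(sources: Sequence[WeightedSource]) -> Layer:
    """Weighted fuzzy-sum fusion: F = 1 - prod(1 - f_i * w_i)."""
    if not sources:
        raise ValueError("need at least one source")
    check_aligned(*[s.fraction.grid for s in sources])
    stack = np.stack([s.fraction.values * s.weight for s in sources])
    vals = 1.0 - np.prod(1.0 - stack, axis=0)
    vals = np.clip(vals, 0.0, 1.0)
    vals[np.any(~np.isfinite(stack), axis=0)] = np.nan
    return footprint(sources[0].fraction.grid, vals)


def _polygon_mask(polygons: PolygonSet | None, grid: GridSpec) -> np.ndarray:
    """Boolean mask of pixels whose center falls inside any polygon."""
    import shapely

    mask = np.zeros(grid.shape, dtype=bool)
    if polygons is None or not len(polygons):
        return mask
    cx, cy = grid.cell_centers()
    pts = shapely.points(cx.ravel(), cy.ravel())
    union = polygons.union()
    mask = shapely.contains(union, pts).reshape(grid.shape)
    return mask


def partition_builtup(F_b: Layer, commercial: PolygonSet | None,
                      tourism: PolygonSet | None,
                      ) -> tuple[Layer, Layer, Layer]:
    """Split built-up into residential / commercial / tourism footprints.

    Pixels overlapped by commercial polygons feed F_bc, remaining pixels
    overlapped by tourism polygons feed F_bt, everything else is
    residential F_br; commercial takes priority where polygon sets
    overlap.  Mass is conserved: F_br + F_bc + F_bt == F_b per pixel.
    """
    com = _polygon_mask(commercial, F_b.grid)
    tou = _polygon_mask(tourism, F_b.grid) & ~com
    res = ~(com | tou)
    def part(mask, code):
        vals = np.where(mask, F_b.values, 0.0)
        vals[~np.isfinite(F_b.values)] = np.nan
        return footprint(F_b.grid, vals, code=code, year=F_b.year)
    return part(res, "1.1"), part(com, "1.2"), part(tou, "1.3")


def cropland_footprint(sources: Sequence[WeightedSource],
                       urban_mask: CategoricalLayer | None = None,
                       elevation: Layer | None = None,
                       region_ids: CategoricalLayer | None = None,
                       urban_buffer_m: float = 1000.0,
                       percentile: float = 99.0) -> Layer:
    """Fused cropland footprint with urban-buffer and elevation filters.

    Sources are fused as in :func:`fuse_weighted_sources`; pixels within
    ``urban_buffer_m`` of an urban-class pixel are zeroed (urban parks and
    golf courses misread as cropland), and primary-source cropland above
    the per-region ``percentile`` of cropland-pixel elevations is removed
    (alpine commission errors).
    """
    fused = fuse_weighted_sources(sources)
    vals = fused.values.copy()
    if urban_mask is not None:
        check_aligned(fused.grid, urban_mask.grid)
        urban = (urban_mask.values == 1)
        dist = distance_to_true(urban, fused.grid.pixel_size)
        vals[dist <= urban_buffer_m] = 0.0
    if elevation is not None:
        if region_ids is None:
            raise ValueError("elevation filter requires region ids")
        check_aligned(fused.grid, elevation.grid, region_ids.grid)
        primary = sources[0].fraction.values
        crop = np.isfinite(primary) & (primary > 0)
        for region in region_ids.classes():
            in_region = region_ids.values == region
            sample = elevation.values[in_region & crop]
            if sample.size == 0:
                continue
            cutoff = np.percentile(sample, percentile)
            vals[in_region & crop & (elevation.values > cutoff)] = 0.0
    return footprint(fused.grid, vals, code="2.1")


def rotation_intensity_surface(rot: CategoricalLayer,
                               fill_radius: float = 20000.0,
                               smooth_radius_px: int = 2) -> Layer:
    """Cropping-rotation intensity raster with modal fill and smoothing.

    Classes 1/2/3 (single/double/triple cropping) map to intensities
    0.39/0.53/0.67.  Nodata pixels are filled with the modal class within
    ``fill_radius`` metres, then the surface is mean-smoothed with a
    circular window of ``smooth_radius_px`` pixels.
    """
    vals = rot.values
    known = (vals != rot.nodata) & np.isin(vals, list(ROTATION_INTENSITY))
    if not known.any():
        log.warning("rotation raster has no valid classes; returning nodata")
        return Layer(rot.grid, np.full(rot.grid.shape, np.nan), kind="raw")
    filled = vals.copy()
    missing = ~known
    if missing.any():
        filled = _modal_fill(vals, known, rot.grid.pixel_size, fill_radius)
    inten = np.full(rot.grid.shape, np.nan)
    for cls, i in ROTATION_INTENSITY.items():
        inten[filled == cls] = i
    # circular mean smoothing
    r = smooth_radius_px
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    win = (yy ** 2 + xx ** 2 <= r ** 2).astype(float)
    valid = np.isfinite(inten)
    padded = np.where(valid, inten, 0.0)
    num = ndimage.convolve(padded, win, mode="nearest")
    den = ndimage.convolve(valid.astype(float), win, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        smooth = np.where(den > 0, num / den, np.nan)
    smooth[~valid] = np.nan
    return Layer(rot.grid, smooth, kind="raw")


def _modal_fill(vals: np.ndarray, known: np.ndarray, pixel_size: float,
                fill_radius: float) -> np.ndarray:
    """Fill unknown pixels with the modal known class within a radius."""
    from scipy.signal import fftconvolve

    r_px = max(1, int(round(fill_radius / pixel_size)))
    yy, xx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
    win = (yy ** 2 + xx ** 2 <= r_px ** 2).astype(float)
    classes = sorted(ROTATION_INTENSITY)
    counts = np.stack([
        fftconvolve((known & (vals == cls)).astype(float), win, mode="same")
        for cls in classes
    ])
    counts = np.where(counts > 0.5, counts, 0.0)  # round FFT noise down
    best = np.argmax(counts, axis=0)
    any_known = counts.sum(axis=0) > 0
    fill = np.asarray(classes)[best]
    out = vals.copy()
    missing = ~known
    out[missing & any_known] = fill[missing & any_known]
    return out


def plantation_footprint(plantation_mask: CategoricalLayer,
                         canopy_fraction: Layer,
                         type_map: CategoricalLayer | None = None,
                         tree_crop_intensity: float = 0.30,
                         planted_forest_intensity: float = 0.06,
                         ) -> tuple[Layer, Layer]:
    """Plantation footprint (mask x canopy cover) and intensity raster.

    ``type_map`` distinguishes tree crops (class 1, intensity 0.30) from
    planted forest (class 2, intensity 0.06); without it, tree-crop
    intensity applies everywhere.
    """
    check_aligned(plantation_mask.grid, canopy_fraction.grid)
    mask = (plantation_mask.values == 1).astype(float)
    vals = mask * canopy_fraction.values
    inten = np.full(plantation_mask.grid.shape, tree_crop_intensity)
    if type_map is not None:
        check_aligned(plantation_mask.grid, type_map.grid)
        inten[type_map.values == 2] = planted_forest_intensity
    F = footprint(plantation_mask.grid, np.clip(vals, 0.0, 1.0), code="2.2")
    return F, Layer(plantation_mask.grid, inten, kind="raw")


def label_patches(landcover: CategoricalLayer, classes: Sequence[int],
                  ) -> CategoricalLayer:
    """8-connected patches of each land-cover class; 0 = background.

    Patch ids are unique across classes (labelled per class, offset).
    """
    struct = np.ones((3, 3), dtype=bool)
    out = np.zeros(landcover.grid.shape, dtype=np.int64)
    offset = 0
    for cls in classes:
        mask = landcover.values == cls
        lab, n = ndimage.label(mask, structure=struct)
        out[mask] = lab[mask] + offset
        offset += n
    return CategoricalLayer(landcover.grid, out, nodata=0)


def livestock_fraction(density: Layer, cap: float = LIVESTOCK_DENSITY_CAP,
                       ) -> np.ndarray:
    """f_gp = sqrt(min(density, cap) / cap); density in animal units/km^2."""
    vals = density.values
    if np.nanmin(vals) < 0:
        raise ValueError("livestock density must be >= 0")
    return np.sqrt(np.minimum(vals, cap) / cap)


def pasture_footprint(landcover: CategoricalLayer,
                      grazing_classes: Sequence[int],
                      sparse_classes: Sequence[int],
                      density: Layer,
                      major_roads: LinearFeatureSet | None = None,
                      cap: float = LIVESTOCK_DENSITY_CAP) -> Layer:
    """Patch-mean livestock footprint over grazing land-cover patches.

    f_gp = sqrt(min(density, 1000)/1000) is averaged within each
    8-connected patch of each grazing class (pixels crossed by major
    roads are dropped from the average) and the mean is broadcast to the
    whole patch.  Sparse-cover pixels join the footprint only where their
    density lies within the central 95% ([2.5%, 97.5%] quantiles) of
    densities seen on the grazed classes.
    """
    if set(grazing_classes) & set(sparse_classes):
        raise ValueError("grazing and sparse class sets must be disjoint")
    check_aligned(landcover.grid, density.grid)
    f_gp = livestock_fraction(density, cap)
    grid = landcover.grid
    road_mask = np.zeros(grid.shape, dtype=bool)
    if major_roads is not None and len(major_roads):
        lengths = rasterize_lengths(
            major_roads.of_type("highway").geometries, grid)
        road_mask = lengths > 0
    out = np.zeros(grid.shape)
    patches = label_patches(landcover, grazing_classes)
    lab = patches.values
    for pid in np.unique(lab[lab > 0]):
        sel = lab == pid
        keep = sel & ~road_mask & np.isfinite(f_gp)
        sample = f_gp[keep if keep.any() else sel & np.isfinite(f_gp)]
        out[sel] = sample.mean() if sample.size else 0.0
    # sparse classes: include where density falls inside the grazed range
    grazed = np.isin(landcover.values, np.asarray(grazing_classes))
    dens_on_grazed = density.values[grazed & np.isfinite(density.values)]
    if dens_on_grazed.size and sparse_classes:
        lo, hi = np.percentile(dens_on_grazed, [2.5, 97.5])
        sparse = np.isin(landcover.values, np.asarray(sparse_classes))
        ok = sparse & (density.values >= lo) & (density.values <= hi)
        out[ok] = f_gp[ok]
    out[~np.isfinite(density.values)] = np.nan
    return footprint(grid, np.clip(out, 0.0, 1.0), code="2.3")
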