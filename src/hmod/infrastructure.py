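"""Footprint builders for linear, point and areal infrastructure threats.

Linear transport features are rasterized *fractionally*: the footprint of a
pixel is (length of feature inside the pixel x corridor width) / pixel
area, capped at 1.  For a straight feature fully crossing a pixel this
reduces to width / pixel_size — a 40 m highway in a 90 m pixel occupies
4/9 of it, not the whole pixel.

Point threats (gas flares, trails) use a linear-decay cone kernel: value
``peak * (1 - d/R)`` to radius R (default 233 m), whose planar integral is
pi R^2 / 3 ~ 0.057 km^2 per well-head.  Powerlines use the same decay from
the line (default radius 250 m, peak 0.25 reflecting positional
uncertainty).  Overlapping kernels combine by per-pixel maximum so a single
land transformation is not double-counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString

from .core import add_capped, modification_from_footprint
from .grid import CategoricalLayer, GridSpec, Layer, check_aligned, footprint
from .registry import IntensitySpec
from .vectors import LinearFeatureSet, PointSet, PolygonSet

log = logging.getLogger(__name__)

#: transport intensity best estimates by feature type
TRANSPORT_INTENSITY = {
    "highway": 0.81,
    "secondary": 0.76,
    "residential": 0.66,
    "track": 0.09,
    "rail": 0.76,
}


@dataclass(frozen=True)
class DecayKernelSpec:
    """Linear-decay cone: value peak at d=0 falling to 0 at d=radius."""

    radius: float = 233.0  # metres
    peak: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("kernel radius must be > 0")
        if not (0.0 < self.peak <= 1.0):
            raise ValueError("kernel peak must lie in (0, 1]")

    def evaluate(self, d: np.ndarray) -> np.ndarray:
        return self.peak * np.maximum(0.0, 1.0 - d / self.radius)

    @property
    def integral_km2(self) -> float:
        """Planar integral of the cone, in km^2: peak * pi R^2 / 3."""
        return self.peak * math.pi * (self.radius / 1000.0) ** 2 / 3.0


FLARE_KERNEL = DecayKernelSpec(radius=233.0, peak=1.0)
TRAIL_KERNEL = DecayKernelSpec(radius=233.0, peak=1.0)
POWERLINE_KERNEL = DecayKernelSpec(radius=250.0, peak=0.25)


def _accumulate_segment(lengths: np.ndarray, grid: GridSpec,
                        x0: float, y0: float, x1: float, y1: float) -> None:
    """Add exact in-pixel lengths (metres) of one segment to ``lengths``."""
    px = grid.pixel_size
    u0, u1 = (x0 - grid.origin_x) / px, (x1 - grid.origin_x) / px
    v0, v1 = (grid.origin_y - y0) / px, (grid.origin_y - y1) / px
    seg_len = math.hypot(x1 - x0, y1 - y0)
    if seg_len == 0.0:
        return
    ts = [0.0, 1.0]
    du, dv = u1 - u0, v1 - v0
    if du != 0.0:
        lo, hi = sorted((u0, u1))
        for k in range(math.ceil(lo), math.floor(hi) + 1):
            t = (k - u0) / du
            if 0.0 < t < 1.0:
                ts.append(t)
    if dv != 0.0:
        lo, hi = sorted((v0, v1))
        for k in range(math.ceil(lo), math.floor(hi) + 1):
            t = (k - v0) / dv
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(set(ts))
    for a, b in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (a + b)
        col = int(math.floor(u0 + tm * du))
        row = int(math.floor(v0 + tm * dv))
        if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
            lengths[row, col] += (b - a) * seg_len


def rasterize_lengths(geometries: Sequence[LineString], grid: GridSpec,
                      ) -> np.ndarray:
    """Exact per-pixel total length (metres) of line features."""
    lengths = np.zeros(grid.shape)
    n_zero = 0
    for geom in geometries:
        if geom.is_empty or geom.length == 0.0:
            n_zero += 1
            continue
        parts = geom.geoms if geom.geom_type == "MultiLineString" else [geom]
        for part in parts:
            coords = np.asarray(part.coords)
            for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
                _accumulate_segment(lengths, grid, x0, y0, x1, y1)
    if n_zero:
        log.info("skipped %d zero-length geometries", n_zero)
    return lengths


def linear_footprint(features: LinearFeatureSet, grid: GridSpec,
                     ftype: str) -> Layer:
    """Fractional footprint of one transport type: length x width / area."""
    subset = features.of_type(ftype)
    width = features.width_of(ftype)
    lengths = rasterize_lengths(subset.geometries, grid)
    area_m2 = grid.pixel_size ** 2
    vals = np.minimum(lengths * width / area_m2, 1.0)
    return footprint(grid, vals, code="4.1")


def transport_modification(per_type_F: dict[str, Layer],
                           intensities: dict[str, float | IntensitySpec] | None = None,
                           ) -> Layer:
    """Per-type H = F x I, summed across types and capped at 1.0."""
    if not per_type_F:
        raise ValueError("need at least one transport footprint")
    inten = intensities or TRANSPORT_INTENSITY
    hs = []
    for ftype, F in per_type_F.items():
        i = inten[ftype]
        hs.append(modification_from_footprint(F, i))
    out = add_capped(hs)
    out.code = "4.1"
    return out


def residential_road_filter(features: LinearFeatureSet, settlements: Layer,
                            max_dist: float = 5000.0) -> LinearFeatureSet:
    """Re-type residential roads far from any settlement as two-track.

    A residential feature is kept if any of its vertices falls within
    ``max_dist`` metres of a pixel with positive settlement footprint;
    otherwise it is re-attributed as "track" (remote mis-attributions).
    """
    from .grid import distance_to_true

    mask = np.isfinite(settlements.values) & (settlements.values > 0)
    dist = distance_to_true(mask, settlements.grid.pixel_size)
    far: list[int] = []
    for i, (geom, ftype) in enumerate(zip(features.geometries, features.types)):
        if ftype != "residential":
            continue
        near = False
        for x, y in np.asarray(geom.coords):
            r, c = settlements.grid.index_of(x, y)
            r = min(max(r, 0), settlements.grid.n_rows - 1)
            c = min(max(c, 0), settlements.grid.n_cols - 1)
            if dist[r, c] <= max_dist:
                near = True
                break
        if not near:
            far.append(i)
    if far:
        log.info("re-typed %d residential roads as track", len(far))
    return features.retype(far, "track")


def kernel_point_footprint(points: PointSet, spec: DecayKernelSpec,
                           grid: GridSpec) -> Layer:
    """Cone-kernel footprint around points, combined by per-pixel maximum."""
    vals = np.zeros(grid.shape)
    if len(points):
        cx, cy = grid.cell_centers()
        for x, y in zip(points.xs, points.ys):
            d = np.hypot(cx - x, cy - y)
            np.maximum(vals, spec.evaluate(d), out=vals)
    return footprint(grid, np.clip(vals, 0.0, 1.0))


def kernel_line_footprint(lines: LinearFeatureSet | Sequence[LineString],
                          spec: DecayKernelSpec, grid: GridSpec) -> Layer:
    """Cone-kernel footprint from the nearest point on any line."""
    geoms = lines.geometries if isinstance(lines, LinearFeatureSet) else list(lines)
    vals = np.zeros(grid.shape)
    if geoms:
        cx, cy = grid.cell_centers()
        centers = shapely.points(cx.ravel(), cy.ravel())
        union = shapely.union_all(geoms)
        d = shapely.distance(centers, union).reshape(grid.shape)
        vals = spec.evaluate(d)
    return footprint(grid, np.clip(vals, 0.0, 1.0))


def polygon_cover_fraction(geometry, grid: GridSpec) -> np.ndarray:
    """Exact per-pixel fraction of area covered by a (multi)polygon."""
    vals = np.zeros(grid.shape)
    if geometry is None or geometry.is_empty:
        return vals
    px = grid.pixel_size
    minx, miny, maxx, maxy = geometry.bounds
    c0 = max(0, int(math.floor((minx - grid.origin_x) / px)))
    c1 = min(grid.n_cols - 1, int(math.floor((maxx - grid.origin_x) / px)))
    r0 = max(0, int(math.floor((grid.origin_y - maxy) / px)))
    r1 = min(grid.n_rows - 1, int(math.floor((grid.origin_y - miny) / px)))
    if c1 < c0 or r1 < r0:
        return vals
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    x0 = grid.origin_x + cc * px
    y1 = grid.origin_y - rr * px
    boxes = shapely.box(x0.ravel(), (y1 - px).ravel(),
                        (x0 + px).ravel(), y1.ravel())
    areas = shapely.area(shapely.intersection(boxes, geometry))
    vals[rr.ravel(), cc.ravel()] = areas / (px * px)
    return vals


def areal_footprint(polygons: PolygonSet | None, grid: GridSpec,
                    points: PointSet | None = None,
                    point_area_km2: float = 0.0) -> Layer:
    """Footprint of areal threats: polygon cover or fixed per-point area.

    Polygons contribute their exact per-pixel cover fraction.  Points
    (e.g. wind turbines, footprint 0.0014 km^2 each) deposit
    ``point_area_km2 / pixel_area`` into their containing pixel, capped at 1.
    """
    vals = np.zeros(grid.shape)
    if polygons is not None and len(polygons):
        vals = polygon_cover_fraction(polygons.union(), grid)
    if points is not None and len(points):
        if point_area_km2 < 0:
            raise ValueError("point area must be >= 0")
        frac = point_area_km2 / grid.pixel_area_km2
        for x, y in zip(points.xs, points.ys):
            if grid.contains(x, y):
                r, c = grid.index_of(x, y)
                vals[r, c] += frac
    return footprint(grid, np.clip(vals, 0.0, 1.0))


def nightlights_footprint(raster: Layer, platform: str) -> Layer:
    """Normalize nighttime-light emissions to a [0, 1] footprint.

    DMSP digital numbers saturate at 63, so F = DN / 63.  VIIRS radiance is
    log10(x + 1)-transformed then divided by the global 95th-percentile
    value of the transform (1.05).
    """
    vals = raster.values
    if np.nanmin(vals) < 0:
        raise ValueError("nightlight values must be >= 0")
    if platform == "dmsp":
        out = vals / 63.0
    elif platform == "viirs":
        out = np.log10(vals + 1.0) / 1.05
    else:
        raise ValueError("platform must be 'dmsp' or 'viirs'")
    return footprint(raster.grid, np.clip(out, 0.0, 1.0), code="4.2",
                     year=raster.year)


def no2_footprint(raster: Layer, norm: float = 0.0003) -> Layer:
    """NO2 column density max-normalized by its 99th-percentile value."""
    vals = raster.values
    if np.nanmin(vals) < 0:
        raise ValueError("NO2 column values must be >= 0")
    return footprint(raster.grid, np.clip(vals / norm, 0.0, 1.0), code="9.5",
                     year=raster.year)


def reservoir_footprint(reservoirs: PolygonSet, water_mask: CategoricalLayer,
                        grid: GridSpec, exclusions: Sequence[int] = (),
                        buffer_m: float = 1000.0) -> Layer:
    """Cover fraction of reservoirs buffered by 1 km, minus open water.

    The buffer captures shoreline modification; masking by the water layer
    removes artifacts from varying water levels.  Polygons listed in
    ``exclusions`` (natural lakes misattributed as reservoirs) are dropped.
    """
    check_aligned(water_mask.grid, grid)
    kept = reservoirs.drop_ids(exclusions)
    vals = np.zeros(grid.shape)
    if len(kept):
        geom = shapely.buffer(kept.union(), buffer_m)
        vals = polygon_cover_fraction(geom, grid)
    vals[water_mask.values == 1] = 0.0
    return footprint(grid, np.clip(vals, 0.0, 1.0), code="7.2")


def enforce_monotone_series(series: Sequence[Layer]) -> list[Layer]:
    """Running per-pixel maximum over a year-sorted footprint series.

    Permanent-infrastructure threats (wells, nightlit areas) can only grow:
    the footprint at year t is the maximum over all years <= t.
    """
    if not series:
        raise ValueError("empty series")
    check_aligned(*[l.grid for l in series])
    out: list[Layer] = []
    running = series[0].values.copy()
    out.append(series[0].with_values(running.copy()))
    for layer in series[1:]:
        running = np.fmax(running, layer.values)
        out.append(layer.with_values(running.copy()))
    return out
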