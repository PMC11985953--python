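"""Seeded synthetic-landscape generator.

Produces complete, schema-valid input bundles (rasters, vector features and
a threat registry) on small grids so that every pipeline stage can run
without external downloads.  Land cover comes from Gaussian-smoothed white
noise thresholded at the configured class-mixture quantiles, which yields
contiguous patches (exercising the patch-mean pasture logic).  Settlements
seed population and built-up fields; roads are random polylines per type;
point and polygon threats are placed uniformly.  All randomness flows from
one seed, so a bundle is reproducible bit-for-bit.

The generator emulates the *structure* of real inputs (value ranges,
formats, spatial coherence), not real geography or the error structure of
any specific source product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon

from .forestry import ForestStack
from .grid import CategoricalLayer, GridSpec, Layer, footprint
from .registry import ThreatRegistry, default_registry
from .sensitivity import ReferencePlotSet
from .vectors import DEFAULT_WIDTHS, LinearFeatureSet, PointSet, PolygonSet

# land-cover codebook used by the generator and the pipeline defaults
LC_OPEN = 1        # grassland / open (grazing)
LC_SHRUB = 2       # shrubland (grazing)
LC_FOREST = 3
LC_SPARSE = 4      # sparse vegetation (conditional grazing)
LC_WETLAND = 5
LC_WATER = 6
LC_URBAN = 7
LC_CROP = 8

GRAZING_CLASSES = (LC_OPEN, LC_SHRUB)
SPARSE_CLASSES = (LC_SPARSE,)

#: default off-road travel factors (min/km) for the generator's codebook
OFFROAD_FACTORS = {
    LC_OPEN: 60.0, LC_SHRUB: 60.0, LC_FOREST: 120.0, LC_SPARSE: 60.0,
    LC_WETLAND: 200.0, LC_WATER: 167.0, LC_URBAN: 60.0, LC_CROP: 60.0,
}


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape; the defaults are the test bed.

    ``class_mixture`` gives target area proportions of the non-urban,
    non-crop land-cover classes (urban and cropland are carved out around
    settlements and in lowland patches afterwards).  Densities are in
    features per 100 km^2 except roads, which are counts of cross-grid
    polylines per type.
    """

    n_rows: int = 256
    n_cols: int = 256
    pixel_size: float = 90.0
    seed: int = 0
    class_mixture: dict[int, float] = field(default_factory=lambda: {
        LC_OPEN: 0.30, LC_SHRUB: 0.15, LC_FOREST: 0.30,
        LC_SPARSE: 0.10, LC_WETLAND: 0.05, LC_WATER: 0.05,
    })
    crop_fraction: float = 0.12
    n_settlements: int = 4
    population_log_range: tuple[float, float] = (6.0, 11.0)  # ln(people)
    roads_per_type: dict[str, int] = field(default_factory=lambda: {
        "highway": 2, "secondary": 3, "residential": 6, "track": 4,
        "rail": 1,
    })
    n_powerlines: int = 2
    n_trails: int = 3
    n_wells: int = 12
    n_turbines: int = 6
    n_mines: int = 2
    n_reservoirs: int = 2
    n_landfills: int = 2
    forest_loss_fraction_per_year: float = 0.004
    burn_fraction: float = 0.15  # share of loss years that coincide with fire
    nightlight_peak_dn: float = 60.0
    no2_peak: float = 0.00025
    livestock_density_mean: float = 120.0  # au/km^2 on grazed land
    smoothness_px: float = 6.0

    def __post_init__(self) -> None:
        if sum(self.class_mixture.values()) > 1.0 + 1e-9:
            raise ValueError("class mixture proportions must sum to <= 1")
        if self.n_settlements > self.n_rows * self.n_cols:
            raise ValueError("more settlements than pixels")
        if not (0.0 <= self.crop_fraction < 1.0):
            raise ValueError("crop_fraction must lie in [0, 1)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.pixel_size)


@dataclass
class LandscapeBundle:
    """Everything the pipeline consumes, on one grid."""

    grid: GridSpec
    registry: ThreatRegistry
    landcover: CategoricalLayer
    water_mask: CategoricalLayer
    urban_mask: CategoricalLayer
    elevation: Layer
    region_ids: CategoricalLayer
    builtup_sources: dict[str, Layer]       # WC / GHSL / GISA fractions
    cropland_sources: dict[str, Layer]      # GCD / GCP / GCI / CCI fractions
    rotation: CategoricalLayer
    plantation_mask: CategoricalLayer
    plantation_type: CategoricalLayer
    canopy_fraction: Layer
    livestock_density: Layer
    population_density: Layer
    population_count: Layer
    nightlights_dmsp: Layer
    no2: Layer
    forest: ForestStack
    roads: LinearFeatureSet
    powerlines: LinearFeatureSet
    trails: LinearFeatureSet
    wells: PointSet
    turbines: PointSet
    mines: PolygonSet
    reservoirs: PolygonSet
    landfills: PolygonSet
    commercial: PolygonSet
    tourism: PolygonSet
    year: int | str = "current"


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _threshold_classes(fld: np.ndarray, mixture: dict[int, float],
                       ) -> np.ndarray:
    """Threshold a continuous field into classes at mixture quantiles."""
    total = sum(mixture.values())
    out = np.zeros(fld.shape, dtype=np.int64)
    qs = np.cumsum([p / total for p in mixture.values()])
    edges = np.quantile(fld, qs[:-1])
    codes = list(mixture)
    bins = np.digitize(fld, edges)
    for i, code in enumerate(codes):
        out[bins == i] = code
    return out


def _random_polyline(rng: np.random.Generator, grid: GridSpec,
                     n_verts: int = 5) -> LineString:
    """A wiggly line crossing the full grid left-right or top-bottom."""
    w, h = grid.width, grid.height
    horizontal = rng.random() < 0.5
    ts = np.linspace(0.0, 1.0, n_verts)
    drift = rng.uniform(0.2, 0.8)
    wiggle = rng.normal(0.0, 0.06, n_verts).cumsum()
    cross = np.clip(drift + wiggle, 0.05, 0.95)
    if horizontal:
        xs = ts * w + grid.origin_x
        ys = grid.origin_y - cross * h
    else:
        xs = cross * w + grid.origin_x
        ys = grid.origin_y - ts * h
    return LineString(zip(xs, ys))


def _random_blob(rng: np.random.Generator, grid: GridSpec,
                 radius_px: float) -> Polygon:
    cx = grid.origin_x + rng.uniform(0.1, 0.9) * grid.width
    cy = grid.origin_y - rng.uniform(0.1, 0.9) * grid.height
    r = radius_px * grid.pixel_size
    return Point(cx, cy).buffer(r * rng.uniform(0.6, 1.4),
                                quad_segs=8)


def generate_landscape(config: LandscapeConfig,
                       registry: ThreatRegistry | None = None,
                       year: int | str = "current") -> LandscapeBundle:
    """Generate one complete, deterministic input bundle."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    shape = grid.shape
    sig = config.smoothness_px

    # --- terrain and land cover -------------------------------------------
    elev_field = _smooth_field(rng, shape, sig * 2)
    elevation = Layer(grid, 800.0 + 600.0 * elev_field, kind="raw")
    lc_field = _smooth_field(rng, shape, sig)
    landcover_vals = _threshold_classes(lc_field, config.class_mixture)

    # cropland: lowland, smooth-field patches replacing open/shrub cover
    crop_field = _smooth_field(rng, shape, sig)
    lowland = elevation.values < np.quantile(elevation.values, 0.9)
    cropable = np.isin(landcover_vals, [LC_OPEN, LC_SHRUB]) & lowland
    if config.crop_fraction > 0 and cropable.any():
        cut = np.quantile(crop_field[cropable],
                          1.0 - min(1.0, config.crop_fraction /
                                    max(cropable.mean(), 1e-9)))
        landcover_vals[cropable & (crop_field > cut)] = LC_CROP

    # --- settlements, population, built-up --------------------------------
    pop = np.zeros(shape)
    builtup_core = np.zeros(shape)
    lo, hi = config.population_log_range
    cx, cy = grid.cell_centers()
    settlement_px = []
    for _ in range(config.n_settlements):
        r = rng.integers(4, grid.n_rows - 4)
        c = rng.integers(4, grid.n_cols - 4)
        settlement_px.append((int(r), int(c)))
        ln_pop = rng.uniform(lo, hi)
        people = float(np.exp(ln_pop))
        spread_m = grid.pixel_size * rng.uniform(3.0, 8.0)
        d2 = (cx - cx[r, c]) ** 2 + (cy - cy[r, c]) ** 2
        kernel = np.exp(-d2 / (2 * spread_m ** 2))
        kernel /= kernel.sum()
        pop += people * kernel
        builtup_core = np.maximum(
            builtup_core, np.clip(kernel / kernel.max(), 0, 1) ** 0.7)
    pop_density = pop / grid.pixel_area_km2  # people per km^2
    landcover_vals[builtup_core > 0.5] = LC_URBAN

    landcover = CategoricalLayer(grid, landcover_vals, nodata=0, labels={
        LC_OPEN: "open", LC_SHRUB: "shrub", LC_FOREST: "forest",
        LC_SPARSE: "sparse", LC_WETLAND: "wetland", LC_WATER: "water",
        LC_URBAN: "urban", LC_CROP: "cropland",
    })
    water_mask = CategoricalLayer(
        grid, (landcover_vals == LC_WATER).astype(np.int64), nodata=-1)
    urban_mask = CategoricalLayer(
        grid, (landcover_vals == LC_URBAN).astype(np.int64), nodata=-1)
    region_ids = CategoricalLayer(
        grid, (np.arange(grid.n_cols)[None, :] * 2 // grid.n_cols
               * np.ones((grid.n_rows, 1), dtype=np.int64)).astype(np.int64),
        nodata=-1)  # two "continents": west / east halves

    def noisy_fraction(base: np.ndarray, noise: float) -> Layer:
        vals = np.clip(base + rng.normal(0.0, noise, shape), 0.0, 1.0)
        return footprint(grid, vals)

    builtup_base = np.clip(builtup_core, 0.0, 1.0)
    builtup_sources = {
        "WC": noisy_fraction(builtup_base, 0.02),
        "GHSL": noisy_fraction(builtup_base * 0.8, 0.03),
        "GISA": noisy_fraction(builtup_base * 0.9, 0.03),
    }
    crop_base = (landcover_vals == LC_CROP).astype(float)
    cropland_sources = {
        "GCD": noisy_fraction(crop_base, 0.01),
        "GCP": noisy_fraction(crop_base * 0.9, 0.02),
        "GCI": noisy_fraction(crop_base * 0.8, 0.02),
        "CCI": noisy_fraction(crop_base * 0.9, 0.02),
    }

    # rotation classes on cropland with a few nodata "cracks"
    rot_vals = np.full(shape, -1, dtype=np.int64)
    crop_mask = landcover_vals == LC_CROP
    rot_field = _smooth_field(rng, shape, sig)
    rot_vals[crop_mask & (rot_field <= -0.4)] = 1
    rot_vals[crop_mask & (rot_field > -0.4) & (rot_field < 0.6)] = 2
    rot_vals[crop_mask & (rot_field >= 0.6)] = 3
    crack = rng.integers(0, grid.n_cols)
    rot_vals[:, crack][crop_mask[:, crack]] = -1
    rotation = CategoricalLayer(grid, rot_vals, nodata=-1)

    # plantations: a slice of forest
    plant_field = _smooth_field(rng, shape, sig)
    plant_mask = (landcover_vals == LC_FOREST) & (plant_field > 1.0)
    plantation_mask = CategoricalLayer(grid, plant_mask.astype(np.int64),
                                       nodata=-1)
    ptype = np.where(plant_field > 1.5, 1, 2).astype(np.int64)  # 1=tree crop
    plantation_type = CategoricalLayer(grid, ptype, nodata=-1)
    canopy = np.clip(0.5 + 0.3 * _smooth_field(rng, shape, sig), 0.0, 1.0)
    canopy[landcover_vals != LC_FOREST] *= 0.3
    canopy_fraction = Layer(grid, canopy, kind="raw")

    # livestock density: positive, patchy, concentrated on grazed cover
    dens_field = _smooth_field(rng, shape, sig)
    dens = config.livestock_density_mean * np.exp(0.8 * dens_field)
    dens[~np.isin(landcover_vals, list(GRAZING_CLASSES) + list(SPARSE_CLASSES))] *= 0.2
    livestock_density = Layer(grid, dens, kind="raw")

    # nightlights and NO2 track built-up with wide halos
    halo = ndimage.gaussian_filter(builtup_base, sigma=sig, mode="nearest")
    halo = halo / halo.max() if halo.max() > 0 else halo
    nightlights_dmsp = Layer(
        grid, np.clip(config.nightlight_peak_dn * halo, 0.0, 63.0),
        kind="raw")
    no2 = Layer(grid, config.no2_peak * (0.3 + 0.7 * halo), kind="raw")

    # forest stack: loss years accumulate at the configured annual fraction
    height = np.where(landcover_vals == LC_FOREST,
                      np.clip(18.0 + 8.0 * _smooth_field(rng, shape, sig), 0.0,
                              None),
                      rng.uniform(0.0, 6.0, shape))
    loss = np.zeros(shape, dtype=np.int64)
    forest_px = np.flatnonzero(landcover_vals == LC_FOREST)
    years = range(2001, 2021)
    per_year = int(config.forest_loss_fraction_per_year * forest_px.size)
    order = rng.permutation(forest_px)
    pos = 0
    for yr in years:
        sel = order[pos:pos + per_year]
        loss.ravel()[sel] = yr
        pos += per_year
    burn = np.zeros(shape, dtype=np.int64)
    lost_px = np.flatnonzero(loss > 0)
    n_burn = int(config.burn_fraction * lost_px.size)
    burn_sel = rng.choice(lost_px, size=n_burn, replace=False) if n_burn else []
    burn.ravel()[burn_sel] = loss.ravel()[burn_sel]  # fire in the loss year
    forest = ForestStack(
        CategoricalLayer(grid, loss, nodata=-9),
        Layer(grid, height, kind="raw"),
        CategoricalLayer(grid, burn, nodata=-9),
    )

    # --- vectors -----------------------------------------------------------
    road_geoms, road_types = [], []
    for ftype, n in config.roads_per_type.items():
        for _ in range(n):
            road_geoms.append(_random_polyline(rng, grid))
            road_types.append(ftype)
    roads = LinearFeatureSet(road_geoms, road_types, dict(DEFAULT_WIDTHS))
    powerlines = LinearFeatureSet(
        [_random_polyline(rng, grid) for _ in range(config.n_powerlines)],
        ["powerline"] * config.n_powerlines, dict(DEFAULT_WIDTHS))
    trails = LinearFeatureSet(
        [_random_polyline(rng, grid) for _ in range(config.n_trails)],
        ["trail"] * config.n_trails, dict(DEFAULT_WIDTHS))

    def random_points(n: int, kind: str) -> PointSet:
        xs = grid.origin_x + rng.uniform(0.05, 0.95, n) * grid.width
        ys = grid.origin_y - rng.uniform(0.05, 0.95, n) * grid.height
        return PointSet(xs, ys, [kind] * n)

    wells = random_points(config.n_wells, "well")
    turbines = random_points(config.n_turbines, "turbine")

    def random_polys(n: int, cls: str, radius_px: float) -> PolygonSet:
        return PolygonSet([_random_blob(rng, grid, radius_px)
                           for _ in range(n)], [cls] * n)

    mines = random_polys(config.n_mines, "quarry", 4.0)
    reservoirs = random_polys(config.n_reservoirs, "reservoir", 6.0)
    landfills = random_polys(config.n_landfills, "landfill", 2.0)

    # commercial / tourism polygons near settlement cores
    def near_settlement_polys(n: int, cls: str) -> PolygonSet:
        geoms = []
        if not settlement_px:
            return PolygonSet([], [])
        for k in range(n):
            r, c = settlement_px[k % len(settlement_px)]
            x = cx[r, c] + rng.normal(0, 4) * grid.pixel_size
            y = cy[r, c] + rng.normal(0, 4) * grid.pixel_size
            geoms.append(Point(x, y).buffer(3 * grid.pixel_size, quad_segs=6))
        return PolygonSet(geoms, [cls] * n)

    commercial = near_settlement_polys(max(1, config.n_settlements // 2),
                                       "commercial")
    tourism = near_settlement_polys(1, "tourism")

    return LandscapeBundle(
        grid=grid,
        registry=registry or default_registry(),
        landcover=landcover,
        water_mask=water_mask,
        urban_mask=urban_mask,
        elevation=elevation,
        region_ids=region_ids,
        builtup_sources=builtup_sources,
        cropland_sources=cropland_sources,
        rotation=rotation,
        plantation_mask=plantation_mask,
        plantation_type=plantation_type,
        canopy_fraction=canopy_fraction,
        livestock_density=livestock_density,
        population_density=Layer(grid, pop_density, kind="raw"),
        population_count=Layer(grid, pop, kind="raw"),
        nightlights_dmsp=nightlights_dmsp,
        no2=no2,
        forest=forest,
        roads=roads,
        powerlines=powerlines,
        trails=trails,
        wells=wells,
        turbines=turbines,
        mines=mines,
        reservoirs=reservoirs,
        landfills=landfills,
        commercial=commercial,
        tourism=tourism,
        year=year,
    )


def null_landscape(config: LandscapeConfig | None = None) -> LandscapeBundle:
    """A bundle with zero features of every kind (all-natural landscape)."""
    cfg = config or LandscapeConfig()
    from dataclasses import replace
    cfg = replace(
        cfg, n_settlements=0, crop_fraction=0.0,
        roads_per_type={}, n_powerlines=0, n_trails=0, n_wells=0,
        n_turbines=0, n_mines=0, n_reservoirs=0, n_landfills=0,
        forest_loss_fraction_per_year=0.0, nightlight_peak_dn=0.0,
        no2_peak=0.0, livestock_density_mean=0.0,
    )
    rng_cfg = cfg
    bundle = generate_landscape(rng_cfg)
    # zero out the fields derived from settlements / activity
    z = np.zeros(bundle.grid.shape)
    for key in ("WC", "GHSL", "GISA"):
        bundle.builtup_sources[key] = footprint(bundle.grid, z.copy())
    for key in ("GCD", "GCP", "GCI", "CCI"):
        bundle.cropland_sources[key] = footprint(bundle.grid, z.copy())
    bundle.commercial = PolygonSet([], [])
    bundle.tourism = PolygonSet([], [])
    bundle.livestock_density = Layer(bundle.grid, z.copy(), kind="raw")
    bundle.population_density = Layer(bundle.grid, z.copy(), kind="raw")
    bundle.population_count = Layer(bundle.grid, z.copy(), kind="raw")
    bundle.nightlights_dmsp = Layer(bundle.grid, z.copy(), kind="raw")
    bundle.no2 = Layer(bundle.grid, z.copy(), kind="raw")
    pm = np.zeros(bundle.grid.shape, dtype=np.int64)
    bundle.plantation_mask = CategoricalLayer(bundle.grid, pm, nodata=-1)
    return bundle


def generate_reference_plots(truth_H: Layer, n_plots: int, noise_sd: float,
                             seed: int | None = None) -> ReferencePlotSet:
    """Stratified random reference plots: observed = truth + N(0, sd), clipped.

    Stratification is by modification class, so every nonempty class
    contributes plots roughly in proportion (with at least one).
    """
    from .core import classify_modification

    rng = np.random.default_rng(seed)
    cls_layer, _ = classify_modification(truth_H)
    grid = truth_H.grid
    rows, cols = [], []
    valid = np.isfinite(truth_H.values)
    strata = [k for k in range(5) if ((cls_layer.values == k) & valid).any()]
    weights = np.array([((cls_layer.values == k) & valid).sum()
                        for k in strata], dtype=float)
    alloc = np.maximum(1, np.round(weights / weights.sum() * n_plots)
                       .astype(int))
    for k, n_k in zip(strata, alloc):
        rr, cc = np.nonzero((cls_layer.values == k) & valid)
        pick = rng.integers(0, rr.size, size=n_k)
        rows.extend(rr[pick])
        cols.extend(cc[pick])
    rows_a = np.asarray(rows)
    cols_a = np.asarray(cols)
    xs = grid.origin_x + (cols_a + 0.5) * grid.pixel_size
    ys = grid.origin_y - (rows_a + 0.5) * grid.pixel_size
    truth = truth_H.values[rows_a, cols_a]
    observed = np.clip(truth + rng.normal(0.0, noise_sd, truth.size), 0.0, 1.0)
    return ReferencePlotSet(xs, ys, observed)


def generate_timeseries(config: LandscapeConfig, years: Sequence[int],
                        growth_per_step: float = 0.10,
                        ) -> list[LandscapeBundle]:
    """Year-stamped bundles with monotone-growing human features.

    Built-up and cropland source fractions, population, nightlights and
    NO2 scale up by ``growth_per_step`` per step (relative to the final
    year); forest loss accrues with the mapping year.  Static features
    (roads, polygons) repeat unchanged.  Deterministic per seed.
    """
    if len(years) < 1:
        raise ValueError("need at least one year")
    base = generate_landscape(config)
    out = []
    n = len(years)
    for i, yr in enumerate(years):
        scale = max(0.0, 1.0 - growth_per_step * (n - 1 - i))
        b = generate_landscape(config, year=yr)
        for key in b.builtup_sources:
            b.builtup_sources[key] = footprint(
                b.grid, np.clip(base.builtup_sources[key].values * scale,
                                0, 1), year=yr)
        for key in b.cropland_sources:
            b.cropland_sources[key] = footprint(
                b.grid, np.clip(base.cropland_sources[key].values * scale,
                                0, 1), year=yr)
        b.population_density = Layer(
            b.grid, base.population_density.values * scale, kind="raw")
        b.population_count = Layer(
            b.grid, base.population_count.values * scale, kind="raw")
        b.nightlights_dmsp = Layer(
            b.grid, base.nightlights_dmsp.values * scale, kind="raw")
        b.no2 = Layer(b.grid, base.no2.values * scale, kind="raw")
        b.year = yr
        out.append(b)
    return out
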