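"""Human-accessibility threat: gravity-model population access.

The pipeline: smooth population density with a Gaussian kernel; class
pixels by the integer part of ln(density) where density > 1; group
8-connected patches of equal class and size each patch's population (z =
floor(ln(pop))); build a minutes-per-km cost surface from transport
features, water and off-road land cover; run multi-source Dijkstra from
each z-group; and accumulate decay-weighted population access
``P = sum_z exp(z) * 0.5^(T_z / 30)`` (access halves per 30 minutes of
travel).  The footprint is P normalized by 12.0 (the value at roughly the
90th percentile globally, about a town of 100k people) and fuzzy-combined
with trail cone kernels.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .core import increasive_mean
from .grid import CategoricalLayer, GridSpec, Layer, check_aligned, footprint
from .infrastructure import TRAIL_KERNEL, DecayKernelSpec, kernel_line_footprint, rasterize_lengths
from .vectors import LinearFeatureSet

log = logging.getLogger(__name__)

#: on-feature travel-time factors, minutes per km
TRAVEL_FACTORS = {
    "highway": 19.0,
    "secondary": 48.0,
    "residential": 96.0,
    "track": 167.0,
    "rail": 169.0,
    "trail": 200.0,
}
WATER_FACTOR = 167.0

#: default off-road factors by land-cover class name, minutes per km
OFFROAD_FACTORS = {"open": 60.0, "forest": 120.0, "wetland": 200.0}

HALF_LIFE_MIN = 30.0
ACCESS_NORMALIZER = 12.0


def smooth_density(pop_density: Layer, kernel_radius: float = 2000.0) -> Layer:
    """Gaussian-weighted mean density (sigma = radius/2, nearest-edge)."""
    vals = pop_density.values
    if np.nanmin(vals) < 0:
        raise ValueError("population density must be >= 0")
    sigma_px = (kernel_radius / 2.0) / pop_density.grid.pixel_size
    sm = ndimage.gaussian_filter(np.nan_to_num(vals), sigma=sigma_px,
                                 mode="nearest")
    weight = ndimage.gaussian_filter(np.isfinite(vals).astype(float),
                                     sigma=sigma_px, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(weight > 0, sm / weight, np.nan)
    out[~np.isfinite(vals)] = np.nan
    return Layer(pop_density.grid, out, kind="raw")


@dataclass
class PopulationPatchSet:
    """Density-class patches with per-patch population size classes."""

    grid: GridSpec
    patch_ids: np.ndarray  # 0 = unclassed background
    density_class: np.ndarray  # -1 where unclassed
    patch_z: dict[int, int] = field(default_factory=dict)

    def z_groups(self) -> dict[int, np.ndarray]:
        """Boolean source mask per population size class z."""
        out: dict[int, np.ndarray] = {}
        for pid, z in self.patch_z.items():
            mask = self.patch_ids == pid
            out.setdefault(z, np.zeros(self.grid.shape, dtype=bool))
            out[z] |= mask
        return out


def population_patches(D: Layer, population: Layer) -> PopulationPatchSet:
    """Class smoothed density by floor(ln D) (D > 1) and patch populations.

    Patches are 8-connected components of equal-class pixels; each patch's
    size class is z = floor(ln(total population within the patch)).
    """
    check_aligned(D.grid, population.grid)
    vals = D.values
    classed = np.isfinite(vals) & (vals > 1.0)
    cls = np.full(D.grid.shape, -1, dtype=np.int64)
    cls[classed] = np.floor(np.log(vals[classed])).astype(np.int64)
    if not classed.any():
        log.warning("no pixels with smoothed density > 1; empty patch set")
        return PopulationPatchSet(D.grid, np.zeros(D.grid.shape, np.int64),
                                  cls, {})
    struct = np.ones((3, 3), dtype=bool)
    patch_ids = np.zeros(D.grid.shape, dtype=np.int64)
    patch_z: dict[int, int] = {}
    offset = 0
    pop = np.nan_to_num(population.values)
    for c in np.unique(cls[classed]):
        lab, n = ndimage.label(cls == c, structure=struct)
        for k in range(1, n + 1):
            sel = lab == k
            pid = offset + k
            patch_ids[sel] = pid
            total = float(pop[sel].sum())
            patch_z[pid] = int(math.floor(math.log(total))) if total > 1 else 0
        offset += n
    return PopulationPatchSet(D.grid, patch_ids, cls, patch_z)


def build_cost_surface(landcover: CategoricalLayer,
                       features: LinearFeatureSet | None,
                       water_mask: CategoricalLayer | None,
                       offroad_factors: dict[int, float],
                       travel_factors: dict[str, float] | None = None,
                       water_factor: float = WATER_FACTOR) -> Layer:
    """Minutes-per-km traversal cost per pixel.

    A pixel crossed by transport features takes the minimum factor among
    them; water pixels (without features) take the water factor; all other
    pixels take the off-road factor of their land-cover class.  Every
    class present must have a factor.
    """
    grid = landcover.grid
    vals = landcover.values
    present = set(np.unique(vals[vals != landcover.nodata]).tolist())
    missing = present - set(offroad_factors)
    if missing:
        raise ValueError(f"no travel factor for land-cover classes {sorted(missing)}")
    cost = np.full(grid.shape, np.nan)
    for cls, f in offroad_factors.items():
        if not f > 0:
            raise ValueError("travel factors must be > 0")
        cost[vals == cls] = f
    if water_mask is not None:
        check_aligned(grid, water_mask.grid)
        cost[water_mask.values == 1] = water_factor
    if features is not None and len(features):
        tf = travel_factors or TRAVEL_FACTORS
        for ftype in features.present_types():
            lengths = rasterize_lengths(features.of_type(ftype).geometries, grid)
            on = lengths > 0
            factor = tf[ftype]
            cost[on] = np.fmin(cost[on], factor)
    return Layer(grid, cost, kind="raw")


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def _grid_graph(cost: Layer):
    """Sparse 8-neighbour graph; edge = step km x mean endpoint cost."""
    grid = cost.grid
    n_r, n_c = grid.shape
    c = cost.values
    step_km = grid.pixel_size / 1000.0
    rows_i, cols_j, weights = [], [], []
    idx = np.arange(n_r * n_c).reshape(n_r, n_c)
    for dr, dc in [(-1, 1), (0, 1), (1, 1), (1, 0)]:  # each edge once
        r0 = max(0, -dr)
        r1 = n_r - max(0, dr)
        c0 = max(0, -dc)
        c1 = n_c - max(0, dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ca = c[r0:r1, c0:c1]
        cb = c[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        dist = step_km * (math.sqrt(2.0) if dr and dc else 1.0)
        w = dist * 0.5 * (ca + cb)
        ok = np.isfinite(w)
        rows_i.append(a[ok].ravel())
        cols_j.append(b[ok].ravel())
        weights.append(w[ok].ravel())
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    w = np.concatenate(weights)
    n = n_r * n_c
    return coo_matrix((np.concatenate([w, w]),
                       (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n, n)).tocsr()


def least_cost_time(cost: Layer, sources: np.ndarray) -> Layer:
    """Least-cost travel time (minutes) from a source mask.

    Multi-source Dijkstra over the 8-neighbour pixel graph; edge weight is
    the step distance in km (diagonals x sqrt 2) times the mean of the two
    endpoint minutes-per-km costs.  Unreachable pixels get +inf.
    """
    finite = np.isfinite(cost.values)
    if finite.any() and np.nanmin(cost.values) <= 0:
        raise ValueError("traversal costs must be > 0")
    src = np.asarray(sources, dtype=bool)
    if src.shape != cost.grid.shape:
        raise ValueError("source mask must match the cost grid")
    if not src.any():
        raise ValueError("need at least one source pixel")
    graph = _grid_graph(cost)
    t = _sp_dijkstra(graph, directed=False,
                     indices=np.flatnonzero(src.ravel()), min_only=True)
    T = t.reshape(cost.grid.shape)
    n_unreach = int(np.isinf(T).sum())
    if n_unreach:
        log.info("%d pixels unreachable from sources", n_unreach)
    return Layer(cost.grid, T, kind="raw")


def dijkstra_reference(cost: np.ndarray, pixel_size: float,
                       sources: list[tuple[int, int]]) -> np.ndarray:
    """Brute-force heap Dijkstra on small grids (independent oracle)."""
    n_r, n_c = cost.shape
    step_km = pixel_size / 1000.0
    T = np.full((n_r, n_c), np.inf)
    heap = []
    for r, c in sources:
        T[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        t, r, c = heapq.heappop(heap)
        if t > T[r, c]:
            continue
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_r and 0 <= cc < n_c:
                d = step_km * (math.sqrt(2.0) if dr and dc else 1.0)
                w = d * 0.5 * (cost[r, c] + cost[rr, cc])
                if t + w < T[rr, cc]:
                    T[rr, cc] = t + w
                    heapq.heappush(heap, (t + w, rr, cc))
    return T


def accessibility_population(patches: PopulationPatchSet, cost: Layer,
                             half_life_min: float = HALF_LIFE_MIN) -> Layer:
    """Decay-weighted accessible population P = sum_z exp(z) 0.5^(T_z/30)."""
    check_aligned(patches.grid, cost.grid)
    P = np.zeros(patches.grid.shape)
    for z, src in sorted(patches.z_groups().items()):
        if not src.any():
            continue
        T = least_cost_time(cost, src).values
        with np.errstate(over="ignore"):
            P += math.exp(z) * np.power(0.5, T / half_life_min)
    return Layer(patches.grid, P, kind="raw")


def accessibility_footprint(P: Layer, trails: LinearFeatureSet | None = None,
                            norm: float = ACCESS_NORMALIZER,
                            trail_kernel: DecayKernelSpec = TRAIL_KERNEL,
                            ) -> Layer:
    """F_h = min(1, P/norm), fuzzy-combined with trail cone kernels."""
    base = footprint(P.grid, np.clip(P.values / norm, 0.0, 1.0), code="6.1")
    if trails is not None and len(trails.of_type("trail")):
        tf = kernel_line_footprint(trails.of_type("trail"), trail_kernel,
                                   P.grid)
        combined = increasive_mean([base, tf])
        return footprint(P.grid, combined.values, code="6.1")
    return base
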