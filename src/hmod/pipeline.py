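"""End-to-end orchestration: bundle -> per-threat H -> class H -> cumulative.

``compute_threat_footprints`` builds every footprint the registry mode
requires from an input bundle; ``run_pipeline`` applies intensities,
combines threats (fuzzy sum everywhere except agriculture, which takes the
pixel-wise max of cropland/plantation/pasture), derives the dominant-threat
and modification-class maps, and writes rasters, tables and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .access import (OFFROAD_FACTORS as ACCESS_OFFROAD, accessibility_footprint,
                     accessibility_population, build_cost_surface,
                     population_patches, smooth_density)
from .core import (ClassThresholds, classify_modification, combine_agriculture,
                   dominant_threat, increasive_mean, modification_from_footprint,
                   zonal_summary)
from .forestry import harvest_footprint
from .grid import Layer, footprint, zeros
from .infrastructure import (FLARE_KERNEL, POWERLINE_KERNEL, areal_footprint,
                             kernel_line_footprint, kernel_point_footprint,
                             linear_footprint, nightlights_footprint,
                             no2_footprint, reservoir_footprint,
                             residential_road_filter, transport_modification)
from .registry import ThreatRegistry
from .settlements import (BUILTUP_WEIGHTS, CROPLAND_WEIGHTS, WeightedSource,
                          cropland_footprint, fuse_weighted_sources,
                          partition_builtup, pasture_footprint,
                          plantation_footprint, rotation_intensity_surface)
from .synth import (GRAZING_CLASSES, OFFROAD_FACTORS, SPARSE_CLASSES,
                    LandscapeBundle)

log = logging.getLogger(__name__)

TURBINE_AREA_KM2 = 0.0014
ROAD_TYPES = ("highway", "secondary", "residential", "track", "rail")


@dataclass
class RunManifest:
    seed: int | None
    mode: str
    config_hash: str
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    version: str = "0.1.0"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1))


def _weighted(sources: dict[str, Layer], weights: dict[str, float],
              ) -> list[WeightedSource]:
    return [WeightedSource(sources[k], weights[k], k)
            for k in weights if k in sources]


def compute_threat_footprints(bundle: LandscapeBundle, mode: str = "current",
                              ) -> tuple[dict[str, Layer], dict[str, Layer | float]]:
    """Build footprint and intensity inputs for every threat in ``mode``.

    Returns (footprints, intensities): per-threat-code footprint layers and
    either a scalar intensity or a co-registered intensity raster.
    """
    reg = bundle.registry.subset(mode)
    codes = set(reg.threat_codes())
    grid = bundle.grid
    F: dict[str, Layer] = {}
    I: dict[str, Layer | float] = {}

    # built-up class (1.x): weighted fusion then polygon partition
    if codes & {"1.1", "1.2", "1.3"}:
        weights = BUILTUP_WEIGHTS if mode == "current" else {
            k: v for k, v in BUILTUP_WEIGHTS.items() if k != "WC"}
        F_b = fuse_weighted_sources(
            _weighted(bundle.builtup_sources, weights))
        if mode == "current":
            F_br, F_bc, F_bt = partition_builtup(F_b, bundle.commercial,
                                                 bundle.tourism)
        else:  # polygon sources are current-only
            F_br, F_bc, F_bt = partition_builtup(F_b, None, None)
        if "1.1" in codes:
            F["1.1"], I["1.1"] = F_br, reg.intensity("1.1").best
        if "1.2" in codes:
            F["1.2"], I["1.2"] = F_bc, reg.intensity("1.2").best
        if "1.3" in codes:
            F["1.3"], I["1.3"] = F_bt, reg.intensity("1.3").best

    # cropland (2.1): fused sources, urban buffer + elevation filter,
    # rotation-dependent intensity surface
    if "2.1" in codes:
        weights = CROPLAND_WEIGHTS if mode == "current" else {
            k: v for k, v in CROPLAND_WEIGHTS.items() if k in ("GCD", "CCI")}
        F["2.1"] = cropland_footprint(
            _weighted(bundle.cropland_sources, weights),
            urban_mask=bundle.urban_mask,
            elevation=bundle.elevation,
            region_ids=bundle.region_ids,
        )
        rot = rotation_intensity_surface(bundle.rotation)
        inten = np.where(np.isfinite(rot.values), rot.values,
                         reg.intensity("2.1", "single").best)
        I["2.1"] = Layer(grid, inten, kind="raw")

    # plantations (2.2)
    if "2.2" in codes:
        F_ap, I_ap = plantation_footprint(
            bundle.plantation_mask, bundle.canopy_fraction,
            bundle.plantation_type,
            tree_crop_intensity=reg.intensity("2.2", "tree_crop").best,
            planted_forest_intensity=reg.intensity("2.2", "planted_forest").best)
        F["2.2"], I["2.2"] = F_ap, I_ap

    # pasture/grazing (2.3)
    if "2.3" in codes:
        F["2.3"] = pasture_footprint(
            bundle.landcover, GRAZING_CLASSES, SPARSE_CLASSES,
            bundle.livestock_density, major_roads=bundle.roads)
        I["2.3"] = reg.intensity("2.3").best

    # oil & gas (3.1): flare/well cone kernels
    if "3.1" in codes:
        F["3.1"] = kernel_point_footprint(bundle.wells, FLARE_KERNEL, grid)
        I["3.1"] = reg.intensity("3.1").best

    # mining (3.2): polygon cover
    if "3.2" in codes:
        F["3.2"] = areal_footprint(bundle.mines, grid)
        I["3.2"] = reg.intensity("3.2").best

    # renewables (3.3): per-turbine area
    if "3.3" in codes:
        F["3.3"] = areal_footprint(None, grid, points=bundle.turbines,
                                   point_area_km2=TURBINE_AREA_KM2)
        I["3.3"] = reg.intensity("3.3").best

    # transportation (4.1) is handled separately (per-type widths and
    # intensities, capped addition) in run_pipeline; mark presence here
    # with the summed footprint for threat counting.
    settlements_F = F.get("1.1", zeros(grid))
    if "4.1" in codes:
        roads = residential_road_filter(bundle.roads, settlements_F)
        per_type = {t: linear_footprint(roads, grid, t)
                    for t in ROAD_TYPES if len(roads.of_type(t))}
        H_tr = transport_modification(per_type) if per_type else zeros(
            grid, kind="H")
        F["4.1"] = footprint(
            grid, np.clip(sum(l.values for l in per_type.values()), 0, 1)
            if per_type else np.zeros(grid.shape), code="4.1")
        I["4.1"] = ("precombined", H_tr)  # type: ignore[assignment]

    # utilities (4.2): powerline kernel fuzzy-combined with nightlights
    if "4.2" in codes:
        parts = [kernel_line_footprint(bundle.powerlines, POWERLINE_KERNEL,
                                       grid)]
        parts.append(nightlights_footprint(bundle.nightlights_dmsp, "dmsp"))
        comb = increasive_mean(parts)
        F["4.2"] = footprint(grid, comb.values, code="4.2")
        I["4.2"] = reg.intensity("4.2", "powerline").best

    # forestry (5.3)
    if "5.3" in codes:
        map_year = bundle.year if isinstance(bundle.year, int) else 2022
        F["5.3"] = harvest_footprint(bundle.forest, map_year)
        I["5.3"] = reg.intensity("5.3").best

    # human accessibility (6.1)
    if "6.1" in codes:
        D = smooth_density(bundle.population_density)
        patches = population_patches(D, bundle.population_count)
        features = _merge_lines(bundle.roads, bundle.trails)
        cost = build_cost_surface(bundle.landcover, features,
                                  bundle.water_mask, OFFROAD_FACTORS)
        P = accessibility_population(patches, cost)
        F["6.1"] = accessibility_footprint(P, bundle.trails)
        I["6.1"] = reg.intensity("6.1").best

    # reservoirs (7.2)
    if "7.2" in codes:
        F["7.2"] = reservoir_footprint(bundle.reservoirs, bundle.water_mask,
                                       grid)
        I["7.2"] = reg.intensity("7.2").best

    # landfills (9.4), air pollution (9.5)
    if "9.4" in codes:
        F["9.4"] = areal_footprint(bundle.landfills, grid)
        I["9.4"] = reg.intensity("9.4").best
    if "9.5" in codes:
        F["9.5"] = no2_footprint(bundle.no2)
        I["9.5"] = reg.intensity("9.5").best

    for code, layer in F.items():
        layer.code = code
        layer.year = bundle.year
    return F, I


def _merge_lines(a, b):
    from .vectors import LinearFeatureSet
    return LinearFeatureSet(list(a.geometries) + list(b.geometries),
                            list(a.types) + list(b.types), dict(a.widths))


def compute_threat_modification(F: dict[str, Layer],
                                I: dict[str, Layer | float],
                                ) -> dict[str, Layer]:
    """H_t = F_t x I_t per threat (transport arrives pre-combined)."""
    H: dict[str, Layer] = {}
    for code, f_layer in F.items():
        spec = I[code]
        if isinstance(spec, tuple) and spec[0] == "precombined":
            H[code] = spec[1]
        else:
            H[code] = modification_from_footprint(f_layer, spec)
        H[code].code = code
        H[code].year = f_layer.year
    return H


def combine_by_class(H: dict[str, Layer],
                     registry: ThreatRegistry) -> dict[str, Layer]:
    """Per-threat-class H: fuzzy sum, except agriculture's pixel max."""
    grid = next(iter(H.values())).grid
    out: dict[str, Layer] = {}
    by_class: dict[str, list[Layer]] = {}
    for code, layer in H.items():
        cls = registry.get(code).class_code
        by_class.setdefault(cls, []).append(layer)
    for cls, layers in by_class.items():
        if cls == "2":
            def get(code):
                return H.get(code, zeros(grid, kind="H"))
            combined = combine_agriculture(get("2.1"), get("2.2"), get("2.3"))
        else:
            combined = increasive_mean(layers)
        combined.code = cls
        combined.scope = "threat_class"
        combined.year = layers[0].year
        out[cls] = combined
    return out


def cumulative_modification(H: dict[str, Layer]) -> Layer:
    """Overall H: fuzzy sum over every individual threat layer."""
    out = increasive_mean(list(H.values()))
    out.code = "all"
    out.scope = "cumulative"
    return out


def run_pipeline(bundle: LandscapeBundle, mode: str = "current",
                 out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Run the full workflow on one bundle; optionally write outputs.

    Returns a dict with per-threat H, per-class H, cumulative H, dominant
    threat, class map + area table, and zonal summary by dominant class.
    """
    t0 = time.time()
    timings = {}
    F, I = compute_threat_footprints(bundle, mode)
    timings["footprints"] = time.time() - t0
    H = compute_threat_modification(F, I)
    H_class = combine_by_class(H, bundle.registry.subset(mode))
    H_all = cumulative_modification(H)
    dom = dominant_threat(list(H_class.values()))
    class_map, class_table = classify_modification(H_all)
    zonal = zonal_summary(H_all, dom)
    timings["combine"] = time.time() - t0 - timings["footprints"]
    result = {
        "footprints": F,
        "threats": H,
        "classes": H_class,
        "cumulative": H_all,
        "dominant": dom,
        "class_map": class_map,
        "class_table": class_table,
        "zonal": zonal,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for code, layer in H.items():
            p = out / f"H_threat_{code.replace('.', '_')}.tif"
            hio.write_layer(layer, p)
            written.append(str(p))
        for cls, layer in H_class.items():
            p = out / f"H_class_{cls}.tif"
            hio.write_layer(layer, p)
            written.append(str(p))
        hio.write_layer(H_all, out / "H_cumulative.tif")
        hio.write_categorical(dom, out / "dominant_threat.tif")
        hio.write_categorical(class_map, out / "modification_classes.tif")
        class_table.to_csv(out / "class_areas.csv", index=False)
        zonal.to_csv(out / "zonal_by_dominant.csv", index=False)
        written += ["H_cumulative.tif", "dominant_threat.tif",
                    "modification_classes.tif", "class_areas.csv",
                    "zonal_by_dominant.csv"]
        cfg_hash = hashlib.sha256(
            json.dumps({"mode": mode, "seed": seed,
                        "grid": [bundle.grid.n_rows, bundle.grid.n_cols,
                                 bundle.grid.pixel_size]},
                       sort_keys=True).encode()).hexdigest()[:16]
        RunManifest(seed=seed, mode=mode, config_hash=cfg_hash,
                    outputs=written, timings=timings).write(
            out / "manifest.json")
    return result


def validate_inputs(bundle: LandscapeBundle) -> list[str]:
    """Schema/range/grid report; empty list means the bundle is clean."""
    problems: list[str] = []
    grid = bundle.grid
    named_layers = {
        "landcover": bundle.landcover, "water_mask": bundle.water_mask,
        "urban_mask": bundle.urban_mask, "elevation": bundle.elevation,
        "livestock_density": bundle.livestock_density,
        "population_density": bundle.population_density,
        "nightlights_dmsp": bundle.nightlights_dmsp, "no2": bundle.no2,
    }
    for name, layer in named_layers.items():
        if layer.grid != grid:
            problems.append(f"{name}: grid mismatch")
    for group in (bundle.builtup_sources, bundle.cropland_sources):
        for name, layer in group.items():
            vals = layer.valid_values()
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                problems.append(f"source {name}: fraction outside [0, 1]")
            if layer.grid != grid:
                problems.append(f"source {name}: grid mismatch")
    for name in ("livestock_density", "population_density", "no2"):
        vals = named_layers[name].valid_values()
        if vals.size and vals.min() < 0:
            problems.append(f"{name}: negative values")
    present = set(bundle.landcover.classes().tolist())
    missing = present - set(OFFROAD_FACTORS)
    if missing:
        problems.append(
            f"no travel factor for land-cover classes {sorted(missing)}")
    return problems
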