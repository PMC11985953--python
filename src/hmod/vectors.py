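"""Vector feature collections (shapely-backed) used by footprint builders."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, shape, mapping
from shapely.validation import make_valid

LINE_TYPES = ("highway", "secondary", "residential", "track", "rail",
              "powerline", "trail")

#: default transport corridor widths in metres, by feature type
DEFAULT_WIDTHS = {
    "highway": 40.0,
    "secondary": 20.0,
    "residential": 15.0,
    "track": 5.0,
    "rail": 20.0,
}


class GeometryError(ValueError):
    pass


@dataclass
class LinearFeatureSet:
    """Line features with a per-feature type attribute and per-type widths."""

    geometries: list[LineString]
    types: list[str]
    widths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WIDTHS))

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.types):
            raise ValueError("one type attribute per geometry required")
        for t, w in self.widths.items():
            if not w > 0:
                raise ValueError(f"width for '{t}' must be > 0")

    def __len__(self) -> int:
        return len(self.geometries)

    def of_type(self, ftype: str) -> "LinearFeatureSet":
        keep = [(g, t) for g, t in zip(self.geometries, self.types) if t == ftype]
        return LinearFeatureSet([g for g, _ in keep], [t for _, t in keep],
                                dict(self.widths))

    def present_types(self) -> list[str]:
        out: list[str] = []
        for t in self.types:
            if t not in out:
                out.append(t)
        return out

    def width_of(self, ftype: str) -> float:
        if ftype not in self.widths:
            raise ValueError(f"no width configured for feature type '{ftype}'")
        return self.widths[ftype]

    def retype(self, indices: Iterable[int], new_type: str) -> "LinearFeatureSet":
        idx = set(indices)
        types = [new_type if i in idx else t for i, t in enumerate(self.types)]
        return LinearFeatureSet(list(self.geometries), types, dict(self.widths))

    def total_length(self) -> float:
        return float(sum(g.length for g in self.geometries))


@dataclass
class PolygonSet:
    """Polygon features with a land-use class attribute and optional ids."""

    geometries: list[Polygon]
    classes: list[str]
    ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.classes):
            raise ValueError("one class attribute per geometry required")
        if not self.ids:
            self.ids = list(range(len(self.geometries)))
        repaired = []
        for g in self.geometries:
            if not g.is_valid:
                g = make_valid(g)
                if g.is_empty or not g.is_valid:
                    raise GeometryError("unrepairable invalid polygon")
            repaired.append(g)
        self.geometries = repaired

    def __len__(self) -> int:
        return len(self.geometries)

    def of_class(self, cls: str) -> "PolygonSet":
        keep = [(g, c, i) for g, c, i in
                zip(self.geometries, self.classes, self.ids) if c == cls]
        return PolygonSet([k[0] for k in keep], [k[1] for k in keep],
                          [k[2] for k in keep])

    def drop_ids(self, exclude: Iterable[int]) -> "PolygonSet":
        ex = set(exclude)
        keep = [(g, c, i) for g, c, i in
                zip(self.geometries, self.classes, self.ids) if i not in ex]
        return PolygonSet([k[0] for k in keep], [k[1] for k in keep],
                          [k[2] for k in keep])

    def union(self) -> shapely.Geometry:
        if not self.geometries:
            return Polygon()
        return shapely.union_all(self.geometries)


@dataclass
class PointSet:
    """Point features (wells, turbines) with an optional kind attribute."""

    xs: np.ndarray
    ys: np.ndarray
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=np.float64)
        self.ys = np.asarray(self.ys, dtype=np.float64)
        if self.xs.shape != self.ys.shape:
            raise ValueError("xs and ys must have the same length")
        if not self.kinds:
            self.kinds = ["point"] * len(self.xs)

    def __len__(self) -> int:
        return len(self.xs)

    def of_kind(self, kind: str) -> "PointSet":
        sel = [i for i, k in enumerate(self.kinds) if k == kind]
        return PointSet(self.xs[sel], self.ys[sel],
                        [self.kinds[i] for i in sel])


def lines_to_geojson(fs: LinearFeatureSet) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"type": t},
             "geometry": mapping(g)}
            for g, t in zip(fs.geometries, fs.types)
        ],
    }


def polygons_to_geojson(ps: PolygonSet) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"landuse": c, "id": i},
             "geometry": mapping(g)}
            for g, c, i in zip(ps.geometries, ps.classes, ps.ids)
        ],
    }


def points_to_geojson(ps: PointSet) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"kind": k},
             "geometry": mapping(Point(x, y))}
            for x, y, k in zip(ps.xs, ps.ys, ps.kinds)
        ],
    }


def lines_from_geojson(data: dict, widths: dict[str, float] | None = None,
                       ) -> LinearFeatureSet:
    geoms, types = [], []
    for feat in data["features"]:
        geoms.append(shape(feat["geometry"]))
        types.append(feat["properties"].get("type", "track"))
    return LinearFeatureSet(geoms, types, dict(widths or DEFAULT_WIDTHS))


def polygons_from_geojson(data: dict) -> PolygonSet:
    geoms, classes, ids = [], [], []
    for feat in data["features"]:
        geoms.append(shape(feat["geometry"]))
        classes.append(feat["properties"].get("landuse", "unknown"))
        ids.append(int(feat["properties"].get("id", len(ids))))
    return PolygonSet(geoms, classes, ids)


def points_from_geojson(data: dict) -> PointSet:
    xs, ys, kinds = [], [], []
    for feat in data["features"]:
        g = shape(feat["geometry"])
        xs.append(g.x)
        ys.append(g.y)
        kinds.append(feat["properties"].get("kind", "point"))
    return PointSet(np.asarray(xs), np.asarray(ys), kinds)
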