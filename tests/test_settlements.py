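"""Built-up and agriculture footprint builders."""

import numpy as np
import pytest
from shapely.geometry import box

from hmod.grid import CategoricalLayer, GridSpec, Layer, footprint
from hmod.settlements import (WeightedSource, cropland_footprint,
                              fuse_weighted_sources, label_patches,
                              livestock_fraction, partition_builtup,
                              pasture_footprint, plantation_footprint,
                              rotation_intensity_surface)
from hmod.core import increasive_mean, modification_from_footprint
from hmod.vectors import LinearFeatureSet, PolygonSet
from shapely.geometry import LineString


def const_source(grid, f, w, label=""):
    return WeightedSource(footprint(grid, np.full(grid.shape, f)), w, label)


class TestFuseWeightedSources:
    def test_single_source(self, grid90):
        F = fuse_weighted_sources([const_source(grid90, 0.5, 0.8)])
        assert F.values[0, 0] == pytest.approx(0.4)

    def test_all_zero(self, grid90):
        F = fuse_weighted_sources([const_source(grid90, 0.0, 0.9),
                                   const_source(grid90, 0.0, 0.8)])
        assert np.all(F.values == 0.0)

    def test_builtup_full_cover(self, grid90):
        """Full cover in all three sources: 1 - 0.1*0.2*0.2 = 0.996."""
        F = fuse_weighted_sources([const_source(grid90, 1.0, 0.9, "WC"),
                                   const_source(grid90, 1.0, 0.8, "GISA"),
                                   const_source(grid90, 1.0, 0.8, "GHSL")])
        assert F.values[0, 0] == pytest.approx(0.996)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fuse_weighted_sources([])

    def test_bad_weight_rejected(self, grid90):
        with pytest.raises(ValueError):
            const_source(grid90, 0.5, 1.5)

    def test_equals_increasive_mean_of_weighted_layers(self, grid90):
        """Fusion is the fuzzy sum of the weighted single-source layers."""
        rng = np.random.default_rng(2)
        sources = [
            WeightedSource(footprint(grid90, rng.uniform(0, 1, grid90.shape)),
                           w) for w in (0.9, 0.8, 0.5)]
        fused = fuse_weighted_sources(sources)
        alt = increasive_mean([
            modification_from_footprint(s.fraction, s.weight)
            for s in sources])
        np.testing.assert_allclose(fused.values, alt.values, atol=1e-12)

    def test_monotone_and_bounded_below_by_max(self, grid90):
        rng = np.random.default_rng(4)
        f = rng.uniform(0, 1, grid90.shape)
        s1 = WeightedSource(footprint(grid90, f), 0.7)
        s2 = const_source(grid90, 0.3, 0.5)
        fused = fuse_weighted_sources([s1, s2]).values
        assert np.all(fused >= 0.7 * f - 1e-12)
        bumped = fuse_weighted_sources([WeightedSource(
            footprint(grid90, np.minimum(1, f + 0.1)), 0.7), s2]).values
        assert np.all(bumped >= fused - 1e-12)


class TestPartitionBuiltup:
    def make_fb(self, grid):
        rng = np.random.default_rng(1)
        return footprint(grid, rng.uniform(0, 1, grid.shape))

    def test_no_polygons_all_residential(self, grid90):
        F_b = self.make_fb(grid90)
        F_br, F_bc, F_bt = partition_builtup(F_b, None, None)
        np.testing.assert_allclose(F_br.values, F_b.values)
        assert np.all(F_bc.values == 0)
        assert np.all(F_bt.values == 0)

    def test_commercial_pixel(self, grid90):
        vals = np.full(grid90.shape, 0.9)
        F_b = footprint(grid90, vals)
        com = PolygonSet([box(0.0, -90.0, 90.0, 0.0)], ["commercial"])
        F_br, F_bc, _ = partition_builtup(F_b, com, None)
        assert F_bc.values[0, 0] == pytest.approx(0.9)
        assert F_br.values[0, 0] == 0.0
        assert F_br.values[3, 3] == pytest.approx(0.9)

    def test_overlap_priority_commercial(self, grid90):
        F_b = footprint(grid90, np.full(grid90.shape, 0.5))
        poly = PolygonSet([box(0.0, -90.0, 90.0, 0.0)], ["x"])
        F_br, F_bc, F_bt = partition_builtup(F_b, poly, poly)
        assert F_bc.values[0, 0] == pytest.approx(0.5)
        assert F_bt.values[0, 0] == 0.0

    def test_mass_conservation(self, grid90):
        F_b = self.make_fb(grid90)
        com = PolygonSet([box(-10.0, -200.0, 200.0, 40.0)], ["c"])
        tou = PolygonSet([box(100.0, -400.0, 500.0, -150.0)], ["t"])
        F_br, F_bc, F_bt = partition_builtup(F_b, com, tou)
        np.testing.assert_allclose(
            F_br.values + F_bc.values + F_bt.values, F_b.values, atol=1e-9)


class TestCroplandFootprint:
    def test_single_source_weight(self, grid90):
        F = cropland_footprint([const_source(grid90, 0.6, 0.9, "GCD")])
        assert F.values[0, 0] == pytest.approx(0.54)

    def test_urban_buffer_zeroes_nearby(self):
        grid = GridSpec(1, 30, 90.0)
        urban = np.zeros(grid.shape, dtype=np.int64)
        urban[0, 0] = 1
        F = cropland_footprint(
            [const_source(grid, 1.0, 0.9, "GCD")],
            urban_mask=CategoricalLayer(grid, urban, nodata=-1))
        # centers within 1000 m of the urban pixel center: cols 0..11
        assert np.all(F.values[0, :12] == 0.0)
        assert F.values[0, 20] == pytest.approx(0.9)

    def test_elevation_percentile_filter(self):
        """Exactly the >99th-percentile cropland pixel is dropped."""
        grid = GridSpec(10, 10, 90.0)
        elev_vals = np.arange(100, dtype=float).reshape(10, 10)
        src = const_source(grid, 1.0, 0.9, "GCD")
        regions = CategoricalLayer(grid, np.zeros(grid.shape, np.int64),
                                   nodata=-1)
        F = cropland_footprint([src], elevation=Layer(grid, elev_vals,
                                                      kind="raw"),
                               region_ids=regions)
        # oracle: np.percentile of 0..99 at 99 = 98.01; only 99 exceeds it
        assert F.values[9, 9] == 0.0
        assert F.values[9, 8] == pytest.approx(0.9)
        assert (F.values == 0).sum() == 1

    def test_elevation_without_regions_rejected(self, grid90):
        with pytest.raises(ValueError):
            cropland_footprint([const_source(grid90, 1.0, 0.9)],
                               elevation=Layer(grid90,
                                               np.zeros(grid90.shape),
                                               kind="raw"))


class TestRotationIntensity:
    def test_all_single_constant(self, grid90):
        rot = CategoricalLayer(grid90, np.ones(grid90.shape, np.int64),
                               nodata=-1)
        out = rotation_intensity_surface(rot)
        np.testing.assert_allclose(out.values, 0.39, atol=1e-12)

    def test_isolated_nodata_filled_modal(self):
        grid = GridSpec(7, 7, 90.0)
        vals = np.full(grid.shape, 2, dtype=np.int64)
        vals[3, 3] = -1
        rot = CategoricalLayer(grid, vals, nodata=-1)
        out = rotation_intensity_surface(rot, fill_radius=500.0,
                                         smooth_radius_px=0)
        assert out.values[3, 3] == pytest.approx(0.53)

    def test_all_nodata_warns_and_returns_nodata(self, grid90):
        rot = CategoricalLayer(grid90, np.full(grid90.shape, -1, np.int64),
                               nodata=-1)
        out = rotation_intensity_surface(rot)
        assert np.all(np.isnan(out.values))

    def test_smoothing_preserves_constant(self, grid90):
        rot = CategoricalLayer(grid90, np.full(grid90.shape, 3, np.int64),
                               nodata=-1)
        out = rotation_intensity_surface(rot, smooth_radius_px=2)
        np.testing.assert_allclose(out.values, 0.67, atol=1e-12)


class TestPlantationFootprint:
    def test_tree_crop(self, grid90):
        mask = CategoricalLayer(grid90, np.ones(grid90.shape, np.int64),
                                nodata=-1)
        canopy = Layer(grid90, np.full(grid90.shape, 0.8), kind="raw")
        F, I = plantation_footprint(mask, canopy)
        assert F.values[0, 0] == pytest.approx(0.8)
        assert I.values[0, 0] == pytest.approx(0.30)
        H = modification_from_footprint(F, I.values)
        assert H.values[0, 0] == pytest.approx(0.24)

    def test_mask_zero(self, grid90):
        mask = CategoricalLayer(grid90, np.zeros(grid90.shape, np.int64),
                                nodata=-1)
        canopy = Layer(grid90, np.full(grid90.shape, 1.0), kind="raw")
        F, _ = plantation_footprint(mask, canopy)
        assert np.all(F.values == 0.0)

    def test_planted_forest_intensity(self, grid90):
        mask = CategoricalLayer(grid90, np.ones(grid90.shape, np.int64),
                                nodata=-1)
        canopy = Layer(grid90, np.full(grid90.shape, 1.0), kind="raw")
        types = CategoricalLayer(grid90, np.full(grid90.shape, 2, np.int64),
                                 nodata=-1)
        F, I = plantation_footprint(mask, canopy, types)
        H = modification_from_footprint(F, I.values)
        assert H.values[0, 0] == pytest.approx(0.06)


def flood_fill_oracle(mask):
    """Brute-force 8-connected labelling for small grids."""
    lab = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and lab[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                while stack:
                    rr, cc = stack.pop()
                    if not (0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]):
                        continue
                    if not mask[rr, cc] or lab[rr, cc]:
                        continue
                    lab[rr, cc] = nxt
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            stack.append((rr + dr, cc + dc))
    return lab


class TestPastureFootprint:
    def make_density(self, grid, vals):
        return Layer(grid, vals, kind="raw")

    def test_zero_density_zero_footprint(self, grid90):
        lc = CategoricalLayer(grid90, np.ones(grid90.shape, np.int64),
                              nodata=0)
        F = pasture_footprint(lc, [1], [], self.make_density(
            grid90, np.zeros(grid90.shape)))
        assert np.all(F.values == 0.0)

    def test_patch_mean_of_sqrt(self):
        """Patch {250, 1000} au/km2 -> f_gp {0.5, 1.0} -> F 0.75 on both."""
        grid = GridSpec(1, 2, 90.0)
        lc = CategoricalLayer(grid, np.ones(grid.shape, np.int64), nodata=0)
        dens = self.make_density(grid, np.array([[250.0, 1000.0]]))
        F = pasture_footprint(lc, [1], [], dens)
        assert F.values[0] == pytest.approx([0.75, 0.75])

    def test_density_cap(self):
        grid = GridSpec(1, 1, 90.0)
        lc = CategoricalLayer(grid, np.ones(grid.shape, np.int64), nodata=0)
        F = pasture_footprint(lc, [1], [],
                              self.make_density(grid, np.array([[4000.0]])))
        assert F.values[0, 0] == pytest.approx(1.0)

    def test_negative_density_rejected(self, grid90):
        lc = CategoricalLayer(grid90, np.ones(grid90.shape, np.int64),
                              nodata=0)
        with pytest.raises(ValueError):
            pasture_footprint(lc, [1], [], self.make_density(
                grid90, np.full(grid90.shape, -5.0)))

    def test_constant_within_patches_and_mean_conserved(self):
        grid = GridSpec(16, 16, 90.0)
        rng = np.random.default_rng(9)
        lc_vals = (rng.random(grid.shape) < 0.5).astype(np.int64)
        lc = CategoricalLayer(grid, lc_vals, nodata=0)
        dens = self.make_density(grid, rng.uniform(0, 1000, grid.shape))
        F = pasture_footprint(lc, [1], [], dens)
        f_gp = livestock_fraction(dens)
        lab = flood_fill_oracle(lc_vals == 1)
        for pid in range(1, lab.max() + 1):
            sel = lab == pid
            vals = F.values[sel]
            assert np.allclose(vals, vals[0])          # constant per patch
            assert vals[0] == pytest.approx(f_gp[sel].mean())

    def test_patch_labels_match_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        grid = GridSpec(24, 24, 90.0)
        lc_vals = (rng.random(grid.shape) < 0.4).astype(np.int64) * 3
        lc = CategoricalLayer(grid, lc_vals, nodata=0)
        patches = label_patches(lc, [3])
        oracle = flood_fill_oracle(lc_vals == 3)
        # same partition: bijection between label sets
        assert (patches.values > 0).sum() == (oracle > 0).sum()
        mapping = {}
        for got, want in zip(patches.values.ravel(), oracle.ravel()):
            if want == 0:
                assert got == 0
                continue
            assert mapping.setdefault(got, want) == want

    def test_sparse_class_95pct_rule(self):
        """Sparse pixels join only inside the grazed [2.5, 97.5]% range."""
        grid = GridSpec(1, 6, 90.0)
        lc = CategoricalLayer(
            grid, np.array([[1, 1, 1, 4, 4, 4]], dtype=np.int64), nodata=0)
        dens = self.make_density(
            grid, np.array([[100.0, 200.0, 300.0, 200.0, 1.0, 990.0]]))
        F = pasture_footprint(lc, [1], [4], dens)
        assert F.values[0, 3] == pytest.approx(np.sqrt(0.2))  # inside range
        assert F.values[0, 4] == 0.0   # below grazed 2.5th percentile
        assert F.values[0, 5] == 0.0   # above grazed 97.5th percentile

    def test_road_pixels_excluded_from_mean(self):
        grid = GridSpec(1, 3, 90.0)
        lc = CategoricalLayer(grid, np.ones(grid.shape, np.int64), nodata=0)
        dens = self.make_density(grid, np.array([[250.0, 250.0, 1000.0]]))
        road = LinearFeatureSet(
            [LineString([(225.0, 0.0), (225.0, -90.0)])], ["highway"])
        F = pasture_footprint(lc, [1], [], dens, major_roads=road)
        # pixel 2 carries the highway; mean over remaining = sqrt(0.25)
        assert F.values[0, 0] == pytest.approx(0.5)
        assert F.values[0, 2] == pytest.approx(0.5)  # broadcast to patch
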