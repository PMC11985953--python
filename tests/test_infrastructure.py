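"""Linear, kernel, areal and normalized footprints."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon, box

from hmod.grid import CategoricalLayer, GridSpec, Layer, footprint
from hmod.infrastructure import (FLARE_KERNEL, POWERLINE_KERNEL,
                                 DecayKernelSpec, areal_footprint,
                                 enforce_monotone_series,
                                 kernel_line_footprint,
                                 kernel_point_footprint, linear_footprint,
                                 nightlights_footprint, no2_footprint,
                                 polygon_cover_fraction, rasterize_lengths,
                                 reservoir_footprint,
                                 residential_road_filter,
                                 transport_modification)
from hmod.vectors import DEFAULT_WIDTHS, LinearFeatureSet, PointSet, PolygonSet


def hline(y, x0, x1):
    return LineString([(x0, y), (x1, y)])


class TestLinearFootprint:
    def test_highway_crossing_90m_pixel(self):
        """A 40 m highway straight across a 90 m pixel covers 4/9 of it."""
        grid = GridSpec(3, 3, 90.0)
        fs = LinearFeatureSet([hline(-135.0, 0.0, 270.0)], ["highway"])
        F = linear_footprint(fs, grid, "highway")
        assert F.values[1, :] == pytest.approx([4 / 9] * 3)
        assert np.all(F.values[0, :] == 0)

    def test_highway_crossing_300m_pixel(self):
        grid = GridSpec(1, 1, 300.0)
        fs = LinearFeatureSet([hline(-150.0, 0.0, 300.0)], ["highway"])
        F = linear_footprint(fs, grid, "highway")
        assert F.values[0, 0] == pytest.approx(40.0 / 300.0)

    def test_half_crossing(self):
        """Length = pixel_size/2 gives F = width / (2 * pixel_size)."""
        grid = GridSpec(1, 1, 90.0)
        fs = LinearFeatureSet([hline(-45.0, 0.0, 45.0)], ["secondary"])
        F = linear_footprint(fs, grid, "secondary")
        assert F.values[0, 0] == pytest.approx(20.0 / 180.0)

    def test_length_width_conservation(self):
        """Sum(F x pixel area) == total length x width for interior lines."""
        grid = GridSpec(32, 32, 90.0)
        rng = np.random.default_rng(3)
        geoms = []
        for _ in range(8):
            pts = rng.uniform(200, 2600, size=(4, 2))
            pts[:, 1] *= -1
            geoms.append(LineString(pts))
        fs = LinearFeatureSet(geoms, ["rail"] * 8)
        F = linear_footprint(fs, grid, "rail")
        total_area = F.values.sum() * grid.pixel_size ** 2
        expected = fs.total_length() * DEFAULT_WIDTHS["rail"]
        assert total_area == pytest.approx(expected, rel=0.005)

    def test_split_invariance(self):
        """Splitting a line into collinear segments changes nothing."""
        grid = GridSpec(4, 4, 90.0)
        whole = LinearFeatureSet([hline(-100.0, 10.0, 350.0)], ["track"])
        split = LinearFeatureSet(
            [hline(-100.0, 10.0, 120.0), hline(-100.0, 120.0, 350.0)],
            ["track", "track"])
        a = linear_footprint(whole, grid, "track").values
        b = linear_footprint(split, grid, "track").values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_additive_in_disjoint_sets(self):
        grid = GridSpec(4, 4, 90.0)
        a = LinearFeatureSet([hline(-100.0, 0.0, 360.0)], ["track"])
        b = LinearFeatureSet([hline(-250.0, 0.0, 360.0)], ["track"])
        both = LinearFeatureSet(a.geometries + b.geometries,
                                ["track", "track"])
        np.testing.assert_allclose(
            linear_footprint(both, grid, "track").values,
            linear_footprint(a, grid, "track").values
            + linear_footprint(b, grid, "track").values, atol=1e-12)

    def test_diagonal_length_exact(self):
        grid = GridSpec(2, 2, 90.0)
        diag = LineString([(0.0, 0.0), (180.0, -180.0)])
        lengths = rasterize_lengths([diag], grid)
        assert lengths[0, 0] == pytest.approx(90.0 * math.sqrt(2))
        assert lengths[1, 1] == pytest.approx(90.0 * math.sqrt(2))
        assert lengths[0, 1] == 0.0

    def test_zero_length_geometry_skipped(self):
        grid = GridSpec(2, 2, 90.0)
        lengths = rasterize_lengths([LineString([(10, -10), (10, -10)])],
                                    grid)
        assert np.all(lengths == 0)


class TestTransportModification:
    def test_highway_only(self):
        grid = GridSpec(1, 1, 90.0)
        F = footprint(grid, np.array([[4.0 / 9.0]]))
        H = transport_modification({"highway": F})
        assert H.values[0, 0] == pytest.approx(0.36)

    def test_cap_at_one(self):
        grid = GridSpec(1, 1, 90.0)
        one = footprint(grid, np.array([[1.0]]))
        H = transport_modification({"highway": one, "rail": one})
        assert H.values[0, 0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            transport_modification({})


class TestResidentialRoadFilter:
    def make_settlements(self, grid, on=True):
        vals = np.zeros(grid.shape)
        if on:
            vals[0, 0] = 0.9
        return footprint(grid, vals)

    def test_near_road_kept(self):
        grid = GridSpec(20, 20, 500.0)
        s = self.make_settlements(grid)
        near = LinearFeatureSet([hline(-700.0, 0.0, 1000.0)], ["residential"])
        out = residential_road_filter(near, s)
        assert out.types == ["residential"]

    def test_far_road_retyped(self):
        grid = GridSpec(40, 40, 500.0)
        s = self.make_settlements(grid)
        far = LinearFeatureSet([hline(-15000.0, 15000.0, 16000.0)],
                               ["residential"])
        out = residential_road_filter(far, s)
        assert out.types == ["track"]

    def test_no_settlements_all_retyped(self):
        grid = GridSpec(10, 10, 500.0)
        s = self.make_settlements(grid, on=False)
        fs = LinearFeatureSet([hline(-700.0, 0.0, 1000.0)], ["residential"])
        assert residential_road_filter(fs, s).types == ["track"]


class TestKernels:
    def test_peak_at_center(self):
        grid = GridSpec(3, 3, 90.0)
        cx, cy = grid.cell_centers()
        pts = PointSet([cx[1, 1]], [cy[1, 1]])
        F = kernel_point_footprint(pts, FLARE_KERNEL, grid)
        assert F.values[1, 1] == pytest.approx(1.0)

    def test_zero_beyond_radius(self):
        grid = GridSpec(1, 5, 90.0)
        cx, cy = grid.cell_centers()
        pts = PointSet([cx[0, 0]], [cy[0, 0]])
        F = kernel_point_footprint(pts, FLARE_KERNEL, grid)
        # pixels at 270 and 360 m are past the 233 m radius
        assert F.values[0, 3] == 0.0
        assert F.values[0, 4] == 0.0

    def test_flare_cone_integral(self):
        """Numeric integral of the cone matches pi R^2 / 3 ~ 0.057 km^2."""
        # quadrature on a fine grid centred on the flare
        R = FLARE_KERNEL.radius
        step = 2.0  # metres
        xs = np.arange(-R, R + step, step)
        X, Y = np.meshgrid(xs, xs)
        vals = FLARE_KERNEL.evaluate(np.hypot(X, Y))
        integral_km2 = vals.sum() * step * step / 1e6
        analytic = math.pi * (R / 1000.0) ** 2 / 3.0
        assert analytic == pytest.approx(0.057, abs=0.001)
        assert integral_km2 == pytest.approx(analytic, rel=0.02)

    def test_radially_non_increasing(self):
        grid = GridSpec(11, 11, 45.0)
        cx, cy = grid.cell_centers()
        pts = PointSet([cx[5, 5]], [cy[5, 5]])
        F = kernel_point_footprint(pts, FLARE_KERNEL, grid).values
        row = F[5, 5:]
        assert np.all(np.diff(row) <= 1e-12)

    def test_overlapping_kernels_take_max(self):
        grid = GridSpec(1, 3, 90.0)
        cx, cy = grid.cell_centers()
        pts = PointSet([cx[0, 0], cx[0, 1]], [cy[0, 0], cy[0, 1]])
        F = kernel_point_footprint(pts, FLARE_KERNEL, grid)
        assert F.values[0, 0] == pytest.approx(1.0)  # not summed above peak

    def test_powerline_kernel(self):
        grid = GridSpec(1, 4, 125.0)
        line = LineString([(0.0, 0.0), (0.0, -125.0)])  # along left edge
        fs = LinearFeatureSet([line], ["powerline"])
        F = kernel_line_footprint(fs, POWERLINE_KERNEL, grid)
        # centers at 62.5, 187.5, 312.5 m from the line
        assert F.values[0, 0] == pytest.approx(0.25 * (1 - 62.5 / 250.0))
        assert F.values[0, 1] == pytest.approx(0.25 * (1 - 187.5 / 250.0))
        assert F.values[0, 2] == 0.0

    def test_kernel_spec_validation(self):
        with pytest.raises(ValueError):
            DecayKernelSpec(radius=-1.0)
        with pytest.raises(ValueError):
            DecayKernelSpec(radius=100.0, peak=0.0)


class TestArealFootprint:
    def test_full_pixel(self):
        grid = GridSpec(2, 2, 90.0)
        poly = PolygonSet([box(0.0, -90.0, 90.0, 0.0)], ["quarry"])
        F = areal_footprint(poly, grid)
        assert F.values[0, 0] == pytest.approx(1.0)
        assert F.values[1, 1] == 0.0

    def test_half_pixel(self):
        grid = GridSpec(1, 1, 90.0)
        poly = PolygonSet([box(0.0, -90.0, 45.0, 0.0)], ["quarry"])
        assert areal_footprint(poly, grid).values[0, 0] == pytest.approx(0.5)

    def test_area_conservation(self):
        """Sum of fractions x pixel area equals the geometric area."""
        grid = GridSpec(16, 16, 90.0)
        poly = Point(700.0, -700.0).buffer(400.0, quad_segs=64)
        frac = polygon_cover_fraction(poly, grid)
        total = frac.sum() * grid.pixel_size ** 2
        assert total == pytest.approx(poly.area, rel=1e-6)

    def test_turbine_point_area(self):
        grid = GridSpec(2, 2, 90.0)
        pts = PointSet([45.0], [-45.0])
        F = areal_footprint(None, grid, points=pts, point_area_km2=0.0014)
        assert F.values[0, 0] == pytest.approx(0.0014 / 0.0081)


class TestNormalizations:
    def test_dmsp_saturation(self):
        grid = GridSpec(1, 3, 90.0)
        raster = Layer(grid, np.array([[0.0, 31.5, 63.0]]), kind="raw")
        F = nightlights_footprint(raster, "dmsp")
        assert F.values[0] == pytest.approx([0.0, 0.5, 1.0])

    def test_viirs_log_transform(self):
        grid = GridSpec(1, 2, 90.0)
        x95 = 10 ** 1.05 - 1.0
        raster = Layer(grid, np.array([[0.0, x95]]), kind="raw")
        F = nightlights_footprint(raster, "viirs")
        assert F.values[0, 0] == 0.0
        assert F.values[0, 1] == pytest.approx(1.0)

    def test_negative_rejected(self):
        grid = GridSpec(1, 1, 90.0)
        with pytest.raises(ValueError):
            nightlights_footprint(Layer(grid, np.array([[-1.0]]),
                                        kind="raw"), "dmsp")

    def test_no2_normalization(self):
        grid = GridSpec(1, 3, 90.0)
        raster = Layer(grid, np.array([[0.0, 0.00015, 0.0006]]), kind="raw")
        F = no2_footprint(raster)
        assert F.values[0] == pytest.approx([0.0, 0.5, 1.0])


class TestReservoirFootprint:
    def test_water_masked_and_buffered(self):
        grid = GridSpec(10, 10, 200.0)
        res = PolygonSet([box(400.0, -1200.0, 1200.0, -400.0)], ["reservoir"])
        water = np.zeros(grid.shape, dtype=np.int64)
        water[3, 3] = 1  # inside the reservoir
        wm = CategoricalLayer(grid, water, nodata=-1)
        F = reservoir_footprint(res, wm, grid)
        assert F.values[3, 3] == 0.0            # masked open water
        assert F.values[2, 2] == pytest.approx(1.0)  # inside polygon
        # pixel centred 500 m outside the polygon edge but inside buffer
        assert F.values[1, 4] == pytest.approx(1.0)

    def test_exclusion_list(self):
        grid = GridSpec(4, 4, 200.0)
        res = PolygonSet([box(0.0, -800.0, 800.0, 0.0)], ["reservoir"],
                         ids=[42])
        wm = CategoricalLayer(grid, np.zeros(grid.shape, np.int64),
                              nodata=-1)
        F = reservoir_footprint(res, wm, grid, exclusions=[42])
        assert np.all(F.values == 0.0)


class TestMonotoneSeries:
    def test_running_max(self):
        grid = GridSpec(1, 1, 90.0)
        series = [footprint(grid, np.array([[v]]), year=y)
                  for v, y in [(0.5, 1990), (0.2, 2000), (0.6, 2010)]]
        out = enforce_monotone_series(series)
        assert [l.values[0, 0] for l in out] == pytest.approx([0.5, 0.5, 0.6])

    def test_constant_unchanged(self):
        grid = GridSpec(2, 2, 90.0)
        series = [footprint(grid, np.full(grid.shape, 0.3), year=y)
                  for y in (1990, 2000)]
        out = enforce_monotone_series(series)
        for l in out:
            assert np.all(l.values == 0.3)

    def test_single_year_identity(self):
        grid = GridSpec(2, 2, 90.0)
        layer = footprint(grid, np.full(grid.shape, 0.4))
        out = enforce_monotone_series([layer])
        np.testing.assert_array_equal(out[0].values, layer.values)

    def test_non_decreasing_property(self):
        grid = GridSpec(8, 8, 90.0)
        rng = np.random.default_rng(5)
        series = [footprint(grid, rng.uniform(0, 1, grid.shape), year=y)
                  for y in range(1990, 2020, 5)]
        out = enforce_monotone_series(series)
        for a, b in zip(out[:-1], out[1:]):
            assert np.all(b.values >= a.values - 1e-15)
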