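import datetime as dt

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from phenoheight import (
    BinProfile,
    ExtractionConfig,
    PlotBoundary,
    SurfaceRaster,
    bin_percentiles,
    bin_plot,
    bin_profile,
    extract_field,
    ground_height,
    plot_mean_height,
    plot_p95_height,
    segment_plot,
)
from phenoheight.errors import (
    ConfigurationError,
    EmptyBinError,
    EmptyPlotError,
    GeoreferenceError,
    ResolutionError,
)
from phenoheight.height_extraction import PixelWindow


def make_raster(data, gsd=0.1, x0=0.0, y0=None, date=None, epsg=None):
    data = np.asarray(data, dtype=np.float32)
    y0 = y0 if y0 is not None else data.shape[0] * gsd
    return SurfaceRaster(data=data, x_origin=x0, y_origin=y0, pixel_size=gsd, date=date, crs_epsg=epsg)


def rect_boundary(minx, miny, maxx, maxy, plot_id="T1", axis=(1.0, 0.0), **props):
    return PlotBoundary(plot_id=plot_id, polygon=box(minx, miny, maxx, maxy), axis=axis, properties=props)


def make_window(values, mask=None, gsd=0.1):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else mask
    return PixelWindow(plot_id="T1", values=values, mask=mask, pixel_size=gsd)


def make_profile(p_low, p_high, n_bins=None):
    p_low = np.asarray(p_low, dtype=float)
    p_high = np.asarray(p_high, dtype=float)
    return BinProfile(
        plot_id="T1",
        date=None,
        n_bins=n_bins or len(p_low),
        counts=np.full(len(p_low), 10),
        p_low=p_low,
        p_high=p_high,
    )


class TestSegmentPlot:
    def test_aligned_rectangle_pixel_count(self):
        r = make_raster(np.zeros((60, 120)), gsd=0.1)
        w = segment_plot(r, rect_boundary(1.0, 0.5, 11.0, 5.5))  # 100 x 50 pixels
        assert w.n_valid == 5000
        assert w.values.shape == (50, 100)

    def test_boundary_outside_raster(self):
        r = make_raster(np.zeros((10, 10)), gsd=0.1)
        with pytest.raises(EmptyPlotError):
            segment_plot(r, rect_boundary(100.0, 100.0, 101.0, 101.0))

    def test_crs_mismatch(self):
        r = make_raster(np.zeros((10, 10)), gsd=0.1, epsg=32615)
        b = rect_boundary(0.1, 0.1, 0.5, 0.5)
        b.crs_epsg = 4326
        with pytest.raises(GeoreferenceError):
            segment_plot(r, b)

    def test_matches_brute_force_point_in_polygon(self, rng):
        # oracle: per-pixel shapely point containment, half-open on edges
        r = make_raster(rng.normal(size=(40, 40)), gsd=0.1)
        poly = Polygon([(0.63, 0.4), (3.1, 0.77), (2.8, 3.3), (0.9, 2.95)])
        b = PlotBoundary(plot_id="T1", polygon=poly, axis=(1.0, 0.0))
        w = segment_plot(r, b)
        expected = 0
        for row in range(40):
            for col in range(40):
                x = (col + 0.5) * 0.1
                y = (40 - row - 0.5) * 0.1
                from shapely.geometry import Point

                if poly.contains(Point(x, y)):
                    expected += 1
        assert w.n_valid == expected

    def test_edge_bisecting_column_half_open(self):
        # boundary edge exactly on pixel-center column: min edge in, max edge out
        r = make_raster(np.zeros((10, 20)), gsd=0.1)
        w = segment_plot(r, rect_boundary(0.25, 0.0, 1.05, 1.0))
        # centers at 0.25 + k*0.1 -> x in {0.25,...,0.95}: 8 columns
        assert w.values.shape[1] == 8

    def test_nodata_excluded(self):
        data = np.zeros((10, 10))
        data[:, :5] = np.nan
        r = make_raster(data, gsd=0.1)
        w = segment_plot(r, rect_boundary(0.0, 0.0, 1.0, 1.0))
        assert w.n_valid == 50
        with pytest.raises(EmptyPlotError):
            segment_plot(make_raster(np.full((10, 10), np.nan)), rect_boundary(0.0, 0.0, 1.0, 1.0))

    def test_along_y_axis_window_is_transposed(self):
        data = np.arange(200, dtype=float).reshape(10, 20)
        r = make_raster(data, gsd=0.1)
        wx = segment_plot(r, rect_boundary(0.0, 0.0, 2.0, 1.0, axis=(1.0, 0.0)))
        wy = segment_plot(r, rect_boundary(0.0, 0.0, 2.0, 1.0, axis=(0.0, 1.0)))
        assert wx.values.shape == (10, 20)
        assert wy.values.shape == (20, 10)


class TestBinPlot:
    def test_exact_division(self):
        w = make_window(np.zeros((5, 200)))
        bins = bin_plot(w, 20)
        assert len(bins) == 20
        assert all(b.values.shape[1] == 10 for b in bins)

    def test_remainder_goes_to_first_bins(self):
        w = make_window(np.zeros((5, 203)))
        widths = [b.values.shape[1] for b in bin_plot(w, 20)]
        assert widths[:3] == [11, 11, 11]
        assert widths[3:] == [10] * 17
        assert sum(widths) == 203

    def test_single_bin_is_whole_window(self):
        w = make_window(np.zeros((5, 30)))
        (b,) = bin_plot(w, 1)
        assert b.values.shape == (5, 30)

    def test_too_few_columns(self):
        with pytest.raises(ResolutionError):
            bin_plot(make_window(np.zeros((5, 19))), 20)

    def test_bins_disjoint_and_exhaustive(self):
        w = make_window(np.arange(35.0).reshape(1, 35))
        bins = bin_plot(w, 4)
        cat = np.concatenate([b.values.ravel() for b in bins])
        assert np.array_equal(cat, w.values.ravel())


class TestBinPercentiles:
    def test_constant_window(self):
        assert bin_percentiles(make_window(np.full((3, 4), 7.5))) == (7.5, 7.5)

    def test_0_to_100_gives_3_and_97(self):
        w = make_window(np.arange(101.0).reshape(1, 101))
        assert bin_percentiles(w) == pytest.approx((3.0, 97.0))

    def test_1_to_10_interpolation(self):
        # hand evaluation: index = (n-1) p/100 -> 0.27 and 8.73
        w = make_window(np.arange(1.0, 11.0).reshape(2, 5))
        lo, hi = bin_percentiles(w)
        assert lo == pytest.approx(1.27)
        assert hi == pytest.approx(9.73)

    def test_all_nodata_bin(self):
        w = make_window(np.zeros((2, 2)), mask=np.zeros((2, 2), dtype=bool))
        with pytest.raises(EmptyBinError):
            bin_percentiles(w)

    def test_matches_sort_based_oracle(self, rng):
        # oracle: explicit linear interpolation between order statistics
        for _ in range(200):
            vals = rng.normal(size=rng.integers(2, 60))
            w = make_window(vals.reshape(1, -1))
            lo, hi = bin_percentiles(w, 3, 97)
            s = np.sort(vals)
            n = len(s)
            for p, got in ((3, lo), (97, hi)):
                idx = (n - 1) * p / 100
                f, c = int(np.floor(idx)), int(np.ceil(idx))
                exp = s[f] + (idx - f) * (s[c] - s[f])
                assert got == pytest.approx(exp, abs=1e-9)


class TestPlotHeight:
    def test_ground_is_min_of_bin_lows(self):
        prof = make_profile([10.2, 10.0, 10.4, 10.3], [11, 11, 11, 11])
        assert ground_height(prof) == 10.0
        assert ground_height(make_profile([10.0] * 4, [11] * 4)) == 10.0

    def test_constant_heights(self):
        prof = make_profile([5.0] * 20, [5.0 + 1.7] * 20)
        assert plot_mean_height(prof) == pytest.approx(1.7)

    def test_middle_12_trimmed_to_10(self):
        # middle-12 bin heights 1..12 -> trim 1 and 12 -> mean(2..11) = 6.5
        highs = np.zeros(20)
        highs[4:16] = np.arange(1.0, 13.0)
        prof = make_profile(np.zeros(20), highs)
        assert plot_mean_height(prof) == pytest.approx(6.5)

    def test_exactly_ten_values_averaged(self):
        highs = np.zeros(20)
        highs[4:16] = [3, 9, 1, 7, 5, 8, 2, 6, 4, 10, 11, 12]
        prof = make_profile(np.zeros(20), highs)
        mid = np.sort(highs[4:16])
        assert plot_mean_height(prof) == pytest.approx(mid[1:11].mean())

    def test_outer_bins_ignored_unless_ground_changes(self):
        highs = np.zeros(20)
        highs[4:16] = np.arange(1.0, 13.0)
        base = make_profile(np.zeros(20), highs)
        pert = make_profile(np.zeros(20), highs.copy())
        pert.p_high[0] = 99.0  # outer bin, p_low untouched
        pert.p_high[19] = -5.0
        assert plot_mean_height(pert) == plot_mean_height(base)
        lower_ground = make_profile(np.r_[[-1.0], np.zeros(19)], highs)
        assert plot_mean_height(lower_ground) == pytest.approx(plot_mean_height(base) + 1.0)

    def test_perturbing_middle_bin_acts_through_trim(self):
        highs = np.zeros(20)
        highs[4:16] = np.arange(1.0, 13.0)
        base = make_profile(np.zeros(20), highs)
        pert = make_profile(np.zeros(20), highs.copy())
        pert.p_high[10] = 100.0  # was height 7; now trimmed as the max
        # remaining average: {1..12} minus {7} plus trim of min(1) -> mean of 2..6,8..12
        expected = np.mean([2, 3, 4, 5, 6, 8, 9, 10, 11, 12])
        assert plot_mean_height(pert) == pytest.approx(expected)
        assert plot_mean_height(base) == pytest.approx(6.5)

    def test_reflection_invariance(self):
        highs = np.zeros(20)
        highs[4:16] = [3, 9, 1, 7, 5, 8, 2, 6, 4, 10, 11, 12]
        prof = make_profile(np.zeros(20), highs)
        flipped = make_profile(np.zeros(20), highs[::-1].copy())
        assert plot_mean_height(prof) == pytest.approx(plot_mean_height(flipped))

    def test_negative_bin_heights_floored(self):
        highs = np.full(20, 0.5)
        highs[8] = -0.2  # below the ground estimate
        prof = make_profile(np.zeros(20), highs)
        assert (prof.bin_heights() >= 0).all()

    def test_wrong_bin_count_with_defaults(self):
        prof = make_profile(np.zeros(10), np.ones(10))
        with pytest.raises(ConfigurationError):
            plot_mean_height(prof)


class TestP95:
    def test_constant_plateau(self):
        w = make_window(np.full((10, 40), 101.5))
        assert plot_p95_height(w, 100.0) == pytest.approx(1.5)

    def test_0_to_100_with_ground_zero(self):
        w = make_window(np.arange(101.0).reshape(1, 101))
        assert plot_p95_height(w, 0.0) == pytest.approx(95.0)

    def test_gradient_scene_p95_exceeds_binned_mean(self):
        # height ramps along the row: the whole-plot 95th percentile sits in
        # the tallest region while the trimmed bin mean averages the middle
        ramp = np.tile(np.linspace(0.0, 2.0, 200), (20, 1))
        w = make_window(ramp)
        prof = bin_profile(w, 20)
        binned = plot_mean_height(prof)
        p95 = plot_p95_height(w, ground_height(prof))
        assert p95 > binned


class TestExtractField:
    def _scene(self, n_dates=3, fail_date=None):
        rasters, boundaries = [], []
        for i in range(n_dates):
            data = np.full((30, 120), 10.0, dtype=np.float32)
            data[5:25, 10:50] = 10.0 + 0.5 * (i + 1)  # plot 1 canopy
            data[5:25, 60:100] = 10.0 + 0.3 * (i + 1)  # plot 2 canopy
            date = dt.date(2018, 6, 1) + dt.timedelta(days=7 * i)
            if fail_date == i:
                data[:, 55:] = np.nan
            rasters.append(make_raster(data, gsd=0.1, date=date))
        boundaries = [
            rect_boundary(0.5, 0.2, 5.3, 2.8, plot_id="P1", planting_date="2018-05-14"),
            rect_boundary(5.7, 0.2, 10.5, 2.8, plot_id="P2", planting_date="2018-05-14"),
        ]
        return rasters, boundaries

    def test_record_count(self):
        rasters, boundaries = self._scene(3)
        tab, fails = extract_field(rasters, boundaries)
        assert len(tab) == 6 and not fails

    def test_single_plot_single_date(self):
        rasters, boundaries = self._scene(1)
        tab, fails = extract_field(rasters[:1], boundaries[:1])
        assert len(tab) == 1
        assert tab.days_after_sowing.iloc[0] == 18

    def test_nodata_plot_logged_not_fatal(self):
        rasters, boundaries = self._scene(3, fail_date=1)
        tab, fails = extract_field(rasters, boundaries)
        assert len(tab) == 5
        assert len(fails) == 1
        assert fails[0]["plot_id"] == "P2"

    def test_both_methods_per_record(self):
        rasters, boundaries = self._scene(1)
        cfg = ExtractionConfig(methods=("binned_trimmed", "p95_whole_plot"))
        tab, _ = extract_field(rasters[:1], boundaries, cfg)
        assert sorted(tab.method.unique()) == ["binned_trimmed", "p95_whole_plot"]
        assert len(tab) == 4
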