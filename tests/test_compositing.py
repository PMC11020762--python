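"""Temporal composites, S-G smoothing, index curves, window selection."""

import datetime as dt

import numpy as np
import pytest

from rectile.compositing import (
    IndexCurve,
    TimeWindow,
    mean_index_curve,
    monthly_composites,
    negate,
    select_window,
    sg_smooth,
    temporal_composite,
)
from rectile.errors import DegenerateCurveError, ExtentError, ParameterError
from rectile.raster import RasterStack, SamplePoint, TemporalStack

from conftest import make_temporal

NAN = np.nan


def curve_of(values, start="2018-03-01", step=8, name="NDVI"):
    d0 = dt.date.fromisoformat(start)
    dates = [d0 + dt.timedelta(days=step * i) for i in range(len(values))]
    return IndexCurve(dates, np.asarray(values, dtype=float), name)


class TestTemporalComposite:
    def test_median_of_odd_series(self):
        ts = make_temporal([np.full((4, 4), v) for v in (0.2, 0.5, 0.9)])
        comp = temporal_composite(ts, TimeWindow(ts.dates[0], ts.dates[-1]))
        np.testing.assert_allclose(comp.values[0], 0.5)

    def test_median_skips_nodata(self):
        a = np.full((4, 4), 0.2)
        b = np.full((4, 4), NAN)
        c = np.full((4, 4), 0.9)
        ts = make_temporal([a, b, c])
        comp = temporal_composite(ts, TimeWindow(ts.dates[0], ts.dates[-1]))
        np.testing.assert_allclose(comp.values[0], 0.55)

    @pytest.mark.parametrize(
        "reducer,expected", [("max", 0.7), ("min", 0.1), ("mean", 0.7 / 1.909)]
    )
    def test_other_reducers(self, reducer, expected):
        ts = make_temporal([np.full((2, 2), v) for v in (0.1, 0.7, 0.3)])
        comp = temporal_composite(
            ts, TimeWindow(ts.dates[0], ts.dates[-1]), reducer
        )
        if reducer == "mean":
            expected = (0.1 + 0.7 + 0.3) / 3
        np.testing.assert_allclose(comp.values[0], expected, rtol=1e-6)

    def test_all_nodata_pixel_stays_nodata(self):
        a = np.full((2, 2), NAN)
        a[0, 0] = 1.0
        ts = make_temporal([a, a.copy()])
        comp = temporal_composite(ts, TimeWindow(ts.dates[0], ts.dates[-1]))
        assert not comp.nodata_mask[0, 0]
        assert comp.nodata_mask[1, 1]

    def test_empty_window_error_lists_dates(self):
        ts = make_temporal([np.zeros((2, 2))] * 2)
        with pytest.raises(ExtentError, match="2018-05-01"):
            temporal_composite(
                ts, TimeWindow(dt.date(2019, 1, 1), dt.date(2019, 2, 1))
            )

    def test_permutation_invariance_within_window(self):
        rng = np.random.default_rng(3)
        arrays = [rng.random((3, 3)) for _ in range(5)]
        ts = make_temporal(arrays)
        comp = temporal_composite(ts, TimeWindow(ts.dates[0], ts.dates[-1]))
        ts2 = make_temporal(arrays[::-1])  # same dates, values re-ordered
        comp2 = temporal_composite(ts2, TimeWindow(ts.dates[0], ts.dates[-1]))
        np.testing.assert_allclose(comp.values, comp2.values)

    def test_single_valid_observation_is_identity(self):
        a = np.arange(4.0).reshape(2, 2)
        ts = make_temporal([a])
        comp = temporal_composite(ts, TimeWindow(ts.dates[0], ts.dates[0]))
        np.testing.assert_allclose(comp.values[0], a)


class TestMonthlyComposites:
    def _stack(self):
        dates = [dt.date(2018, m, d) for m in range(5, 11) for d in (5, 20)]
        arrays = [np.full((2, 2), float(i)) for i in range(len(dates))]
        return make_temporal(arrays, dates=dates)

    def test_six_growing_season_months(self):
        ts = self._stack()
        months = [(2018, m) for m in range(5, 11)]
        comps = monthly_composites(ts, months)
        assert len(comps) == 6
        assert comps[0].band_names == ["v_2018-05"]

    def test_months_reordered_input_sorted_output(self):
        ts = self._stack()
        comps = monthly_composites(ts, [(2018, 7), (2018, 5), (2018, 6)])
        assert [c.band_names[0] for c in comps] == [
            "v_2018-05", "v_2018-06", "v_2018-07"
        ]

    def test_single_date_month_equals_that_image(self):
        dates = [dt.date(2018, 5, 15)]
        ts = make_temporal([np.full((2, 2), 7.0)], dates=dates)
        comps = monthly_composites(ts, [(2018, 5)])
        np.testing.assert_allclose(comps[0].values[0], 7.0)

    def test_empty_month_raises(self):
        ts = self._stack()
        with pytest.raises(ExtentError):
            monthly_composites(ts, [(2019, 1)])


class TestSgSmooth:
    def test_linear_series_unchanged_interior(self):
        c = curve_of(np.linspace(0.1, 0.9, 15))
        s = sg_smooth(c, 7, 2)
        np.testing.assert_allclose(s.values[3:-3], c.values[3:-3], atol=1e-12)

    def test_constant_series_unchanged(self):
        c = curve_of([0.4] * 11)
        s = sg_smooth(c, 7, 2)
        np.testing.assert_allclose(s.values, 0.4, atol=1e-12)

    def test_polynomial_reproduction_up_to_order(self):
        t = np.arange(21, dtype=float)
        c = curve_of(0.01 * t**2 - 0.1 * t + 1)
        s = sg_smooth(c, 7, 2)
        np.testing.assert_allclose(s.values[3:-3], c.values[3:-3], atol=1e-10)

    def test_impulse_spike_strictly_reduced(self):
        vals = np.full(15, 0.2)
        vals[7] = 0.9
        c = curve_of(vals)
        s = sg_smooth(c, 7, 2)
        assert abs(s.values[7] - 0.2) < abs(0.9 - 0.2)

    @pytest.mark.parametrize(
        "window,order,n", [(6, 2, 10), (7, 7, 10), (7, 2, 5)]
    )
    def test_invalid_parameters(self, window, order, n):
        with pytest.raises(ParameterError):
            sg_smooth(curve_of([0.1] * n), window, order)


class TestMeanIndexCurve:
    def _coarse(self):
        # 2 dates; NDVI from red/nir bands
        entries = []
        for i, d in enumerate([dt.date(2018, 6, 1), dt.date(2018, 7, 1)]):
            red = np.full((2, 2), 0.1)
            nir = np.full((2, 2), 0.3 + 0.3 * i)
            nir[0, 1] = 0.9  # distinct pixel
            stack = RasterStack(
                ["red", "nir"], np.stack([red, nir]), (0, 2, 1, 1)
            )
            entries.append((d, stack))
        return TemporalStack(entries, "coarse")

    def test_mean_over_two_points(self):
        ts = self._coarse()
        pts = [
            SamplePoint(0.5, 1.5, "grassland"),  # pixel (0,0)
            SamplePoint(1.5, 1.5, "grassland"),  # pixel (0,1), nir 0.9
        ]
        curve = mean_index_curve(ts, "NDVI", pts)
        ndvi_a = (0.3 - 0.1) / 0.4
        ndvi_b = (0.9 - 0.1) / 1.0
        assert curve.values[0] == pytest.approx((ndvi_a + ndvi_b) / 2, rel=1e-6)

    def test_identical_points_equal_pixel_series(self):
        ts = self._coarse()
        pts = [SamplePoint(0.5, 0.5, "grassland")] * 3
        curve = mean_index_curve(ts, "NDVI", pts)
        assert curve.values[0] == pytest.approx(0.5)  # (0.3-0.1)/0.4
        assert curve.values[1] == pytest.approx(0.7142857, rel=1e-5)

    def test_empty_points_rejected(self):
        with pytest.raises(ParameterError):
            mean_index_curve(self._coarse(), "NDVI", [])


class TestSelectWindow:
    def test_explicit_mode_echoes_window(self):
        w = TimeWindow.parse("2018-05-09", "2018-08-12")
        c = curve_of([0.1, 0.5, 0.1])
        assert select_window(c, "explicit", explicit=w) == w

    def test_triangular_curve_symmetric_window(self):
        d0 = dt.date(2018, 1, 1)
        days = np.arange(100, 301)
        vals = np.maximum(0, 1 - np.abs(days - 200) / 100)
        c = IndexCurve([d0 + dt.timedelta(int(d)) for d in days], vals)
        w = select_window(c, "peak_fraction", 0.5)
        peak = d0 + dt.timedelta(200)
        assert (peak - w.start) == (w.end - peak)

    def test_gaussian_half_width_closed_form(self):
        # value >= half max on |t - 200| <= sigma * sqrt(2 ln 2) =~ 23.55 d
        d0 = dt.date(2018, 1, 1)
        days = np.arange(100, 301)
        vals = np.exp(-((days - 200.0) ** 2) / (2 * 20.0**2))
        c = IndexCurve([d0 + dt.timedelta(int(d)) for d in days], vals)
        w = select_window(c, "peak_fraction", 0.5)
        half_width = 20.0 * np.sqrt(2 * np.log(2))
        lo = (w.start - d0).days
        hi = (w.end - d0).days
        assert lo == pytest.approx(200 - half_width, abs=1.0)
        assert hi == pytest.approx(200 + half_width, abs=1.0)

    def test_window_contains_argmax_within_range(self):
        rng = np.random.default_rng(5)
        vals = np.cumsum(rng.normal(size=30))
        c = curve_of(vals)
        w = select_window(c, "peak_fraction", 0.5)
        peak_date = c.dates[int(np.argmax(vals))]
        assert c.dates[0] <= w.start <= peak_date <= w.end <= c.dates[-1]

    def test_constant_curve_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            select_window(curve_of([0.3] * 10), "peak_fraction", 0.5)

    def test_negated_curve_selects_trough(self):
        vals = np.array([0.5, 0.2, -0.3, 0.2, 0.5])
        c = curve_of(vals, name="NDWI")
        w = select_window(negate(c), "peak_fraction", 0.9)
        assert w.start == w.end == c.dates[2]


def test_time_window_validation():
    with pytest.raises(ParameterError):
        TimeWindow(dt.date(2018, 6, 1), dt.date(2018, 5, 1))
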