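"""Climatology statistics: extremes, change fields, stress accounting."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from heatscape.climatology import (change_by_hour_doy, cumulative_stress_june_may,
                                   derive_summary, hour_month_aggregate,
                                   median_as_historic_percentile,
                                   median_first_occurrence_doy,
                                   percentile_bands_by_hour, site_extremes,
                                   stress_flags, stress_hours, summary_table)
from heatscape.timeseries import InputError, MetSeries


def _grids(values, times):
    return xr.DataArray(values, dims=("time", "y", "x"),
                        coords={"time": times})


def _year_index(year=1995):
    return pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")


class TestSiteExtremes:
    times = pd.date_range("1995-01-01", periods=3, freq="h")

    def test_uniform_grid(self):
        ext = site_extremes(_grids(np.full((3, 2, 2), 5.0), self.times))
        assert (ext["utci_max"] == 5.0).all() and (ext["utci_min"] == 5.0).all()

    def test_single_hot_cell(self):
        vals = np.zeros((3, 2, 2))
        vals[:, 1, 1] = 30.0
        ext = site_extremes(_grids(vals, self.times))
        assert (ext["utci_max"] == 30.0).all() and (ext["utci_min"] == 0.0).all()

    def test_invariant_to_cell_layout(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(15, 8, (3, 4, 4))
        a = site_extremes(_grids(vals, self.times))
        b = site_extremes(_grids(vals.reshape(3, 2, 8), self.times))
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_rejected(self):
        vals = np.full((3, 2, 2), np.nan)
        with pytest.raises(InputError):
            site_extremes(_grids(vals, self.times))


class TestChangeFields:
    def _members(self, shifts, year_h=1995, year_f=2045):
        hist, fut = [], []
        rng = np.random.default_rng(1)
        base = pd.Series(12 + rng.normal(0, 1, 8760), index=_year_index(year_h))
        for s in shifts:
            hist.append(base)
            fut.append(pd.Series(base.to_numpy() + s, index=_year_index(year_f)))
        return hist, fut

    def test_uniform_shift(self):
        hist, fut = self._members([1.0, 1.0])
        mean = change_by_hour_doy(hist, fut, "mean")
        sd = change_by_hour_doy(hist, fut, "sd")
        np.testing.assert_allclose(mean, 1.0, atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_two_member_arithmetic(self):
        hist, fut = self._members([1.0, 3.0])
        mean = change_by_hour_doy(hist, fut, "mean")
        sd = change_by_hour_doy(hist, fut, "sd")
        np.testing.assert_allclose(mean, 2.0, atol=1e-12)
        np.testing.assert_allclose(sd, np.sqrt(2.0), atol=1e-12)

    def test_injected_diurnal_cycle_recovered(self):
        idx_h, idx_f = _year_index(1995), _year_index(2045)
        rng = np.random.default_rng(3)
        cycle = 1.0 + 0.8 * np.cos(2 * np.pi * (idx_f.hour - 14) / 24)
        hist = [pd.Series(12 + rng.normal(0, 0.2, 8760), index=idx_h)]
        fut = [pd.Series(12 + cycle + rng.normal(0, 0.2, 8760), index=idx_f)]
        mean = change_by_hour_doy(hist, fut, "mean")
        by_hour = mean.mean(axis=1)
        target = 1.0 + 0.8 * np.cos(2 * np.pi * (np.arange(24) - 14) / 24)
        assert np.abs(by_hour - target).max() < 0.15

    def test_sd_needs_two_members(self):
        hist, fut = self._members([1.0])
        with pytest.raises(InputError):
            change_by_hour_doy(hist, fut, "sd")

    def test_hour_month_aggregation_shape(self):
        hist, fut = self._members([1.0, 2.0])
        agg = hour_month_aggregate(change_by_hour_doy(hist, fut, "mean"))
        assert agg.shape == (24, 12)
        np.testing.assert_allclose(agg, 1.5, atol=1e-12)


class TestMedianAsHistoricPercentile:
    def test_identical_distributions_near_50(self):
        idx_h = pd.date_range("1994-01-01", "1995-12-31 23:00", freq="h")
        rng = np.random.default_rng(0)
        hist = pd.Series(rng.normal(12, 3, len(idx_h)), index=idx_h)
        fut = pd.Series(hist.to_numpy(), index=idx_h)
        field = median_as_historic_percentile([hist], [fut])
        assert abs(np.nanmean(field) - 50.0) < 5.0

    def test_future_above_everything_is_100(self):
        idx = _year_index(1995)
        hist = pd.Series(np.zeros(len(idx)), index=idx)
        fut = pd.Series(np.full(len(idx), 99.0), index=idx)
        field = median_as_historic_percentile([hist], [fut])
        np.testing.assert_allclose(field, 100.0)

    def test_one_sd_shift_maps_to_84th(self):
        # 20 "years" of the same (hour, doy) group via a long flat series
        rng = np.random.default_rng(5)
        idx_h = pd.date_range("1981-01-01", "2000-12-31 23:00", freq="h")
        idx_f = pd.date_range("2041-01-01", "2060-12-31 23:00", freq="h")
        hist = pd.Series(rng.normal(0, 1, len(idx_h)), index=idx_h)
        fut = pd.Series(rng.normal(1, 1, len(idx_f)), index=idx_f)
        field = median_as_historic_percentile([hist], [fut])
        assert np.nanmean(field) == pytest.approx(84.1, abs=3.0)


class TestPercentileBands:
    def test_constant_series(self):
        idx = _year_index(1995)
        bands = percentile_bands_by_hour(pd.Series(7.0, index=idx))
        assert (bands == 7.0).all().all()

    def test_symmetric_contamination_keeps_median(self):
        idx = _year_index(1995)
        rng = np.random.default_rng(2)
        base = pd.Series(10.0, index=idx)
        noise = np.zeros(len(idx))
        noise[:200] = 50
        noise[200:400] = -50
        rng.shuffle(noise)
        bands = percentile_bands_by_hour(base + noise)
        np.testing.assert_allclose(bands["p50"], 10.0)

    def test_uniform_tail_order_statistic(self):
        idx = pd.date_range("1981-01-01", "2000-12-31 23:00", freq="h")
        rng = np.random.default_rng(9)
        bands = percentile_bands_by_hour(
            pd.Series(rng.uniform(0, 1, len(idx)), index=idx), levels=(95,))
        np.testing.assert_allclose(bands["p95"], 0.95, atol=0.02)

    def test_short_series_warns(self):
        idx = pd.date_range("1995-01-01", periods=48, freq="h")
        with pytest.warns(UserWarning, match="fewer than 20"):
            percentile_bands_by_hour(pd.Series(np.arange(48.0), index=idx))


class TestStressHours:
    def test_no_flags_all_zero(self):
        idx = _year_index(1995)
        t = stress_hours(pd.Series(False, index=idx))
        assert t.annual_total == 0.0

    def test_january_1400_counting(self):
        idx = pd.date_range("1995-01-01", "1996-12-31 23:00", freq="h")
        flags = pd.Series((idx.month == 1) & (idx.hour == 14), index=idx)
        t = stress_hours(flags)
        assert t.by_hour[14] == 31.0 and t.by_hour.sum() == 31.0
        assert t.by_month[0] == 31.0 and t.by_month.sum() == 31.0

    def test_month_and_hour_totals_agree(self):
        idx = _year_index(1995)
        rng = np.random.default_rng(4)
        flags = pd.Series(rng.random(len(idx)) < 0.03, index=idx)
        t = stress_hours(flags)
        assert t.by_month.sum() == pytest.approx(t.by_hour.sum(), abs=1e-12)
        assert t.annual_total == pytest.approx(flags.sum() / 1.0)

    def test_sitewide_must_nest_in_anycell(self):
        idx = pd.date_range("1995-01-01", periods=24, freq="h")
        site = pd.Series([True] + [False] * 23, index=idx)
        anyc = pd.Series(False, index=idx)
        with pytest.raises(InputError, match="scope"):
            stress_hours(site, scope_check=anyc)


class TestCumulativeJuneMay:
    def _flags(self, stamps, start="1994-06-01", end="1996-05-31 23:00"):
        idx = pd.date_range(start, end, freq="h")
        flags = pd.Series(False, index=idx)
        for s in stamps:
            flags.loc[pd.Timestamp(s)] = True
        return flags

    def test_single_flag_total_and_first_occurrence(self):
        recs = cumulative_stress_june_may(self._flags(["1994-10-10 14:00"]))
        assert recs[0].total == 1
        assert recs[0].first_occurrence == pd.Timestamp("1994-10-10 14:00")
        assert recs[0].cumulative.is_monotonic_increasing

    def test_may31_belongs_to_previous_june_span(self):
        recs = cumulative_stress_june_may(self._flags(["1995-05-31 23:00"]))
        assert recs[0].label == "1994/95" and recs[0].total == 1
        assert recs[1].total == 0 and recs[1].first_occurrence is None

    def test_known_totals_per_span(self):
        stamps = ["1994-07-01 12:00", "1994-12-25 15:00", "1995-02-01 10:00",
                  "1995-08-09 13:00"]
        recs = cumulative_stress_june_may(self._flags(stamps))
        assert [r.total for r in recs] == [3, 1]

    def test_incomplete_span_rejected(self):
        idx = pd.date_range("1995-01-01", "1995-12-31 23:00", freq="h")
        with pytest.raises(InputError, match="June"):
            cumulative_stress_june_may(pd.Series(False, index=idx))

    def test_median_first_occurrence_excludes_empty_seasons(self):
        recs = cumulative_stress_june_may(
            self._flags(["1994-11-20 12:00"]))
        month, day, excluded = median_first_occurrence_doy(recs)
        assert (month, day) == (11, 20) and excluded == 1


class TestSummaryTable:
    def test_identical_periods(self):
        idx = _year_index(1995)
        rng = np.random.default_rng(0)
        met = MetSeries(pd.DataFrame({
            "tair": 12 + rng.normal(0, 3, len(idx)),
            "rh": np.clip(70 + rng.normal(0, 5, len(idx)), 0, 100),
            "wind10": np.abs(rng.normal(3, 1, len(idx))),
            "swdown": np.abs(rng.normal(150, 50, len(idx)))}, index=idx))
        ext = pd.DataFrame({"utci_max": 12 + rng.normal(0, 8, len(idx))},
                           index=idx)
        ext["utci_min"] = ext["utci_max"] - 5
        ext["utci_mean"] = ext["utci_max"] - 2.5
        table = summary_table(met, met, ext, ext)
        np.testing.assert_allclose(table.variables["net_change"], 0.0, atol=1e-12)
        cf = table.stress["change_factor"].dropna()
        np.testing.assert_allclose(cf, 1.0, atol=1e-12)

    def test_zero_historic_percentage_flagged_undefined(self):
        stress = pd.DataFrame({"hist_pct": [0.0], "fut_pct": [1.0]},
                              index=["site_heat"])
        variables = pd.DataFrame({"hist_mean": [1.0], "fut_mean": [2.0]},
                                 index=["tair"])
        t = derive_summary(variables, stress)
        assert np.isnan(t.stress.loc["site_heat", "change_factor"])

    def test_scope_nesting_in_flags(self):
        idx = pd.date_range("1995-01-01", periods=100, freq="h")
        rng = np.random.default_rng(7)
        mx = rng.normal(20, 10, 100)
        mn = mx - np.abs(rng.normal(5, 2, 100))
        ext = pd.DataFrame({"utci_max": mx, "utci_min": mn,
                            "utci_mean": (mx + mn) / 2}, index=idx)
        f = stress_flags(ext)
        assert not (f["site_heat"] & ~f["any_heat"]).any()
        assert not (f["site_cold"] & ~f["any_cold"]).any()
        assert not (f["site_no_stress"] & ~f["any_no_stress"]).any()
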