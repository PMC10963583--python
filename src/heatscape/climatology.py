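"""Thermal-stress climatology statistics.

Everything downstream of the UTCI fields: site-wide extremes, mean-change
and ensemble-spread fields by hour × day-of-year, future medians
recontextualised as historic percentiles, percentile bands of site-wide
extremes by hour, stress-hour accounting by month and hour, cumulative
June→May stress seasons with first-occurrence dates, and the period
summary table (means, net changes, stress percentages and change
factors).

Site-wide stress scopes follow the extreme-value logic: *any-cell* heat
stress needs only the site maximum above the threshold (UTCI_max > 26),
*site-wide* heat stress needs every cell above it (UTCI_min > 26); cold
stress mirrors this with UTCI_min / UTCI_max below 0.  "No stress"
rollups are the complements: site-wide no stress means neither any-cell
heat nor any-cell cold; any-cell no stress means neither site-wide heat
nor site-wide cold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .timegroups import DAILY, build_time_groups
from .timeseries import VARIABLES, InputError, MetSeries
from .utci import StressScale

MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


# ---------------------------------------------------------------------------
# site-wide extremes
# ---------------------------------------------------------------------------

def site_extremes(utci_grids: xr.DataArray) -> pd.DataFrame:
    """Per-timestamp site-wide UTCI max, min and spatial mean.

    ``utci_grids`` is a (time, y, x) array; cells that are all-NaN at any
    timestamp raise, since extremes would be meaningless.
    """
    vals = utci_grids.values.reshape(utci_grids.shape[0], -1)
    if vals.shape[1] == 0 or np.isnan(vals).all(axis=1).any():
        raise InputError("site_extremes requires at least one valid cell per timestamp")
    idx = pd.DatetimeIndex(utci_grids["time"].values, name="time")
    return pd.DataFrame(
        {"utci_max": np.nanmax(vals, axis=1),
         "utci_min": np.nanmin(vals, axis=1),
         "utci_mean": np.nanmean(vals, axis=1)},
        index=idx)


def stress_flags(extremes: pd.DataFrame, scale: StressScale | None = None) -> pd.DataFrame:
    """Boolean rollup flags per timestamp from site-wide extremes."""
    scale = scale or StressScale()
    heat_thr, cold_thr = scale.heat[0], scale.cold[0]
    f = pd.DataFrame(index=extremes.index)
    f["any_heat"] = extremes["utci_max"] > heat_thr
    f["site_heat"] = extremes["utci_min"] > heat_thr
    f["any_cold"] = extremes["utci_min"] < cold_thr
    f["site_cold"] = extremes["utci_max"] < cold_thr
    f["site_no_stress"] = ~f["any_heat"] & ~f["any_cold"]
    f["any_no_stress"] = ~f["site_heat"] & ~f["site_cold"]
    f["strong_heat"] = extremes["utci_max"] > scale.heat[1]
    f["very_strong_heat"] = extremes["utci_max"] > scale.heat[2]
    return f


# ---------------------------------------------------------------------------
# change fields by hour × day of year
# ---------------------------------------------------------------------------

def _hour_doy_mean(series: pd.Series) -> np.ndarray:
    """(24, 365) per-(hour, doy) period mean (Feb 29 folded into Feb 28)."""
    tg = build_time_groups(series.index, DAILY)
    sums = np.bincount(tg.gid, weights=series.to_numpy(), minlength=tg.n_groups)
    counts = np.bincount(tg.gid, minlength=tg.n_groups)
    if np.any(counts == 0):
        raise InputError("incomplete year: empty (hour, day-of-year) groups")
    return (sums / counts).reshape(24, 365)


def change_by_hour_doy(hist_members: list[pd.Series], fut_members: list[pd.Series],
                       statistic: str = "mean") -> np.ndarray:
    """Ensemble mean or SD (n−1) of per-member (hour, doy) mean changes.

    Each member contributes the difference of its future-period and
    historic-period (hour, day-of-year) means; the ensemble statistic is
    taken across members, giving a (24, 365) field.
    """
    if len(hist_members) != len(fut_members):
        raise InputError("historic and future member lists must pair up")
    if statistic == "sd" and len(hist_members) < 2:
        raise InputError("ensemble SD needs at least two members")
    changes = np.stack([_hour_doy_mean(f) - _hour_doy_mean(h)
                        for h, f in zip(hist_members, fut_members)])
    if statistic == "mean":
        return changes.mean(axis=0)
    if statistic == "sd":
        return changes.std(axis=0, ddof=1)
    raise InputError(f"unknown statistic {statistic!r}")


def hour_month_aggregate(field24x365: np.ndarray) -> np.ndarray:
    """Collapse a (24, 365) field to (24, 12) calendar-month means."""
    doy_month = pd.date_range("2001-01-01", periods=365, freq="D").month.to_numpy()
    out = np.empty((24, 12))
    for m in range(12):
        out[:, m] = field24x365[:, doy_month == m + 1].mean(axis=1)
    return out


def median_as_historic_percentile(hist_members: list[pd.Series],
                                  fut_members: list[pd.Series]) -> np.ndarray:
    """Future-period medians as percentile ranks of the historic
    distribution, per (hour, day-of-year) group; ensemble mean across
    members.  Ranks beyond the historic range report 0 or 100.
    """
    fields = []
    for h, f in zip(hist_members, fut_members):
        tg_h = build_time_groups(h.index, DAILY)
        tg_f = build_time_groups(f.index, DAILY)
        hv, fv = h.to_numpy(), f.to_numpy()
        out = np.full(tg_h.n_groups, np.nan)
        order = np.lexsort((hv, tg_h.gid))
        counts = np.bincount(tg_h.gid, minlength=tg_h.n_groups)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        med = pd.Series(fv).groupby(tg_f.gid).median()
        for g in med.index:
            n = counts[g]
            if n == 0:
                continue  # flagged missing (NaN)
            sv = hv[order[starts[g]:starts[g] + n]]
            if n == 1:  # degenerate single-value history: rank by comparison
                out[g] = 0.0 if med[g] < sv[0] else (100.0 if med[g] > sv[0] else 50.0)
            else:
                out[g] = np.interp(med[g], sv, np.linspace(0.0, 100.0, n))
        fields.append(out.reshape(24, 365))
    return np.nanmean(np.stack(fields), axis=0)


def percentile_bands_by_hour(values: pd.Series,
                             levels=(5, 50, 95)) -> pd.DataFrame:
    """Empirical percentiles of a series per hour of day (rows 0–23)."""
    counts = values.groupby(values.index.hour).size()
    if (counts < 20).any() and (min(levels) < 25 or max(levels) > 75):
        warnings.warn("fewer than 20 values in some hours; tail percentiles "
                      "are unstable")
    out = values.groupby(values.index.hour).quantile([lv / 100 for lv in levels])
    bands = out.unstack()
    bands.columns = [f"p{lv:02d}" for lv in levels]
    bands.index.name = "hour"
    return bands


# ---------------------------------------------------------------------------
# stress-hour accounting
# ---------------------------------------------------------------------------

@dataclass
class StressHoursTable:
    """Annual mean stress hours by month (12) and by hour of day (24)."""

    by_month: np.ndarray
    by_hour: np.ndarray
    n_years: int

    @property
    def annual_total(self) -> float:
        return float(self.by_month.sum())

    def to_frame(self) -> pd.DataFrame:
        month = pd.Series(self.by_month, index=list(MONTH_NAMES), name="hours")
        hour = pd.Series(self.by_hour, index=range(24), name="hours")
        return pd.concat({"by_month": month, "by_hour": hour})


def stress_hours(flags: pd.Series, scope_check: pd.Series | None = None) -> StressHoursTable:
    """Annual mean flagged hours by month and by hour of day.

    ``flags`` is an hourly boolean series; totals divide by the number of
    calendar years spanned.  If ``scope_check`` (the corresponding
    any-cell flags for a site-wide rollup) is given, the site-wide ⊆
    any-cell nesting is enforced.
    """
    if flags.dtype != bool:
        raise InputError("stress flags must be boolean")
    if scope_check is not None and bool((flags & ~scope_check.astype(bool)).any()):
        raise InputError("site-wide stress without any-cell stress: scope mismatch")
    n_years = int(flags.index.year.nunique())
    fm = flags.groupby(flags.index.month).sum()
    fh = flags.groupby(flags.index.hour).sum()
    by_month = np.zeros(12)
    by_month[fm.index.to_numpy() - 1] = fm.to_numpy()
    by_hour = np.zeros(24)
    by_hour[fh.index.to_numpy()] = fh.to_numpy()
    return StressHoursTable(by_month / n_years, by_hour / n_years, n_years)


@dataclass
class CumulativeStressRecord:
    """One June→May season of cumulative stress hours."""

    label: str                      # e.g. "1995/96"
    cumulative: pd.Series           # running total, hourly
    total: int
    first_occurrence: pd.Timestamp | None


def cumulative_stress_june_may(flags: pd.Series) -> list[CumulativeStressRecord]:
    """Cumulative stress hours per complete June→May span.

    Spans run 1 June 00:00 through 31 May 23:00; incomplete spans at the
    series edges are dropped, and a series with no complete span raises.
    """
    if flags.dtype != bool:
        raise InputError("stress flags must be boolean")
    idx = flags.index
    season_year = np.where(idx.month >= 6, idx.year, idx.year - 1)
    records = []
    for year in np.unique(season_year):
        span = flags[season_year == year]
        expected = pd.Timestamp(f"{year}-06-01"), pd.Timestamp(f"{year + 1}-05-31 23:00")
        if span.index[0] != expected[0] or span.index[-1] != expected[1]:
            continue
        cum = span.astype(int).cumsum()
        hits = span[span]
        records.append(CumulativeStressRecord(
            label=f"{year}/{(year + 1) % 100:02d}",
            cumulative=cum,
            total=int(cum.iloc[-1]),
            first_occurrence=hits.index[0] if len(hits) else None,
        ))
    if not records:
        raise InputError("no complete June-May span in the series")
    return records


def median_first_occurrence_doy(records: list[CumulativeStressRecord]):
    """Median day of year of first occurrence across seasons.

    Seasons without any occurrence are excluded from the median and
    counted; days are expressed on the June-anchored axis (1 June = 0) so
    the median is taken within the season, then mapped back to a
    calendar (month, day).  Returns ``(month, day, n_excluded)``.
    """
    offsets = []
    n_excluded = 0
    for r in records:
        if r.first_occurrence is None:
            n_excluded += 1
            continue
        start = pd.Timestamp(f"{r.first_occurrence.year if r.first_occurrence.month >= 6 else r.first_occurrence.year - 1}-06-01")
        offsets.append((r.first_occurrence.normalize() - start).days)
    if not offsets:
        return None, None, n_excluded
    med = int(np.median(offsets))
    date = pd.Timestamp("2001-06-01") + pd.Timedelta(days=med)
    return date.month, date.day, n_excluded


# ---------------------------------------------------------------------------
# period summary table
# ---------------------------------------------------------------------------

STRESS_ROLLUPS = ("any_heat", "site_heat", "any_no_stress", "site_no_stress",
                  "any_cold", "site_cold")


@dataclass
class SummaryTable:
    """Period means / net changes and stress percentages / change factors."""

    variables: pd.DataFrame   # rows: variable; cols: hist_mean, fut_mean, net_change
    stress: pd.DataFrame      # rows: rollup; cols: hist_pct, fut_pct, change_factor

    def rounded(self) -> "SummaryTable":
        v = self.variables.copy()
        v[["hist_mean", "fut_mean", "net_change"]] = v[
            ["hist_mean", "fut_mean", "net_change"]].round(1)
        s = self.stress.copy()
        s[["hist_pct", "fut_pct"]] = s[["hist_pct", "fut_pct"]].round(2)
        s["change_factor"] = s["change_factor"].round(2)
        return SummaryTable(v, s)

    def __str__(self) -> str:
        return (self.variables.to_string(float_format="%.2f") + "\n\n"
                + self.stress.to_string(float_format="%.2f"))


def derive_summary(variables: pd.DataFrame, stress: pd.DataFrame) -> SummaryTable:
    """Fill in net changes and change factors from period values.

    ``variables`` needs hist_mean/fut_mean columns; ``stress`` needs
    hist_pct/fut_pct.  A zero historic percentage flags the change factor
    as undefined (NaN) rather than dividing by zero.
    """
    v = variables.copy()
    v["net_change"] = v["fut_mean"] - v["hist_mean"]
    s = stress.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        s["change_factor"] = np.where(s["hist_pct"] > 0,
                                      s["fut_pct"] / s["hist_pct"], np.nan)
    return SummaryTable(v, s)


def summary_table(hist_met: MetSeries, fut_met: MetSeries,
                  hist_extremes: pd.DataFrame, fut_extremes: pd.DataFrame,
                  scale: StressScale | None = None) -> SummaryTable:
    """Ensemble period summary: variable means, stress shares, factors."""
    rows = {}
    for v in VARIABLES:
        rows[v] = {"hist_mean": hist_met.data[v].mean(),
                   "fut_mean": fut_met.data[v].mean()}
    rows["utci"] = {"hist_mean": hist_extremes["utci_mean"].mean(),
                    "fut_mean": fut_extremes["utci_mean"].mean()}
    variables = pd.DataFrame(rows).T

    fh = stress_flags(hist_extremes, scale)
    ff = stress_flags(fut_extremes, scale)
    stress = pd.DataFrame({
        "hist_pct": {r: 100.0 * fh[r].mean() for r in STRESS_ROLLUPS},
        "fut_pct": {r: 100.0 * ff[r].mean() for r in STRESS_ROLLUPS},
    })
    return derive_summary(variables, stress)
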