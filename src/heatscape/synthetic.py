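"""Synthetic meteorology and toy urban scenes with known structure.

The generator emulates the statistical skeleton of an hourly reanalysis
and of downscaled climate-model output over a temperate mid-latitude
site: diurnal and annual harmonic cycles, AR(1) noise with cross-variable
dependence, a beta-mixture cloud process modulating a clear-sky shortwave
envelope, configurable model biases (offset/scale per variable), and a
configurable future change signal (additive for air temperature —
optionally month-resolved — multiplicative for the other drivers).
Because the injected biases and changes are known exactly, every
downstream stage can be tested for recovery of the truth.

Relative humidity is generated on the logit scale and wind speed on the
log scale, then back-transformed, so marginals respect their physical
bounds without hard clipping artefacts.  Cloud transmission is a daily
beta-distributed value with day-to-day AR(1) persistence, floored to
exact zeros below 0.02 so that overcast days exercise the zero-shortwave
code paths downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, special, stats
from shapely.geometry import Point, Polygon

from .rasters import SiteRasters
from .solar import SunPosition, clear_sky_shortwave, solar_position
from .timeseries import VARIABLES, MetSeries


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class VarConfig:
    """Harmonic-cycle + AR(1) parameters for one driver variable.

    ``mean`` is on the natural scale (°C, %, m/s); cycle amplitudes and
    noise act on the generation scale (°C for temperature, logit of
    rh/100, log wind speed).  ``diurnal_phase`` is the local hour of the
    daily peak, ``annual_phase_doy`` the day of year of the annual peak.
    """

    mean: float
    diurnal_amplitude: float = 0.0
    annual_amplitude: float = 0.0
    diurnal_phase: float = 15.0
    annual_phase_doy: float = 15.0  # mid-January: southern-hemisphere summer
    ar1: float = 0.8
    noise_sd: float = 1.0
    bias_offset: float = 0.0
    bias_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1 < 1.0):
            raise ConfigError("AR(1) coefficient must be in [0, 1)")
        if self.diurnal_amplitude < 0 or self.annual_amplitude < 0:
            raise ConfigError("amplitudes must be non-negative")


#: default cross-correlation of the hourly innovations, order (tair, rh,
#: wind10, cloud-clearness).  Warm anomalies dry the air and clear the sky.
DEFAULT_CROSS_CORR = np.array([
    [1.0, -0.6, 0.1, 0.4],
    [-0.6, 1.0, -0.1, -0.5],
    [0.1, -0.1, 1.0, 0.0],
    [0.4, -0.5, 0.0, 1.0],
])


@dataclass
class SynthConfig:
    """Full configuration of the synthetic meteorology generator.

    Defaults sketch a temperate oceanic (Cfb) climate at the package's
    default site (42.883° S, 147.330° E): annual-mean air temperature
    ~12 °C with a ~10 °C seasonal swing, humid (~70 %), moderately windy
    (~3.3 m/s), with mixed clear/overcast cloud.
    """

    tair: VarConfig = field(default_factory=lambda: VarConfig(
        mean=12.0, diurnal_amplitude=3.5, annual_amplitude=5.0,
        diurnal_phase=15.0, ar1=0.95, noise_sd=2.5))
    rh: VarConfig = field(default_factory=lambda: VarConfig(
        mean=70.0, diurnal_amplitude=0.35, annual_amplitude=0.1,
        diurnal_phase=5.0, annual_phase_doy=196.0, ar1=0.9, noise_sd=0.5))
    wind10: VarConfig = field(default_factory=lambda: VarConfig(
        mean=3.3, diurnal_amplitude=0.2, annual_amplitude=0.08,
        diurnal_phase=15.0, annual_phase_doy=330.0, ar1=0.9, noise_sd=0.45))
    # future change signal: additive °C for tair (scalar or 12 monthly
    # values), multiplicative factors for the rest
    tair_change: float | tuple | list = 1.4
    rh_change: float = 0.99
    wind_change: float = 1.0
    swdown_change: float = 1.03
    # cloud process (daily beta transmission with AR(1) persistence)
    cloud_beta_a: float = 0.9
    cloud_beta_b: float = 0.6
    cloud_ar1: float = 0.55
    swdown_bias_scale: float = 1.0
    cross_corr: np.ndarray = field(default_factory=lambda: DEFAULT_CROSS_CORR.copy())
    latitude: float = -42.883
    longitude: float = 147.330
    tz_offset_hours: float = 10.0
    start_year: int = 1995
    end_year: int = 1996
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.cross_corr, dtype=float)
        if c.shape != (4, 4) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ConfigError("cross-correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() <= 1e-10:
            raise ConfigError("cross-correlation matrix must be positive-definite")
        if self.end_year < self.start_year:
            raise ConfigError("end_year before start_year")
        self.cross_corr = c

    def period(self, start_year: int, end_year: int) -> "SynthConfig":
        return replace(self, start_year=start_year, end_year=end_year,
                       cross_corr=self.cross_corr.copy())


def _hourly_index(start_year: int, end_year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31 23:00",
                         freq="h", name="time")


def _cycles(idx: pd.DatetimeIndex, v: VarConfig) -> np.ndarray:
    hour = idx.hour.to_numpy(dtype=float)
    doy = idx.dayofyear.to_numpy(dtype=float)
    return (v.diurnal_amplitude * np.cos(2 * np.pi * (hour - v.diurnal_phase) / 24.0)
            + v.annual_amplitude * np.cos(2 * np.pi * (doy - v.annual_phase_doy) / 365.25))


def _ar1(eps: np.ndarray, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    innov = eps * sd * np.sqrt(1.0 - rho * rho)
    x = signal.lfilter([1.0], [1.0, -rho], innov)
    return x


def _cloud_transmission(eps_hourly: np.ndarray, idx: pd.DatetimeIndex,
                        cfg: SynthConfig) -> np.ndarray:
    """Per-hour shortwave transmission in [0, 1] from a daily beta process."""
    day = (idx.normalize().asi8 // 86_400_000_000_000)
    day = day - day[0]
    n_days = int(day[-1]) + 1
    # daily innovation: renormalised daily mean of the 4th hourly stream
    sums = np.bincount(day, weights=eps_hourly, minlength=n_days)
    counts = np.bincount(day, minlength=n_days).astype(float)
    eta = sums / np.sqrt(counts)
    z = _ar1(eta, cfg.cloud_ar1, 1.0)
    u = stats.norm.cdf(z)
    trans = stats.beta.ppf(u, cfg.cloud_beta_a, cfg.cloud_beta_b)
    trans[trans < 0.02] = 0.0  # exact overcast zeros
    return trans[day]


def _generate_base(cfg: SynthConfig, seed: int, start_year: int,
                   end_year: int) -> MetSeries:
    idx = _hourly_index(start_year, end_year)
    n = len(idx)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cfg.cross_corr)
    eps = rng.standard_normal((n, 4)) @ chol.T

    tair = cfg.tair.mean + _cycles(idx, cfg.tair) + _ar1(eps[:, 0], cfg.tair.ar1, cfg.tair.noise_sd)

    rh_lat = (special.logit(cfg.rh.mean / 100.0) + _cycles(idx, cfg.rh)
              + _ar1(eps[:, 1], cfg.rh.ar1, cfg.rh.noise_sd))
    rh = 100.0 * special.expit(rh_lat)

    w_lat = (np.log(cfg.wind10.mean) + _cycles(idx, cfg.wind10)
             + _ar1(eps[:, 2], cfg.wind10.ar1, cfg.wind10.noise_sd))
    wind = np.exp(w_lat)

    sun = solar_position(idx, cfg.latitude, cfg.longitude, cfg.tz_offset_hours)
    envelope = clear_sky_shortwave(sun)
    swdown = envelope * _cloud_transmission(eps[:, 3], idx, cfg)

    df = pd.DataFrame({"tair": tair, "rh": rh, "wind10": wind, "swdown": swdown},
                      index=idx)
    return MetSeries(df, cfg.tz_offset_hours).validate()


def gen_reference_series(cfg: SynthConfig, seed: int | None = None) -> MetSeries:
    """Reference ("reanalysis") hourly series over the configured period."""
    return _generate_base(cfg, cfg.seed if seed is None else seed,
                          cfg.start_year, cfg.end_year)


def _apply_bias(series: MetSeries, cfg: SynthConfig) -> MetSeries:
    m = series.matrix()
    biases = [cfg.tair, cfg.rh, cfg.wind10]
    for k, v in enumerate(biases):
        m[:, k] = v.bias_offset + v.bias_scale * m[:, k]
    m[:, 3] *= cfg.swdown_bias_scale
    m[:, 1] = np.clip(m[:, 1], 0.0, 100.0)
    m[:, 2] = np.maximum(m[:, 2], 0.0)
    return series.with_matrix(m)


def _apply_change(series: MetSeries, cfg: SynthConfig) -> MetSeries:
    m = series.matrix()
    ch = np.asarray(cfg.tair_change, dtype=float)
    if ch.ndim == 0:
        m[:, 0] += float(ch)
    else:
        if ch.shape != (12,):
            raise ConfigError("tair_change must be scalar or 12 monthly values")
        m[:, 0] += ch[series.index.month.to_numpy() - 1]
    m[:, 1] = np.clip(m[:, 1] * cfg.rh_change, 0.0, 100.0)
    m[:, 2] *= cfg.wind_change
    m[:, 3] *= cfg.swdown_change
    return series.with_matrix(m)


def gen_model_pair(cfg: SynthConfig, seed: int,
                   hist_years: tuple[int, int] | None = None,
                   future_years: tuple[int, int] = (2045, 2046)) -> tuple[MetSeries, MetSeries]:
    """Biased "model" series: (historical, future).

    The historical member shares the reference generator structure (its
    own weather realisation) with per-variable offset/scale biases; the
    future member additionally carries the configured change signal,
    applied to the underlying process before the biases, so the truth the
    bias correction should recover is known exactly.
    """
    hy = hist_years or (cfg.start_year, cfg.end_year)
    ss = np.random.SeedSequence(seed)
    s_hist, s_fut = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    hist = _apply_bias(_generate_base(cfg, s_hist, *hy), cfg)
    fut_base = _generate_base(cfg, s_fut, *future_years)
    fut = _apply_bias(_apply_change(fut_base, cfg), cfg)
    return hist.validate(), fut.validate()


# ---------------------------------------------------------------------------
# toy urban scenes
# ---------------------------------------------------------------------------

@dataclass
class Building:
    footprint: Polygon  # map coordinates, metres
    height: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ConfigError("building height must be positive")
        if not isinstance(self.footprint, Polygon):
            self.footprint = Polygon(self.footprint)


@dataclass
class Tree:
    centre: tuple[float, float]
    crown_radius: float
    crown_top: float
    trunk_height: float = 0.0

    def __post_init__(self) -> None:
        if self.crown_top <= 0 or self.crown_radius <= 0:
            raise ConfigError("tree dimensions must be positive")
        if not (0 <= self.trunk_height < self.crown_top):
            raise ConfigError("trunk height must sit below the crown top")


@dataclass
class SiteSpec:
    """Flat-ground toy scene: box buildings and parabolic tree crowns."""

    extent: tuple[float, float] = (150.0, 150.0)  # (x east, y north) metres
    buildings: list[Building] = field(default_factory=list)
    trees: list[Tree] = field(default_factory=list)
    ground_elevation: float = 0.0


def gen_site_rasters(spec: SiteSpec, cell_size: float = 1.0) -> SiteRasters:
    """Rasterise a toy scene at ``cell_size`` (row 0 = northern edge).

    The crown height profile is parabolic: crown top at the stem,
    descending to the trunk height at the crown edge.
    """
    if cell_size <= 0:
        raise ConfigError("cell size must be positive")
    ex, ey = spec.extent
    ncols = int(round(ex / cell_size))
    nrows = int(round(ey / cell_size))
    xs = (np.arange(ncols) + 0.5) * cell_size
    ys = ey - (np.arange(nrows) + 0.5) * cell_size  # row 0 at northern edge
    xg, yg = np.meshgrid(xs, ys)

    domain = Polygon([(0, 0), (ex, 0), (ex, ey), (0, ey)])
    for i, b in enumerate(spec.buildings):
        if not domain.contains(b.footprint):
            raise ConfigError(f"building {i} footprint outside the site extent")
        for other in spec.buildings[i + 1:]:
            if b.footprint.intersection(other.footprint).area > 0:
                raise ConfigError("overlapping building footprints")

    dem = np.full((nrows, ncols), float(spec.ground_elevation))
    bh = np.zeros_like(dem)
    from shapely import contains_xy

    for b in spec.buildings:
        mask = contains_xy(b.footprint, xg.ravel(), yg.ravel()).reshape(dem.shape)
        bh[mask] = np.maximum(bh[mask], b.height)

    chm = np.zeros_like(dem)
    trunk = np.zeros_like(dem)
    for t in spec.trees:
        cx, cy = t.centre
        r = np.hypot(xg - cx, yg - cy)
        inside = r <= t.crown_radius
        prof = t.trunk_height + (t.crown_top - t.trunk_height) * (
            1.0 - (r / t.crown_radius) ** 2)
        chm[inside] = np.maximum(chm[inside], prof[inside])
        trunk[inside] = np.where(chm[inside] <= prof[inside] + 1e-12,
                                 t.trunk_height, trunk[inside])

    return SiteRasters(dem=dem, dsm=dem + bh, chm=chm, cell_size=cell_size,
                       trunk=trunk, origin=(0.0, ey))


def default_demo_site(extent: float = 60.0) -> SiteSpec:
    """Small mixed scene: two buildings flanking a street, a few trees."""
    e = extent
    b1 = Building(Polygon([(e * 0.1, e * 0.55), (e * 0.45, e * 0.55),
                           (e * 0.45, e * 0.9), (e * 0.1, e * 0.9)]), height=12.0)
    b2 = Building(Polygon([(e * 0.55, e * 0.1), (e * 0.9, e * 0.1),
                           (e * 0.9, e * 0.45), (e * 0.55, e * 0.45)]), height=18.0)
    trees = [
        Tree((e * 0.25, e * 0.25), crown_radius=4.0, crown_top=9.0, trunk_height=2.5),
        Tree((e * 0.72, e * 0.72), crown_radius=5.0, crown_top=12.0, trunk_height=3.0),
        Tree((e * 0.5, e * 0.5), crown_radius=3.0, crown_top=7.0, trunk_height=2.0),
    ]
    return SiteSpec(extent=(e, e), buildings=[b1, b2], trees=trees)
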