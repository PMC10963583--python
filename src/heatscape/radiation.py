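"""Simplified SOLWEIG-style radiation model on 1 m urban rasters.

For every hour and every grid cell the model assembles the shortwave and
longwave flux densities incident on a cylindrical person at 1.5 m above
ground, sums them into the mean radiant flux density S_str, and converts
to mean radiant temperature

    T_mrt = (S_str / (eps_p * sigma))^(1/4) - 273.15,   eps_p = 0.97.

Geometry comes from a DEM/DSM/CHM raster stack: buildings block sunlight
completely, tree crowns (between trunk height and crown top) transmit 3 %
of shortwave and 0 % of longwave.  The sky view factor is a hemispheric
integration of horizon angles over azimuthal search directions.  Longwave
emission uses the Prata clear-sky emissivity with a cloud adjustment
inferred from the shortwave deficit, and a one-parameter sunlit-surface
warming for wall/ground temperatures.  The scheme deliberately omits
SOLWEIG's anisotropic sky radiance and prognostic wall temperatures.

Large scenes are evaluated tile by tile with a buffer wide enough to
contain the longest shadow cast into the tile, which makes the tiling
invisible in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .rasters import SiteRasters
from .solar import SunPosition, clear_sky_shortwave, solar_position, split_direct_diffuse
from .timeseries import InputError, MetSeries
from .utci import vapour_pressure

SIGMA = 5.670374419e-8  # Stefan-Boltzmann, W m-2 K-4


class ConfigError(ValueError):
    pass


@dataclass
class VegParams:
    """Radiative properties of tree crowns (evergreen, bulk values)."""

    sw_transmissivity: float = 0.03
    lw_transmissivity: float = 0.0
    albedo: float = 0.15
    emissivity: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.sw_transmissivity, self.lw_transmissivity,
                  self.albedo, self.emissivity):
            if not 0.0 <= v <= 1.0:
                raise ConfigError("vegetation parameters must lie in [0, 1]")


@dataclass
class PersonModel:
    """Cylindrical person: view weights and radiative properties.

    The up/down/4-lateral view weights (0.06/0.06/4×0.22) are the
    standard cylinder projection-factor weights; they must sum to one.
    """

    emissivity: float = 0.97
    sw_absorption: float = 0.70
    height: float = 1.5
    weight_up: float = 0.06
    weight_down: float = 0.06
    weight_lateral: float = 0.22

    def __post_init__(self) -> None:
        total = self.weight_up + self.weight_down + 4 * self.weight_lateral
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"view weights must sum to 1 (got {total})")


@dataclass
class RadiationConfig:
    """Numerical and surface parameters of the radiation scheme."""

    person: PersonModel = field(default_factory=PersonModel)
    veg: VegParams = field(default_factory=VegParams)
    ground_albedo: float = 0.20        # paved default
    ground_emissivity: float = 0.95
    surface_warming: float = 15.0      # deg C at full sun, see longwave_components
    svf_directions: int = 36
    max_radius: float = 50.0           # m; shadow & horizon search distance
    latitude: float = -42.883
    longitude: float = 147.330


@dataclass
class ShadowField:
    """Per-cell shortwave transmission plus shadow provenance flags."""

    transmission: np.ndarray
    building_shadow: np.ndarray
    veg_shadow: np.ndarray

    @property
    def sunlit(self) -> np.ndarray:
        return ~(self.building_shadow | self.veg_shadow)


def cast_shadow(rasters: SiteRasters, sun: SunPosition,
                veg: VegParams | None = None,
                max_radius: float | None = None,
                eval_height: float = 0.0) -> ShadowField:
    """Shadow volumes cast onto the ground plane (at ``eval_height``).

    A cell is building-shadowed when the discrete ray towards the sun
    (stepped one cell size at a time, nearest-cell sampling) meets the
    DSM above the ray height, and vegetation-shadowed when the ray passes
    through a crown volume (between trunk height and crown top); step
    zero covers self-occlusion, so cells inside building footprints or
    directly under a crown are shadowed at any sun position.
    Transmission is 0 under buildings and the crown shortwave
    transmissivity under vegetation alone.
    """
    veg = veg or VegParams()
    if sun.elevation <= 0:
        raise InputError("cast_shadow requires the sun above the horizon")
    cs = rasters.cell_size
    dem, dsm, chm, trunk = rasters.dem, rasters.dsm, rasters.chm, rasters.trunk
    z0 = dem + eval_height
    veg_top = dem + chm
    veg_base = dem + trunk
    has_veg = chm > 0

    azr = np.radians(sun.azimuth)
    tan_elev = np.tan(np.radians(sun.elevation))
    sin_az, cos_az = np.sin(azr), np.cos(azr)

    zmax = max(float(dsm.max()), float(veg_top.max()))
    nrows, ncols = dem.shape
    if max_radius is None:
        k_max = int(np.ceil(np.hypot(nrows, ncols)))
    else:
        k_max = int(np.floor(max_radius / cs))

    bshad = dsm > z0 + 1e-9  # k = 0: inside a building footprint
    vshad = has_veg & (z0 <= veg_top) & (z0 >= veg_base)
    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    for k in range(1, k_max + 1):
        dz = k * cs * tan_elev
        zk = z0 + dz
        if z0.min() + dz > zmax:
            break
        dr = int(np.rint(-k * cos_az))   # row 0 is north
        dc = int(np.rint(k * sin_az))
        r_src = rows + dr
        c_src = cols + dc
        valid = (r_src >= 0) & (r_src < nrows) & (c_src >= 0) & (c_src < ncols)
        rs = np.clip(r_src, 0, nrows - 1)
        cc = np.clip(c_src, 0, ncols - 1)
        bshad |= valid & (dsm[rs, cc] > zk)
        vshad |= valid & has_veg[rs, cc] & (zk <= veg_top[rs, cc]) & (zk >= veg_base[rs, cc])

    trans = np.where(bshad, 0.0, np.where(vshad, veg.sw_transmissivity, 1.0))
    return ShadowField(transmission=trans, building_shadow=bshad,
                       veg_shadow=vshad & ~bshad)


def sky_view_factor(rasters: SiteRasters, n_directions: int = 36,
                    max_radius: float | None = None,
                    eval_height: float = 0.0) -> np.ndarray:
    """Per-cell sky view factor in [0, 1].

    For each of ``n_directions`` azimuths the maximum horizon angle gamma
    along the ray is found against the opaque surface (DSM or crown top —
    crowns are opaque at the default 0 % longwave transmissivity), and
    the isotropic-sky weight cos²(gamma) is averaged over azimuths; for
    an infinitely long canyon this reproduces the analytic
    cos(arctan(2H/W)) at the floor centre.
    """
    cs = rasters.cell_size
    obstacle = np.maximum(rasters.dsm, rasters.dem + rasters.chm)
    z0 = rasters.dem + eval_height
    nrows, ncols = z0.shape
    if max_radius is None:
        k_max = int(np.ceil(np.hypot(nrows, ncols)))
    else:
        k_max = int(np.floor(max_radius / cs))
    zmax = float(obstacle.max())

    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    svf = np.zeros(z0.shape)
    for az in np.arange(n_directions) * (2 * np.pi / n_directions):
        max_tan = np.zeros(z0.shape)
        sin_az, cos_az = np.sin(az), np.cos(az)
        for k in range(1, k_max + 1):
            dist = k * cs
            dr = int(np.rint(-k * cos_az))
            dc = int(np.rint(k * sin_az))
            r_src = rows + dr
            c_src = cols + dc
            valid = (r_src >= 0) & (r_src < nrows) & (c_src >= 0) & (c_src < ncols)
            rs = np.clip(r_src, 0, nrows - 1)
            cc = np.clip(c_src, 0, ncols - 1)
            tan_h = np.where(valid, (obstacle[rs, cc] - z0) / dist, 0.0)
            np.maximum(max_tan, tan_h, out=max_tan)
        svf += 1.0 / (1.0 + max_tan ** 2)  # cos^2 of the horizon angle
    return svf / n_directions


def prata_emissivity(tair_k, vp_hpa):
    """Prata (1996) clear-sky atmospheric emissivity from vapour pressure."""
    w = 46.5 * np.asarray(vp_hpa, dtype=float) / np.asarray(tair_k, dtype=float)
    return 1.0 - (1.0 + w) * np.exp(-np.sqrt(1.2 + 3.0 * w))


def longwave_components(tair: float, rh: float, cloud_fraction: float,
                        svf: np.ndarray, sun_fraction: np.ndarray,
                        config: RadiationConfig):
    """Longwave flux densities (down, up, lateral) per cell, W/m².

    ``sun_fraction`` is the cell's absorbed-shortwave ratio (received
    global shortwave over the clear-sky maximum, in [0, 1]) driving the
    sunlit-surface warming T_s = T_air + a·sun_fraction with a =
    ``surface_warming``.  Sky emission blends the Prata clear-sky
    emissivity towards blackbody with cloud fraction.  Wall emission uses
    a single-bounce radiosity closure so an isothermal enclosure
    (svf = 0, all surfaces at T_air) radiates exactly sigma·T_air^4.
    """
    ta_k = tair + 273.15
    vp = vapour_pressure(tair, rh)
    eps_clear = prata_emissivity(ta_k, vp)
    eps_sky = eps_clear + (1.0 - eps_clear) * np.clip(cloud_fraction, 0.0, 1.0)
    l_sky = eps_sky * SIGMA * ta_k ** 4

    eps_s = config.ground_emissivity
    ts_k = ta_k + config.surface_warming * np.clip(sun_fraction, 0.0, 1.0)
    emit = eps_s * SIGMA * ts_k ** 4
    # radiosity of enclosing surfaces: J = eps*sigma*Ts^4 + (1-eps)*E_inc,
    # E_inc = svf*Lsky + (1-svf)*J  =>  closed form below
    j_wall = (emit + (1.0 - eps_s) * svf * l_sky) / (1.0 - (1.0 - eps_s) * (1.0 - svf))
    l_down = svf * l_sky + (1.0 - svf) * j_wall
    l_up = emit + (1.0 - eps_s) * l_down
    l_lat = 0.5 * l_down + 0.5 * l_up   # each of the four cardinal directions
    return l_down, l_up, l_lat


def shortwave_components(dni: float, dhi: float, sun: SunPosition,
                         shadow: ShadowField | None, svf: np.ndarray,
                         config: RadiationConfig):
    """Shortwave flux densities on the cylinder (down, up, 4 lateral)."""
    if shadow is None:  # night
        zero = np.zeros_like(svf)
        return zero, zero, [zero] * 4
    trans = shadow.transmission
    cosz = max(np.cos(np.radians(sun.zenith)), 0.0)
    sinz = np.sin(np.radians(sun.zenith))
    k_down = trans * dni * cosz + svf * dhi
    k_up = config.ground_albedo * k_down
    k_lat = []
    for az_face in (0.0, 90.0, 180.0, 270.0):  # N, E, S, W facing faces
        inc = max(np.cos(np.radians(sun.azimuth - az_face)), 0.0)
        k_lat.append(trans * dni * sinz * inc + 0.5 * (0.5 * svf * dhi + 0.5 * k_up))
    return k_down, k_up, k_lat


def mean_radiant_flux(k_down, k_up, k_lat, l_down, l_up, l_lat,
                      person: PersonModel | None = None) -> np.ndarray:
    """S_str: absorption-weighted directional sum of all flux densities."""
    p = person or PersonModel()
    for comp in (k_down, k_up, *k_lat, l_down, l_up, l_lat):
        if np.any(np.asarray(comp) < 0):
            raise InputError("negative radiation component")
    k_sum = p.weight_up * k_down + p.weight_down * k_up + p.weight_lateral * sum(k_lat)
    l_sum = p.weight_up * l_down + p.weight_down * l_up + 4 * p.weight_lateral * l_lat
    return p.sw_absorption * k_sum + p.emissivity * l_sum


def tmrt_from_sstr(sstr, person: PersonModel | None = None):
    """Invert S_str to mean radiant temperature in °C (exact closed form)."""
    p = person or PersonModel()
    s = np.asarray(sstr, dtype=float)
    if np.any(s < 0):
        raise InputError("S_str must be non-negative")
    return (s / (p.emissivity * SIGMA)) ** 0.25 - 273.15


def cloud_fraction_series(met: MetSeries, config: RadiationConfig) -> np.ndarray:
    """Hourly cloud-fraction estimate from the shortwave deficit.

    Daytime: 1 − swdown/clear-sky (clipped to [0, 1]); night-time hours
    carry the last daytime estimate forward (0.5 before the first day).
    """
    sun = solar_position(met.index, config.latitude, config.longitude,
                         met.tz_offset_hours)
    cs = clear_sky_shortwave(sun)
    frac = np.full(len(met), np.nan)
    day = cs > 20.0
    frac[day] = np.clip(1.0 - met.data["swdown"].to_numpy()[day] / cs[day], 0.0, 1.0)
    s = pd.Series(frac).ffill().fillna(0.5)
    return s.to_numpy()


def tmrt_timeseries(rasters: SiteRasters, met: MetSeries,
                    config: RadiationConfig | None = None,
                    svf: np.ndarray | None = None) -> xr.DataArray:
    """T_mrt (°C) for every timestamp and cell of one (sub-)scene."""
    config = config or RadiationConfig()
    if svf is None:
        svf = sky_view_factor(rasters, config.svf_directions, config.max_radius)
    sun_all = solar_position(met.index, config.latitude, config.longitude,
                             met.tz_offset_hours)
    cs_all = clear_sky_shortwave(sun_all)
    cloud = cloud_fraction_series(met, config)
    d = met.data
    out = np.empty((len(met),) + rasters.shape, dtype=np.float32)
    for i in range(len(met)):
        sun = SunPosition(float(np.asarray(sun_all.azimuth)[i]),
                          float(np.asarray(sun_all.zenith)[i]))
        sw = float(d["swdown"].iloc[i])
        daytime = sun.elevation > 0 and sw > 0
        if daytime:
            shadow = cast_shadow(rasters, sun, config.veg, config.max_radius)
            dni, dhi = split_direct_diffuse(sw, sun)
            sun_fraction = shadow.transmission * sw / max(cs_all[i], sw, 1e-9)
        else:
            shadow, dni, dhi = None, 0.0, 0.0
            sun_fraction = np.zeros(rasters.shape)
        k_down, k_up, k_lat = shortwave_components(
            float(dni), float(dhi), sun, shadow, svf, config)
        l_down, l_up, l_lat = longwave_components(
            float(d["tair"].iloc[i]), float(d["rh"].iloc[i]), cloud[i],
            svf, sun_fraction, config)
        sstr = mean_radiant_flux(k_down, k_up, k_lat, l_down, l_up, l_lat,
                                 config.person)
        out[i] = tmrt_from_sstr(sstr, config.person)
    ny, nx = rasters.shape
    return xr.DataArray(
        out, dims=("time", "y", "x"),
        coords={"time": met.index,
                "y": np.arange(ny) * rasters.cell_size,
                "x": np.arange(nx) * rasters.cell_size},
        name="tmrt", attrs={"units": "degC"})


def run_tiled(rasters: SiteRasters, met: MetSeries, tile: float = 50.0,
              buffer: float = 50.0,
              config: RadiationConfig | None = None) -> xr.DataArray:
    """Tile-and-buffer evaluation of :func:`tmrt_timeseries` over a site.

    Each tile is evaluated on a window padded by ``buffer`` metres (the
    shadow/horizon search radius is capped at the buffer), then centre-
    cropped and concatenated; with a buffer at least as long as the
    longest shadow cast into a tile the result is independent of tiling.
    """
    config = config or RadiationConfig()
    if buffer < rasters.cell_size:
        raise ConfigError("buffer must be at least one cell")
    if tile <= 0:
        raise ConfigError("tile size must be positive")
    config = RadiationConfig(**{**config.__dict__, "max_radius": min(config.max_radius, buffer)})
    cs = rasters.cell_size
    t_cells = int(round(tile / cs))
    b_cells = int(round(buffer / cs))
    nrows, ncols = rasters.shape
    n_tr = int(np.ceil(nrows / t_cells))
    n_tc = int(np.ceil(ncols / t_cells))

    full = np.empty((len(met), nrows, ncols), dtype=np.float32)
    for tr in range(n_tr):
        for tc in range(n_tc):
            r0, c0 = tr * t_cells, tc * t_cells
            r1, c1 = min(r0 + t_cells, nrows), min(c0 + t_cells, ncols)
            wr0, wc0 = max(r0 - b_cells, 0), max(c0 - b_cells, 0)
            wr1, wc1 = min(r1 + b_cells, nrows), min(c1 + b_cells, ncols)
            window = rasters.window(wr0, wr1, wc0, wc1)
            da = tmrt_timeseries(window, met, config)
            full[:, r0:r1, c0:c1] = da.values[:, r0 - wr0:r1 - wr0, c0 - wc0:c1 - wc0]
    return xr.DataArray(
        full, dims=("time", "y", "x"),
        coords={"time": met.index, "y": np.arange(nrows) * cs,
                "x": np.arange(ncols) * cs},
        name="tmrt", attrs={"units": "degC"})
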