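"""Solar geometry and simple irradiance partitioning.

Solar azimuth/zenith follow the NOAA solar calculator closed form (a
truncated Meeus ephemeris, accurate to ~0.1–0.2° for 1900–2100), which is
ample for shadow casting at 1 m scale.  The clear-sky envelope is a
Meinel-style one-parameter transmittance; the direct/diffuse split uses
the Erbs clearness-index relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SOLAR_CONSTANT = 1367.0  # W/m2


@dataclass
class SunPosition:
    """Sun direction: azimuth clockwise from north, zenith from vertical (deg)."""

    azimuth: np.ndarray | float
    zenith: np.ndarray | float

    @property
    def elevation(self):
        return 90.0 - np.asarray(self.zenith)


def _julian_day(times_utc: pd.DatetimeIndex) -> np.ndarray:
    # days since the Julian epoch; pandas epoch 1970-01-01 = JD 2440587.5
    return times_utc.asi8 / 86_400_000_000_000 + 2440587.5


def solar_position(times, latitude: float, longitude: float,
                   tz_offset_hours: float = 0.0) -> SunPosition:
    """NOAA-style solar azimuth and zenith.

    Parameters
    ----------
    times : DatetimeIndex or Timestamp
        Local standard time if ``tz_offset_hours`` is nonzero, else UTC.
    latitude, longitude : float
        Degrees; south/west negative.
    tz_offset_hours : float
        Offset of the supplied times from UTC (east positive).
    """
    scalar = not isinstance(times, pd.DatetimeIndex)
    idx = pd.DatetimeIndex([times]) if scalar else times
    utc = idx - pd.Timedelta(hours=tz_offset_hours)

    jd = _julian_day(utc)
    jc = (jd - 2451545.0) / 36525.0

    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = np.radians(m)
    c = (np.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + np.sin(2 * mr) * (0.019993 - 0.000101 * jc)
         + np.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(np.radians(app_long)))

    y = np.tan(eps / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r) - 2 * ecc * np.sin(mr)
        + 4 * ecc * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r) - 1.25 * ecc * ecc * np.sin(2 * mr))

    minutes = (utc.hour * 60 + utc.minute + utc.second / 60.0).to_numpy(dtype=float)
    tst = np.mod(minutes + eot + 4.0 * longitude, 1440.0)
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)
    har = np.radians(ha)

    latr = np.radians(latitude)
    cosz = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(har)
    cosz = np.clip(cosz, -1.0, 1.0)
    zen = np.degrees(np.arccos(cosz))

    sinz = np.sin(np.radians(zen))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = (np.sin(latr) * cosz - np.sin(decl)) / (np.cos(latr) * sinz)
    cos_az = np.clip(np.nan_to_num(cos_az, nan=1.0), -1.0, 1.0)
    az_base = np.degrees(np.arccos(cos_az))
    az = np.where(ha > 0.0, np.mod(az_base + 180.0, 360.0), np.mod(540.0 - az_base, 360.0))

    if scalar:
        return SunPosition(float(az[0]), float(zen[0]))
    return SunPosition(az, zen)


def air_mass(zenith) -> np.ndarray:
    """Kasten–Young relative optical air mass (infinite below horizon)."""
    z = np.asarray(zenith, dtype=float)
    cosz = np.cos(np.radians(z))
    am = np.where(
        z < 90.0,
        1.0 / (cosz + 0.50572 * np.power(96.07995 - np.minimum(z, 90.0), -1.6364)),
        np.inf,
    )
    return am


def clear_sky_shortwave(sun: SunPosition) -> np.ndarray | float:
    """Clear-sky global horizontal irradiance (W/m²), Meinel transmittance.

    GHI = S0 · 0.7^(AM^0.678) · cos(zenith); zero at or below the horizon.
    Monotone in solar elevation and bounded by the solar constant.
    """
    z = np.asarray(sun.zenith, dtype=float)
    cosz = np.cos(np.radians(z))
    am = air_mass(z)
    with np.errstate(over="ignore"):
        ghi = np.where(z < 90.0, SOLAR_CONSTANT * 0.7 ** (am ** 0.678) * cosz, 0.0)
    ghi = np.maximum(ghi, 0.0)
    return float(ghi) if ghi.ndim == 0 else ghi


def erbs_diffuse_fraction(kt) -> np.ndarray:
    """Erbs et al. (1982) diffuse fraction of global irradiance."""
    kt = np.asarray(kt, dtype=float)
    fd = np.where(
        kt <= 0.22,
        1.0 - 0.09 * kt,
        np.where(
            kt <= 0.80,
            0.9511 - 0.1604 * kt + 4.388 * kt ** 2 - 16.638 * kt ** 3 + 12.336 * kt ** 4,
            0.165,
        ),
    )
    return np.clip(fd, 0.0, 1.0)


def split_direct_diffuse(swdown, sun: SunPosition):
    """Split global horizontal shortwave into (direct-normal, diffuse-horizontal).

    Closure ``DNI·cos(zenith) + DHI = swdown`` holds exactly.  Sunlight
    reported while the sun is below the horizon is treated as all diffuse
    (with a warning): the synthetic cloud model can place small positive
    values at the day's edges.
    """
    sw = np.asarray(swdown, dtype=float)
    z = np.asarray(sun.zenith, dtype=float)
    if np.any(sw < 0):
        raise ValueError("swdown must be non-negative")
    cosz = np.cos(np.radians(z))
    up = (z < 90.0) & (cosz > 1e-6)
    if np.any(sw[~up] > 0) if sw.ndim else (not up and sw > 0):
        warnings.warn("positive shortwave with sun below horizon treated as diffuse")
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.where(up, sw / (SOLAR_CONSTANT * np.where(up, cosz, 1.0)), 0.0)
    fd = erbs_diffuse_fraction(np.clip(kt, 0.0, 1.0))
    dhi = np.where(up, fd * sw, sw)
    dni = np.where(up, (sw - dhi) / np.where(up, cosz, 1.0), 0.0)
    return dni, dhi
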