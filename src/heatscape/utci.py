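"""Universal Thermal Climate Index: operational polynomial and stress scale.

The UTCI equates the actual environment (air temperature, mean radiant
temperature, 10 m wind, humidity) to the air temperature of a reference
state — T_mrt = T_air, 50 % relative humidity, 0.5 m/s wind — producing
the same physiological strain for a standard person walking at 4 km/h
(135 W metabolic rate).  The operational approximation is the published
sixth-order polynomial in (T_air, va, T_mrt − T_air, vapour pressure)
fitted to the UTCI-Fiala multi-node model; its coefficients are the
standard published constants and are reproduced verbatim below.

Evaluation here uses a per-timestep algebraic reduction: for fixed
T_air, wind and humidity the polynomial collapses to degree six in
T_mrt − T_air, which makes metre-scale grids (thousands of cells per
hour, air temperature uniform across the site) cheap.  The direct
term-by-term sum is retained for scalar/vector use and as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .timeseries import InputError

# exponent tuples (ta, va, dtmrt, pa) in the canonical published order:
# pa power outermost, then dtmrt, then va, then ta, total degree <= 6
UTCI_EXPONENTS = np.array(
    [(i, j, k, l)
     for l in range(7)
     for k in range(7 - l)
     for j in range(7 - l - k)
     for i in range(7 - l - k - j)],
    dtype=np.int64,
)

# the 210 published coefficients, same order as UTCI_EXPONENTS
UTCI_COEFFS = np.array([
    6.07562052e-01, -2.27712343e-02, 8.06470249e-04, -1.54271372e-04,
    -3.24651735e-06, 7.32602852e-08, 1.35959073e-09, -2.25836520e+00,
    8.80326035e-02, 2.16844454e-03, -1.53347087e-05, -5.72983704e-07,
    -2.55090145e-09, -7.51269505e-01, -4.08350271e-03, -5.21670675e-05,
    1.94544667e-06, 1.14099531e-08, 1.58137256e-01, -6.57263143e-05,
    2.22697524e-07, -4.16117031e-08, -1.27762753e-02, 9.66891875e-06,
    2.52785852e-09, 4.56306672e-04, -1.74202546e-07, -5.91491269e-06,
    3.98374029e-01, 1.83945314e-04, -1.73754510e-04, -7.60781159e-07,
    3.77830287e-08, 5.43079673e-10, -2.00518269e-02, 8.92859837e-04,
    3.45433048e-06, -3.77925774e-07, -1.69699377e-09, 1.69992415e-04,
    -4.99204314e-05, 2.47417178e-07, 1.07596466e-08, 8.49242932e-05,
    1.35191328e-06, -6.21531254e-09, -4.99410301e-06, -1.89489258e-08,
    8.15300114e-08, 7.55043090e-04, -5.65095215e-05, -4.52166564e-07,
    2.46688878e-08, 2.42674348e-10, 1.54547250e-04, 5.24110970e-06,
    -8.75874982e-08, -1.50743064e-09, -1.56236307e-05, -1.33895614e-07,
    2.49709824e-09, 6.51711721e-07, 1.94960053e-09, -1.00361113e-08,
    -1.21206673e-05, -2.18203660e-07, 7.51269482e-09, 9.79063848e-11,
    1.25006734e-06, -1.81584736e-09, -3.52197671e-10, -3.36514630e-08,
    1.35908359e-10, 4.17032620e-10, -1.30369025e-09, 4.13908461e-10,
    9.22652254e-12, -5.08220384e-09, -2.24730961e-11, 1.17139133e-10,
    6.62154879e-10, 4.03863260e-13, 1.95087203e-12, -4.73602469e-12,
    5.12733497e+00, -3.12788561e-01, -1.96701861e-02, 9.99690870e-04,
    9.51738512e-06, -4.66426341e-07, 5.48050612e-01, -3.30552823e-03,
    -1.64119440e-03, -5.16670694e-06, 9.52692432e-07, -4.29223622e-02,
    5.00845667e-03, 1.00601257e-06, -1.81748644e-06, -1.25813502e-03,
    -1.79330391e-04, 2.34994441e-06, 1.29735808e-04, 1.29064870e-06,
    -2.28558686e-06, -3.69476348e-02, 1.62325322e-03, -3.14279680e-05,
    2.59835559e-06, -4.77136523e-08, 8.64203390e-03, -6.87405181e-04,
    -9.13863872e-06, 5.15916806e-07, -3.59217476e-05, 3.28696511e-05,
    -7.10542454e-07, -1.24382300e-05, -7.38584400e-09, 2.20609296e-07,
    -7.32469180e-04, -1.87381964e-05, 4.80925239e-06, -8.75492040e-08,
    2.77862930e-05, -5.06004592e-06, 1.14325367e-07, 2.53016723e-06,
    -1.72857035e-08, -3.95079398e-08, -3.59413173e-07, 7.04388046e-07,
    -1.89309167e-08, -4.79768731e-07, 7.96079978e-09, 1.62897058e-09,
    3.94367674e-08, -1.18566247e-09, 3.34678041e-10, -1.15606447e-10,
    -2.80626406e+00, 5.48712484e-01, -3.99428410e-03, -9.54009191e-04,
    1.93090978e-05, -3.08806365e-01, 1.16952364e-02, 4.95271903e-04,
    -1.90710882e-05, 2.10787756e-03, -6.98445738e-04, 2.30109073e-05,
    4.17856590e-04, -1.27043871e-05, -3.04620472e-06, 5.14507424e-02,
    -4.32510997e-03, 8.99281156e-05, -7.14663943e-07, -2.66016305e-04,
    2.63789586e-04, -7.01199003e-06, -1.06823306e-04, 3.61341136e-06,
    2.29748967e-07, 3.04788893e-04, -6.42070836e-05, 1.16257971e-06,
    7.68023384e-06, -5.47446896e-07, -3.59937910e-08, -4.36497725e-06,
    1.68737969e-07, 2.67489271e-08, 3.23926897e-09, -3.53874123e-02,
    -2.21201190e-01, 1.55126038e-02, -2.63917279e-04, 4.53433455e-02,
    -4.32943862e-03, 1.45389826e-04, 2.17508610e-04, -6.66724702e-05,
    3.33217140e-05, -2.26921615e-03, 3.80261982e-04, -5.45314314e-09,
    -7.96355448e-04, 2.53458034e-05, -6.31223658e-06, 3.02122035e-04,
    -4.77403547e-06, 1.73825715e-06, -4.09087898e-07, 6.14155345e-01,
    -6.16755931e-02, 1.33374846e-03, 3.55375387e-03, -5.13027851e-04,
    1.02449757e-04, -1.48526421e-03, -4.11469183e-05, -6.80434415e-06,
    -9.77675906e-06, 8.82773108e-02, -3.01859306e-03, 1.04452989e-03,
    2.47090539e-04, 1.48348065e-03,
])

assert UTCI_COEFFS.shape[0] == UTCI_EXPONENTS.shape[0] == 210

# saturation vapour pressure over water (Hardy / ITS-90 formulation)
_SAT_G = (-2.8365744e3, -6.028076559e3, 1.954263612e1, -2.737830188e-2,
          1.6261698e-5, 7.0229056e-10, -1.8680009e-13)


def saturation_vapour_pressure(tair):
    """Saturation vapour pressure over water in hPa (Hardy/Wexler form)."""
    tk = np.asarray(tair, dtype=float) + 273.15
    es = 2.7150305 * np.log(tk)
    for i, g in enumerate(_SAT_G):
        es = es + g * tk ** (i - 2)
    return np.exp(es) * 0.01  # Pa -> hPa


def vapour_pressure(tair, rh):
    """Ambient vapour pressure in hPa from temperature (°C) and RH (%)."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise InputError("rh must lie in [0, 100]")
    return saturation_vapour_pressure(tair) * rh / 100.0


# validity window of the operational polynomial
TAIR_RANGE = (-50.0, 50.0)
DTMRT_RANGE = (-30.0, 70.0)
WIND_RANGE = (0.5, 17.0)
PA_MAX_KPA = 5.0  # vapour pressure cap (50 hPa) of the polynomial's fit domain


def _clamp(x, lo, hi):
    return np.clip(x, lo, hi)


def utci_polynomial(ta, va, dtmrt, pa_kpa):
    """Direct evaluation of the published offset polynomial (no clamping)."""
    ta = np.asarray(ta, dtype=float)
    va = np.asarray(va, dtype=float)
    d = np.asarray(dtmrt, dtype=float)
    pa = np.asarray(pa_kpa, dtype=float)
    # precomputed power tables keep this a 210-term fused sum
    pt = [np.ones_like(ta)] + [None] * 6
    pv = [np.ones_like(va)] + [None] * 6
    pd = [np.ones_like(d)] + [None] * 6
    pp = [np.ones_like(pa)] + [None] * 6
    for n in range(1, 7):
        pt[n] = pt[n - 1] * ta
        pv[n] = pv[n - 1] * va
        pd[n] = pd[n - 1] * d
        pp[n] = pp[n - 1] * pa
    off = np.zeros(np.broadcast(ta, va, d, pa).shape)
    for (i, j, k, l), c in zip(UTCI_EXPONENTS, UTCI_COEFFS):
        off += c * pt[i] * pv[j] * pd[k] * pp[l]
    return ta + off


def utci(tair, tmrt, wind10, rh, clamp: bool = True, return_flags: bool = False):
    """UTCI (°C) from the four drivers.

    Inputs outside the polynomial's validity window (T_air in [-50, 50],
    T_mrt − T_air in [-30, 70], wind in [0.5, 17] m/s) are clamped to it;
    set ``return_flags=True`` to receive a boolean mask of clamped
    entries alongside the values.
    """
    tair = np.asarray(tair, dtype=float)
    tmrt = np.asarray(tmrt, dtype=float)
    wind10 = np.asarray(wind10, dtype=float)
    rh = np.asarray(rh, dtype=float)
    for name, arr in (("tair", tair), ("tmrt", tmrt), ("wind10", wind10), ("rh", rh)):
        if not np.all(np.isfinite(arr)):
            raise InputError(f"non-finite {name} passed to utci")
    d = tmrt - tair
    flags = ((tair < TAIR_RANGE[0]) | (tair > TAIR_RANGE[1])
             | (d < DTMRT_RANGE[0]) | (d > DTMRT_RANGE[1])
             | (wind10 < WIND_RANGE[0]) | (wind10 > WIND_RANGE[1]))
    if clamp:
        ta = _clamp(tair, *TAIR_RANGE)
        dd = _clamp(d, *DTMRT_RANGE)
        va = _clamp(wind10, *WIND_RANGE)
        pa = np.minimum(vapour_pressure(ta, rh) / 10.0, PA_MAX_KPA)
    else:
        ta, dd, va = tair, d, wind10
        pa = vapour_pressure(ta, rh) / 10.0  # kPa
    val = utci_polynomial(ta, va, dd, pa)
    if return_flags:
        return val, np.broadcast_to(flags, np.shape(val)).copy()
    return val


def utci_grid(tair: float, wind10: float, rh: float, tmrt_grid: np.ndarray):
    """UTCI over a T_mrt grid with site-uniform met (fast reduction).

    For fixed (T_air, wind, humidity) the polynomial is degree six in
    delta = T_mrt − T_air; its seven coefficients are assembled once and
    evaluated by Horner's rule over the grid.  Agrees with
    :func:`utci_polynomial` to rounding error.
    """
    ta = float(np.clip(tair, *TAIR_RANGE))
    va = float(np.clip(wind10, *WIND_RANGE))
    pa = min(float(vapour_pressure(ta, rh)) / 10.0, PA_MAX_KPA)
    tpow = ta ** np.arange(7)
    vpow = va ** np.arange(7)
    ppow = pa ** np.arange(7)
    cd = np.zeros(7)
    w = UTCI_COEFFS * tpow[UTCI_EXPONENTS[:, 0]] * vpow[UTCI_EXPONENTS[:, 1]] \
        * ppow[UTCI_EXPONENTS[:, 3]]
    np.add.at(cd, UTCI_EXPONENTS[:, 2], w)
    d = np.clip(np.asarray(tmrt_grid, dtype=float) - ta, *DTMRT_RANGE)
    out = np.full_like(d, cd[6])
    for k in range(5, -1, -1):
        out = out * d + cd[k]
    return ta + out


# ---------------------------------------------------------------------------
# stress categorisation
# ---------------------------------------------------------------------------

class StressCategory(IntEnum):
    """Ordered UTCI assessment-scale categories."""

    EXTREME_COLD = 0
    VERY_STRONG_COLD = 1
    STRONG_COLD = 2
    MODERATE_COLD = 3
    NO_STRESS = 4
    MODERATE_HEAT = 5
    STRONG_HEAT = 6
    VERY_STRONG_HEAT = 7
    EXTREME_HEAT = 8


@dataclass
class StressScale:
    """Threshold table for the assessment scale (strict inequalities).

    Heat categories require UTCI strictly above their threshold and cold
    categories strictly below, so boundary values fall in the milder
    class; the binary rollups are any-heat (UTCI > 26) and any-cold
    (UTCI < 0).
    """

    heat: tuple = (26.0, 32.0, 38.0, 46.0)
    cold: tuple = (0.0, -13.0, -27.0, -40.0)

    def classify(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise InputError("non-finite UTCI values")
        out = np.full(v.shape, int(StressCategory.NO_STRESS), dtype=np.int8)
        for level, thr in enumerate(self.heat):
            out[v > thr] = int(StressCategory.MODERATE_HEAT) + level
        for level, thr in enumerate(self.cold):
            out[v < thr] = int(StressCategory.MODERATE_COLD) - level
        return out

    def any_heat(self, values) -> np.ndarray:
        return np.asarray(values) > self.heat[0]

    def any_cold(self, values) -> np.ndarray:
        return np.asarray(values) < self.cold[0]


def classify_stress(values, scale: StressScale | None = None) -> np.ndarray:
    """Category codes (:class:`StressCategory`) for UTCI values."""
    return (scale or StressScale()).classify(values)
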