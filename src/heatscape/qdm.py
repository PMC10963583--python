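"""Grouped quantile delta mapping (QDM).

QDM corrects a projected model series against a reference while
preserving the model's own projected change at every quantile: for a
projected value x in time group g,

    tau   = F_proj,g(x)                      (empirical CDF of the group)
    mult: x_hat = Q_ref,g(tau) * x / Q_hist,g(tau)
    add:  x_hat = Q_ref,g(tau) + x - Q_hist,g(tau)

Empirical quantile functions use type-7 (linear) interpolation on
``n_quantiles`` evenly spaced tau levels; values beyond the training
range use constant extrapolation of the edge adjustment factor.
Multiplicative correction of air temperature is performed after shifting
to Kelvin, since ratios across 0 °C are ill-posed.

The historical period itself is corrected by plain quantile mapping
(Q_ref,g(F_hist,g(x))), the tau -> tau special case of the same scheme.

All group computations are vectorised across the full (hour × block)
grouping via per-group quantile matrices, so a 20-year hourly series
corrects in well under a second per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import InputError

KELVIN = 273.15


@dataclass
class CorrectionConfig:
    """Settings shared by QDM and MBCn."""

    n_quantiles: int = 100
    kind: str = "multiplicative"          # or "additive"
    trace_threshold: float = 1e-6         # denominators below this are "zero"
    mbcn_max_iter: int = 30
    mbcn_tol: float = 1e-4                # energy-distance improvement cutoff
    rotation_seed: int = 1234
    temperature_in_kelvin: bool = True    # shift tair before multiplicative QDM

    def __post_init__(self) -> None:
        if self.n_quantiles < 10:
            raise InputError("n_quantiles must be at least 10")
        if self.trace_threshold <= 0:
            raise InputError("trace threshold must be positive")
        if self.kind not in ("multiplicative", "additive"):
            raise InputError(f"unknown correction kind {self.kind!r}")


# ---------------------------------------------------------------------------
# grouped empirical quantiles
# ---------------------------------------------------------------------------

def group_quantile_matrix(values: np.ndarray, gid: np.ndarray, n_groups: int,
                          n_quantiles: int) -> np.ndarray:
    """(n_groups, n_quantiles) matrix of type-7 quantiles per group.

    Groups may have different sizes; empty groups raise, naming the group.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite values passed to quantile mapping")
    counts = np.bincount(gid, minlength=n_groups)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise InputError(f"empty time groups (dense ids {empty[:5].tolist()}...)")
    order = np.lexsort((values, gid))
    svals = values[order]
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

    taus = np.linspace(0.0, 1.0, n_quantiles)
    # type-7: position p = tau * (n - 1) within each group
    p = taus[None, :] * (counts[:, None] - 1)
    i = np.floor(p).astype(np.int64)
    i = np.minimum(i, np.maximum(counts[:, None] - 2, 0))
    w = p - i
    lo = svals[starts[:, None] + i]
    hi = svals[starts[:, None] + np.minimum(i + 1, counts[:, None] - 1)]
    return lo * (1.0 - w) + w * hi


class QuantileMap:
    """Per-group empirical quantile structure for the three series."""

    def __init__(self, ref, hist, proj, gid_ref, gid_hist, gid_proj,
                 n_groups: int, n_quantiles: int = 100):
        self.taus = np.linspace(0.0, 1.0, n_quantiles)
        self.n_groups = n_groups
        self.q_ref = group_quantile_matrix(ref, gid_ref, n_groups, n_quantiles)
        self.q_hist = group_quantile_matrix(hist, gid_hist, n_groups, n_quantiles)
        self.q_proj = group_quantile_matrix(proj, gid_proj, n_groups, n_quantiles)


def _tau_of(q: np.ndarray, g: np.ndarray, x: np.ndarray, taus: np.ndarray,
            block: int = 200_000) -> np.ndarray:
    """tau = F_g(x) by linear interpolation on the group's quantile grid.

    Ties resolve to the lower edge of the plateau; beyond-range values
    map to tau = 0 or 1 (constant extrapolation downstream).
    """
    nq = len(taus)
    out = np.empty_like(x, dtype=float)
    for s in range(0, len(x), block):  # blocked to bound the (n, nq) temporary
        sl = slice(s, s + block)
        rows = q[g[sl]]
        xi = x[sl][:, None]
        idx = np.sum(rows < xi, axis=1)
        inner = (idx > 0) & (idx < nq)
        j = np.clip(idx, 1, nq - 1)
        qlo = np.take_along_axis(rows, (j - 1)[:, None], 1)[:, 0]
        qhi = np.take_along_axis(rows, j[:, None], 1)[:, 0]
        span = qhi - qlo
        frac = np.where(span > 0, (x[sl] - qlo) / np.where(span > 0, span, 1.0), 0.0)
        tau = taus[j - 1] + frac * (taus[j] - taus[j - 1])
        tau = np.where(idx == 0, 0.0, np.where(idx == nq, 1.0, np.where(inner, tau, tau)))
        out[sl] = np.clip(tau, 0.0, 1.0)
    return out


def _quantile_at(q: np.ndarray, g: np.ndarray, tau: np.ndarray,
                 taus: np.ndarray) -> np.ndarray:
    """Inverse lookup: group quantile function evaluated at tau."""
    nq = len(taus)
    p = tau * (nq - 1)
    i = np.clip(np.floor(p).astype(np.int64), 0, nq - 2)
    w = p - i
    rows = q[g]
    lo = np.take_along_axis(rows, i[:, None], 1)[:, 0]
    hi = np.take_along_axis(rows, (i + 1)[:, None], 1)[:, 0]
    return lo * (1.0 - w) + w * hi


# ---------------------------------------------------------------------------
# adjustment-factor hygiene
# ---------------------------------------------------------------------------

def sanitize_factors(factors: np.ndarray, variable: str = "swdown"):
    """Zero out non-finite multiplicative adjustment factors.

    Downwelling shortwave mixes exact zeros (night, overcast) between
    series, which produces infinite (x/0) or undefined (0/0) adjustment
    factors; both are defined as 0.  Returns (cleaned factors,
    replacement count).  Total function: never raises.
    """
    f = np.asarray(factors, dtype=float)
    bad = ~np.isfinite(f)
    n_replaced = int(bad.sum())
    if n_replaced and variable != "swdown":
        # the zeroing rule is a shortwave phenomenon; elsewhere it means
        # the caller fed degenerate data, but we still return a total result
        pass
    out = np.where(bad, 0.0, f)
    return out, n_replaced


# ---------------------------------------------------------------------------
# the correction itself
# ---------------------------------------------------------------------------

def qdm_correct(ref, mod_hist, mod_proj, gid_ref, gid_hist, gid_proj,
                n_groups: int, config: CorrectionConfig | None = None,
                variable: str = "", kind: str | None = None):
    """Grouped QDM of ``mod_proj`` plus quantile mapping of ``mod_hist``.

    Returns ``(corrected_proj, corrected_hist, diagnostics)`` where
    diagnostics records the number of zeroed adjustment factors.
    """
    config = config or CorrectionConfig()
    kind = kind or config.kind
    ref = np.asarray(ref, dtype=float)
    mod_hist = np.asarray(mod_hist, dtype=float)
    mod_proj = np.asarray(mod_proj, dtype=float)
    for name, arr in (("ref", ref), ("mod_hist", mod_hist), ("mod_proj", mod_proj)):
        if not np.all(np.isfinite(arr)):
            raise InputError(f"non-finite values in {name}")

    shift = KELVIN if (kind == "multiplicative" and variable == "tair"
                       and config.temperature_in_kelvin) else 0.0
    if kind == "multiplicative" and np.any(ref + shift < 0):
        raise InputError("multiplicative correction requires non-negative data")

    qm = QuantileMap(ref + shift, mod_hist + shift, mod_proj + shift,
                     gid_ref, gid_hist, gid_proj, n_groups, config.n_quantiles)

    tau_p = _tau_of(qm.q_proj, gid_proj, mod_proj + shift, qm.taus)
    ref_q = _quantile_at(qm.q_ref, gid_proj, tau_p, qm.taus)
    hist_q = _quantile_at(qm.q_hist, gid_proj, tau_p, qm.taus)

    n_replaced = 0
    if kind == "multiplicative":
        small = np.abs(hist_q) < config.trace_threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(small, np.inf, (mod_proj + shift) / np.where(small, 1.0, hist_q))
            factor = np.where(small & (np.abs(mod_proj + shift) < config.trace_threshold),
                              np.nan, factor)
        if variable == "swdown":
            factor, n_replaced = sanitize_factors(factor, variable)
        elif not np.all(np.isfinite(factor)):
            raise InputError(
                f"non-finite adjustment factors for {variable or 'series'}; "
                "only shortwave factors may be zeroed")
        corrected_proj = ref_q * factor - shift
    else:
        corrected_proj = ref_q + (mod_proj + shift) - hist_q - shift

    # historical period: plain grouped quantile mapping onto the reference
    tau_h = _tau_of(qm.q_hist, gid_hist, mod_hist + shift, qm.taus)
    corrected_hist = _quantile_at(qm.q_ref, gid_hist, tau_h, qm.taus) - shift

    return corrected_proj, corrected_hist, {"factors_zeroed": n_replaced}
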