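"""N-dimensional multivariate bias correction (MBCn) of the four drivers.

MBCn aligns the joint distribution of model output with a reference by
iterating random orthogonal rotations with univariate quantile mapping:

1. draw a Haar-random rotation Q and rotate reference, model-historical
   and model-projected matrices into the new basis;
2. apply additive QDM to every rotated coordinate within its time group
   (rotated coordinates are signed, so the additive form is used);
3. rotate back; repeat until the energy distance between the corrected
   historical matrix and the reference stops improving.

The converged output only supplies *rank orderings*: within each
(hour, day-of-year) group, each variable's univariately QDM-corrected
values are reordered to the rank order of the converged iterate, so the
final marginals are exactly the univariate-QDM marginals while the rank
dependence between variables follows the reference.

Exposed statsmodels-style: build :class:`MBCn` (or the univariate-only
:class:`QuantileDeltaMapping`) from three :class:`~heatscape.timeseries.MetSeries`,
call ``fit()`` and read the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .qdm import CorrectionConfig, qdm_correct
from .timegroups import DAILY, WEEKLY, build_time_groups
from .timeseries import VARIABLES, InputError, MetSeries


def random_rotation(dim: int, seed) -> np.ndarray:
    """Haar-distributed random orthogonal matrix (QR with sign-fixed R)."""
    if dim < 2:
        raise InputError("rotation dimension must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(g)
    return q * np.sign(np.diag(r))


def energy_distance(x: np.ndarray, y: np.ndarray, max_points: int = 1024,
                    seed: int = 0) -> float:
    """Multivariate energy distance, subsampled for large inputs."""
    rng = np.random.default_rng(seed)
    if len(x) > max_points:
        x = x[rng.choice(len(x), max_points, replace=False)]
    if len(y) > max_points:
        y = y[rng.choice(len(y), max_points, replace=False)]
    dxy = cdist(x, y).mean()
    dxx = cdist(x, x).mean()
    dyy = cdist(y, y).mean()
    return float(2.0 * dxy - dxx - dyy)


def _rank_reorder(target: np.ndarray, donor: np.ndarray, gid: np.ndarray) -> np.ndarray:
    """Within each group, donor values rearranged to the ranks of target."""
    out = np.empty_like(donor)
    order_t = np.lexsort((target, gid))
    order_d = np.lexsort((donor, gid))
    out[order_t] = donor[order_d]
    return out


def mbcn_core(ref: np.ndarray, hist: np.ndarray, proj: np.ndarray,
              gid_ref: np.ndarray, gid_hist: np.ndarray, gid_proj: np.ndarray,
              n_groups: int, config: CorrectionConfig):
    """Iterated rotation + additive QDM; returns corrected (hist, proj, trace).

    Inputs are standardised internally by the reference mean/sd per
    column; only ranks of the output are consumed downstream, so the
    result is returned on the standardised scale.
    """
    mu, sd = ref.mean(axis=0), ref.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    r = (ref - mu) / sd
    h = (hist - mu) / sd
    p = (proj - mu) / sd

    rng = np.random.default_rng(config.rotation_seed)
    trace: list[float] = []
    best = (np.inf, h.copy(), p.copy())
    prev = np.inf
    converged = False
    for _ in range(config.mbcn_max_iter):
        q = random_rotation(r.shape[1], rng)
        rr, hr, pr = r @ q, h @ q, p @ q
        for j in range(r.shape[1]):
            pr[:, j], hr[:, j], _ = qdm_correct(
                rr[:, j], hr[:, j], pr[:, j], gid_ref, gid_hist, gid_proj,
                n_groups, config, kind="additive")
        h, p = hr @ q.T, pr @ q.T
        e = energy_distance(h, r, seed=config.rotation_seed)
        trace.append(e)
        if e < best[0]:
            best = (e, h.copy(), p.copy())
        if prev - e < config.mbcn_tol and prev != np.inf:
            converged = True
            break
        prev = e
    if not converged:
        warnings.warn(
            f"MBCn did not converge in {config.mbcn_max_iter} iterations "
            f"(energy-distance trace tail {trace[-3:]}); best iterate used")
    return best[1], best[2], trace, converged


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class BiasCorrectionResults:
    """Corrected series plus diagnostics from a QDM or MBCn fit."""

    corrected_hist: MetSeries
    corrected_proj: MetSeries
    factors_zeroed: dict
    energy_trace: list = field(default_factory=list)
    converged: bool = True
    clamped: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = []
        for v in VARIABLES:
            rows.append({
                "variable": v,
                "hist_mean": self.corrected_hist.data[v].mean(),
                "proj_mean": self.corrected_proj.data[v].mean(),
                "net_change": (self.corrected_proj.data[v].mean()
                               - self.corrected_hist.data[v].mean()),
                "factors_zeroed": self.factors_zeroed.get(v, 0),
            })
        table = pd.DataFrame(rows).to_string(index=False, float_format="%.3f")
        lines = [self.__class__.__name__, "=" * 40, table]
        if self.energy_trace:
            lines.append(f"MBCn iterations: {len(self.energy_trace)} "
                         f"(converged={self.converged}, "
                         f"final energy distance {self.energy_trace[-1]:.5f})")
        return "\n".join(lines)


class QuantileDeltaMapping:
    """Univariate grouped QDM of all four drivers (hour × week groups).

    Parameters
    ----------
    ref, mod_hist, mod_proj : MetSeries
        Reference, model-historical and model-projected hourly series.
    config : CorrectionConfig, optional
        Multiplicative by default; air temperature is shifted to Kelvin.
    """

    grouping = WEEKLY

    def __init__(self, ref: MetSeries, mod_hist: MetSeries, mod_proj: MetSeries,
                 config: CorrectionConfig | None = None):
        self.ref, self.hist, self.proj = ref, mod_hist, mod_proj
        self.config = config or CorrectionConfig()
        self.g_ref = build_time_groups(ref.index, self.grouping)
        self.g_hist = build_time_groups(mod_hist.index, self.grouping)
        self.g_proj = build_time_groups(mod_proj.index, self.grouping)

    def fit(self) -> BiasCorrectionResults:
        n_groups = self.g_ref.n_groups
        mh, mp = self.hist.matrix(), self.proj.matrix()
        out_h, out_p = np.empty_like(mh), np.empty_like(mp)
        zeroed = {}
        for j, v in enumerate(VARIABLES):
            out_p[:, j], out_h[:, j], diag = qdm_correct(
                self.ref.data[v].to_numpy(), mh[:, j], mp[:, j],
                self.g_ref.gid, self.g_hist.gid, self.g_proj.gid,
                n_groups, self.config, variable=v)
            zeroed[v] = diag["factors_zeroed"]
        ch, clamps_h = _clamp_physical(out_h)
        cp, clamps_p = _clamp_physical(out_p)
        return BiasCorrectionResults(
            corrected_hist=self.hist.with_matrix(ch),
            corrected_proj=self.proj.with_matrix(cp),
            factors_zeroed=zeroed,
            clamped={"hist": clamps_h, "proj": clamps_p},
        )


def _clamp_physical(m: np.ndarray):
    """Clip rh to [0, 100] and wind/shortwave to >= 0; count the clamps."""
    clamps = {}
    out = m.copy()
    bad_rh = (m[:, 1] < 0) | (m[:, 1] > 100)
    out[:, 1] = np.clip(m[:, 1], 0.0, 100.0)
    clamps["rh"] = int(bad_rh.sum())
    for j, name in ((2, "wind10"), (3, "swdown")):
        bad = m[:, j] < 0
        out[:, j] = np.maximum(m[:, j], 0.0)
        clamps[name] = int(bad.sum())
    return out, clamps


class MBCn(QuantileDeltaMapping):
    """Diurnal MBCn: weekly univariate QDM marginals, then the iterative
    rotation scheme on (hour × day-of-year) groups, finished by rank
    reordering so every marginal equals its univariate-QDM marginal."""

    def fit(self) -> BiasCorrectionResults:
        marginals = super().fit()   # weekly univariate QDM
        gd_ref = build_time_groups(self.ref.index, DAILY)
        gd_hist = build_time_groups(self.hist.index, DAILY)
        gd_proj = build_time_groups(self.proj.index, DAILY)

        h_core, p_core, trace, converged = mbcn_core(
            self.ref.matrix(), self.hist.matrix(), self.proj.matrix(),
            gd_ref.gid, gd_hist.gid, gd_proj.gid, gd_ref.n_groups, self.config)

        qh = marginals.corrected_hist.matrix()
        qp = marginals.corrected_proj.matrix()
        out_h, out_p = np.empty_like(qh), np.empty_like(qp)
        for j in range(qh.shape[1]):
            out_h[:, j] = _rank_reorder(h_core[:, j], qh[:, j], gd_hist.gid)
            out_p[:, j] = _rank_reorder(p_core[:, j], qp[:, j], gd_proj.gid)

        return BiasCorrectionResults(
            corrected_hist=self.hist.with_matrix(out_h),
            corrected_proj=self.proj.with_matrix(out_p),
            factors_zeroed=marginals.factors_zeroed,
            energy_trace=trace,
            converged=converged,
            clamped=marginals.clamped,
        )


def mbcn_correct(ref: MetSeries, mod_hist: MetSeries, mod_proj: MetSeries,
                 config: CorrectionConfig | None = None) -> BiasCorrectionResults:
    """Functional wrapper around :class:`MBCn`."""
    return MBCn(ref, mod_hist, mod_proj, config).fit()
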