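"""End-to-end orchestration: simulate → correct → radiate → UTCI → summarize.

A :class:`RunConfig` (YAML-loadable) fixes every input, parameter and
seed; :func:`run_pipeline` executes the stages in order, persists the
intermediates under the output directory, and emits a :class:`RunManifest`
with a config hash and per-artifact checksums so that a rerun with the
same config and seeds is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climatology import (cumulative_stress_june_may, site_extremes,
                          stress_flags, stress_hours, summary_table)
from .mbcn import MBCn
from .qdm import CorrectionConfig
from .radiation import RadiationConfig, run_tiled
from .rasters import write_site_rasters
from .synthetic import (SynthConfig, default_demo_site, gen_model_pair,
                        gen_reference_series, gen_site_rasters)
from .timeseries import MetSeries
from .utci import StressScale, utci_grid


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    n_members: int = 1
    ref_years: tuple[int, int] = (1995, 1996)
    hist_years: tuple[int, int] = (1995, 1996)
    future_years: tuple[int, int] = (2045, 2046)
    site_extent: float = 60.0
    cell_size: float = 1.0
    tile: float = 30.0
    buffer: float = 20.0
    n_quantiles: int = 100
    mbcn_max_iter: int = 20
    heat_thresholds: tuple = (26.0, 32.0, 38.0, 46.0)
    cold_thresholds: tuple = (0.0, -13.0, -27.0, -40.0)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        spans = [tuple(self.ref_years), tuple(self.hist_years), tuple(self.future_years)]
        if tuple(self.hist_years)[1] >= tuple(self.future_years)[0]:
            raise PipelineError("config: historic and future periods overlap")
        for lo, hi in spans:
            if hi < lo:
                raise PipelineError("config: period end before start")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = yaml.safe_load(self.to_yaml())
        d.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _member_seed(base: int, member: int) -> int:
    ss = np.random.SeedSequence([base, member])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def utci_extremes_for(tmrt, met: MetSeries) -> pd.DataFrame:
    """Site-wide UTCI extremes per timestamp from a T_mrt stack."""
    d = met.data
    n = len(met)
    out = np.empty((n, 3))
    tvals = tmrt.values
    for i in range(n):
        grid = utci_grid(float(d["tair"].iloc[i]), float(d["wind10"].iloc[i]),
                         float(d["rh"].iloc[i]), tvals[i])
        out[i] = grid.max(), grid.min(), grid.mean()
    return pd.DataFrame(out, columns=["utci_max", "utci_min", "utci_mean"],
                        index=met.index)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full chain on synthetic inputs; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.hash(), __version__, config.seed)
    caught: list[str] = []

    def _persist(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest.checksums[name] = _checksum(path)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # -- simulate ---------------------------------------------------
        try:
            synth = SynthConfig(start_year=config.ref_years[0],
                                end_year=config.ref_years[1], seed=config.seed)
            ref = gen_reference_series(synth)
            site = default_demo_site(config.site_extent)
            rasters = gen_site_rasters(site, config.cell_size)
            _persist("reference.nc", ref.to_netcdf)
            write_site_rasters(rasters, out / "rasters")
            for layer in ("dem", "dsm", "chm", "trunk"):
                p = out / "rasters" / f"{layer}.tif"
                manifest.checksums[f"rasters/{layer}.tif"] = _checksum(p)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"simulate stage failed: {e}") from e

        # -- correct / radiate / utci per member ------------------------
        scale = StressScale(config.heat_thresholds, config.cold_thresholds)
        rad = RadiationConfig(latitude=synth.latitude, longitude=synth.longitude,
                              max_radius=config.buffer)
        cc = CorrectionConfig(n_quantiles=config.n_quantiles,
                              mbcn_max_iter=config.mbcn_max_iter)
        hist_mets, fut_mets, hist_ext, fut_ext = [], [], [], []
        for m in range(config.n_members):
            seed = _member_seed(config.seed, m)
            try:
                hist, fut = gen_model_pair(synth, seed,
                                           hist_years=tuple(config.hist_years),
                                           future_years=tuple(config.future_years))
                res = MBCn(ref, hist, fut, cc).fit()
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"correct stage failed (member {m}): {e}") from e
            ch, cp = res.corrected_hist, res.corrected_proj
            _persist(f"member{m}_hist_corrected.nc", ch.to_netcdf)
            _persist(f"member{m}_future_corrected.nc", cp.to_netcdf)
            try:
                tmrt_h = run_tiled(rasters, ch, config.tile, config.buffer, rad)
                tmrt_f = run_tiled(rasters, cp, config.tile, config.buffer, rad)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"radiate stage failed (member {m}): {e}") from e
            try:
                eh = utci_extremes_for(tmrt_h, ch)
                ef = utci_extremes_for(tmrt_f, cp)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"utci stage failed (member {m}): {e}") from e
            _persist(f"member{m}_hist_extremes.csv",
                     lambda p, df=eh: df.to_csv(p, float_format="%.4f"))
            _persist(f"member{m}_future_extremes.csv",
                     lambda p, df=ef: df.to_csv(p, float_format="%.4f"))
            hist_mets.append(ch)
            fut_mets.append(cp)
            hist_ext.append(eh)
            fut_ext.append(ef)

        # -- summarize --------------------------------------------------
        try:
            pooled_h = MetSeries(pd.concat([m.data for m in hist_mets]),
                                 ref.tz_offset_hours)
            pooled_f = MetSeries(pd.concat([m.data for m in fut_mets]),
                                 ref.tz_offset_hours)
            eh_all = pd.concat(hist_ext)
            ef_all = pd.concat(fut_ext)
            table = summary_table(pooled_h, pooled_f, eh_all, ef_all, scale)
            _persist("summary_variables.csv",
                     lambda p: table.rounded().variables.to_csv(p))
            _persist("summary_stress.csv",
                     lambda p: table.rounded().stress.to_csv(p))
            hours = {}
            for period, exts in (("hist", hist_ext), ("future", fut_ext)):
                per_member = [stress_hours(stress_flags(e, scale)["any_heat"])
                              for e in exts]
                hours[period] = float(np.mean([t.annual_total for t in per_member]))
            _persist("stress_hours.json",
                     lambda p: p.write_text(json.dumps(hours, indent=2)))
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"summarize stage failed: {e}") from e

        caught = sorted({str(w.message) for w in wlist})

    manifest.warnings = caught
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
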