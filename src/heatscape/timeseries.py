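"""Aligned hourly series of the four UTCI driver variables.

A :class:`MetSeries` carries air temperature (°C), relative humidity (%),
10 m wind speed (m/s) and downwelling shortwave radiation (W/m²) on a
strictly hourly, timezone-fixed (local standard time) axis.  It is a thin
wrapper around a :class:`pandas.DataFrame`; NetCDF and CSV round-trips go
through xarray / pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

#: canonical column order, recorded so multivariate matrices are unambiguous
VARIABLES = ("tair", "rh", "wind10", "swdown")

#: units for NetCDF metadata
UNITS = {"tair": "degC", "rh": "percent", "wind10": "m s-1", "swdown": "W m-2"}


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


@dataclass
class MetSeries:
    """Hourly four-variable meteorological series in local standard time.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``tair``, ``rh``, ``wind10``, ``swdown`` on a tz-naive
        hourly ``DatetimeIndex`` interpreted as local standard time.
    tz_offset_hours : float
        Fixed offset of local standard time from UTC (east positive);
        used for solar geometry.
    """

    data: pd.DataFrame
    tz_offset_hours: float = 10.0

    def __post_init__(self) -> None:
        missing = [v for v in VARIABLES if v not in self.data.columns]
        if missing:
            raise InputError(f"MetSeries missing columns: {missing}")
        self.data = self.data.loc[:, list(VARIABLES)]

    # -- validation ------------------------------------------------------

    def validate(self) -> "MetSeries":
        """Check physical bounds and the hourly time axis; return self."""
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise InputError("MetSeries index must be a DatetimeIndex")
        dt = np.diff(idx.asi8)
        if len(dt) and not np.all(dt == 3_600_000_000_000):
            raise InputError("timestamps must be strictly increasing at 1 h steps")
        d = self.data
        if not np.isfinite(d.to_numpy()).all():
            raise InputError("non-finite values in MetSeries")
        if (d["rh"].lt(0) | d["rh"].gt(100)).any():
            raise InputError("rh outside [0, 100]")
        if d["wind10"].lt(0).any():
            raise InputError("wind10 < 0")
        if d["swdown"].lt(0).any():
            raise InputError("swdown < 0")
        return self

    # -- convenience -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def matrix(self) -> np.ndarray:
        """(n, 4) float array in canonical column order."""
        return self.data.to_numpy(dtype=float)

    def with_matrix(self, values: np.ndarray) -> "MetSeries":
        """New MetSeries with the same index and replaced values."""
        if values.shape != (len(self), len(VARIABLES)):
            raise InputError(f"expected shape {(len(self), len(VARIABLES))}")
        df = pd.DataFrame(values, index=self.index, columns=list(VARIABLES))
        return MetSeries(df, self.tz_offset_hours)

    # -- I/O -------------------------------------------------------------

    def to_xarray(self) -> xr.Dataset:
        ds = xr.Dataset(
            {v: ("time", self.data[v].to_numpy()) for v in VARIABLES},
            coords={"time": self.data.index},
            attrs={"tz_offset_hours": self.tz_offset_hours},
        )
        for v in VARIABLES:
            ds[v].attrs["units"] = UNITS[v]
        return ds

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "MetSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            df = ds[list(VARIABLES)].to_dataframe()
            tz = float(ds.attrs.get("tz_offset_hours", 10.0))
        df.index.name = "time"
        return cls(df, tz)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="time")

    @classmethod
    def from_csv(cls, path, tz_offset_hours: float = 10.0) -> "MetSeries":
        df = pd.read_csv(path, index_col="time", parse_dates=True)
        return cls(df, tz_offset_hours)
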