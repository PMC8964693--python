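"""Sea-surface-temperature series containers and I/O.

An :class:`SSTSeries` holds one reef's (or one pixel's) temperature record at
daily or weekly cadence. Daily records may carry per-day minima and maxima in
addition to the daily mean; weekly records carry weekly means only. Remote
sensing products at both cadences (global weekly products and regional daily
hydrodynamic reanalyses) map onto the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "SSTSeries",
    "to_weekly",
    "read_sst_csv",
    "write_sst_csv",
    "read_sst_netcdf",
    "write_sst_netcdf",
]


@dataclass
class SSTSeries:
    """Temperature time series for one reef.

    Parameters
    ----------
    reef_id : str
        Reef (or pixel) label.
    data : pandas.DataFrame
        Indexed by ``DatetimeIndex``; columns ``sst_mean`` and, for daily
        series with sub-daily information, ``sst_min`` / ``sst_max`` (°C).
    cadence : {"daily", "weekly"}
    attrs : dict
        Free-form metadata (e.g. planted anomaly schedule for synthetic
        series, latitude/longitude).
    """

    reef_id: str
    data: pd.DataFrame
    cadence: str = "daily"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cadence not in ("daily", "weekly"):
            raise ValueError(f"cadence must be 'daily' or 'weekly', got {self.cadence!r}")
        if "sst_mean" not in self.data.columns:
            raise ValueError("data must contain an 'sst_mean' column")
        idx = pd.DatetimeIndex(self.data.index)
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        self.data = self.data.copy()
        self.data.index = idx
        if {"sst_min", "sst_max"} <= set(self.data.columns):
            lo = self.data["sst_min"].to_numpy(float)
            hi = self.data["sst_max"].to_numpy(float)
            mid = self.data["sst_mean"].to_numpy(float)
            ok = np.isnan(lo) | np.isnan(hi) | ((lo <= mid + 1e-9) & (mid <= hi + 1e-9))
            if not ok.all():
                raise ValueError("sst_min <= sst_mean <= sst_max violated")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def has_minmax(self) -> bool:
        return {"sst_min", "sst_max"} <= set(self.data.columns)

    def window(self, start, end) -> pd.DataFrame:
        """Rows within the half-open interval [start, end)."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        return self.data[(self.data.index >= start) & (self.data.index < end)]


def to_weekly(series: SSTSeries) -> SSTSeries:
    """Aggregate a daily series to ISO-week means.

    Weeks with fewer than seven daily observations (partial leading or
    trailing weeks) are dropped so that every retained weekly mean is built
    from a full week. The emitted date for each week is its Monday.
    """
    if series.cadence == "weekly":
        return series
    iso = series.dates.isocalendar()
    key = list(zip(iso["year"].to_numpy(), iso["week"].to_numpy()))
    df = series.data.assign(_k=key)
    grouped = df.groupby("_k", sort=False)
    full = grouped.size() == 7
    means = grouped["sst_mean"].mean()[full]
    mondays = [pd.Timestamp.fromisocalendar(y, w, 1) for (y, w) in means.index]
    out = pd.DataFrame({"sst_mean": means.to_numpy()}, index=pd.DatetimeIndex(mondays))
    out = out.sort_index()
    return SSTSeries(series.reef_id, out, cadence="weekly", attrs=dict(series.attrs))


# ---------------------------------------------------------------------------
# I/O — long CSV (reef_id, date, sst_mean[, sst_min, sst_max]) and CF netCDF.


def write_sst_csv(series_list: list[SSTSeries], path) -> None:
    frames = []
    for s in series_list:
        df = s.data.reset_index(names="date")
        df.insert(0, "reef_id", s.reef_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sst_csv(path, cadence: str = "daily") -> list[SSTSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for reef_id, sub in df.groupby("reef_id", sort=False):
        sub = sub.drop(columns="reef_id").set_index("date").sort_index()
        out.append(SSTSeries(str(reef_id), sub, cadence=cadence))
    return out


def write_sst_netcdf(series_list: list[SSTSeries], path) -> None:
    """Write series as CF-style netCDF (dimensions time × reef).

    Uses the netCDF3-classic writer, readable by any netCDF stack. All series
    must share a common time axis.
    """
    times = series_list[0].dates
    for s in series_list[1:]:
        if not s.dates.equals(times):
            raise ValueError("all series must share the same time axis for netCDF export")
    reefs = [s.reef_id for s in series_list]
    data_vars = {}
    for col in ("sst_mean", "sst_min", "sst_max"):
        if all(col in s.data.columns for s in series_list):
            arr = np.column_stack([s.data[col].to_numpy(float) for s in series_list])
            data_vars[col] = xr.DataArray(
                arr,
                dims=("time", "reef"),
                attrs={"units": "degC", "standard_name": "sea_surface_temperature"},
            )
    ds = xr.Dataset(data_vars, coords={"time": times, "reef": reefs})
    ds.to_netcdf(path, engine="scipy")


def read_sst_netcdf(path, cadence: str = "daily") -> list[SSTSeries]:
    ds = xr.open_dataset(path, engine="scipy")
    out = []
    for reef in ds["reef"].values:
        cols = {}
        for col in ("sst_mean", "sst_min", "sst_max"):
            if col in ds:
                cols[col] = ds[col].sel(reef=reef).to_numpy()
        df = pd.DataFrame(cols, index=pd.DatetimeIndex(ds["time"].values))
        out.append(SSTSeries(str(reef), df, cadence=cadence))
    ds.close()
    return out
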