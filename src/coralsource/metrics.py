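"""Environmental predictor metrics derived from reef SST series.

Seven reef-habitat predictors are computed per reef: latitude (LAT, °S),
average SST over a pre-bleaching window (SST_av.pre) and over a longer window
including bleaching years (SST_av.post), the standard deviation of daily mean
SST (SST_stdev), the mean daily temperature range (DTR), the year-to-year
dispersion of SST-anomaly frequency (SSTA_Freq_stdev), and the dispersion of
thermal-stress-anomaly degree heating weeks (TSA_DHW_stdev).

Anomaly conventions follow the NOAA Coral Reef Watch family of definitions:
the climatological baseline is the maximum monthly mean (MMM) for HotSpots,
degree heating weeks (DHW) accumulate HotSpots of at least 1 °C over a
trailing 12-week window, and SST anomalies are counted against the
calendar-week climatology with a 1 °C threshold. Every threshold and window
length is a config key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import SSTSeries, to_weekly

__all__ = [
    "FEATURES",
    "MetricConfig",
    "Climatology",
    "ReefEnvProfile",
    "average_sst",
    "sst_stdev",
    "daily_temperature_range",
    "build_climatology",
    "dhw",
    "tsa_dhw_series",
    "tsa_dhw_stdev",
    "ssta_frequencies",
    "ssta_freq_stdev",
    "experiment_dhw",
    "profile_reef",
    "write_profiles",
    "read_profiles",
    "feature_frame",
]

#: Canonical predictor names, used as model feature keys throughout.
FEATURES = (
    "LAT",
    "SST_av.pre",
    "SST_av.post",
    "SST_stdev",
    "DTR",
    "SSTA_Freq_stdev",
    "TSA_DHW_stdev",
)

#: Fixed column order for the profile table on disk.
PROFILE_COLUMNS = (
    "reef_id",
    "lat",
    "lon",
    "SST_av.pre",
    "SST_av.post",
    "SST_stdev",
    "DTR",
    "SSTA_Freq_stdev",
    "TSA_DHW_stdev",
)


@dataclass
class MetricConfig:
    """Windows and thresholds for the seven predictors.

    Date intervals are half-open ``[start, end)``; "2014 to 2016" therefore
    spans 2014-01-01 up to (not including) 2017-01-01.
    """

    window_pre: tuple = ("2014-01-01", "2017-01-01")
    window_post: tuple = ("2013-01-01", "2019-01-01")
    baseline_years: tuple = (2013, 2019)
    hotspot_threshold: float = 1.0  # °C, HotSpot counted toward DHW
    ssta_threshold: float = 1.0  # °C, anomalous week
    tsa_threshold: float = 1.0  # °C, TSA counted toward TSA_DHW
    dhw_weeks: int = 12


@dataclass
class Climatology:
    """Monthly and calendar-week mean SST over a baseline, plus the MMM."""

    monthly_means: pd.Series
    weekly_means: pd.Series
    baseline_years: tuple

    @property
    def mmm(self) -> float:
        """Maximum monthly mean (°C) — the DHW HotSpot baseline."""
        return float(self.monthly_means.max())

    @property
    def max_weekly_mean(self) -> float:
        return float(self.weekly_means.max())


@dataclass
class ReefEnvProfile:
    """The seven predictors plus location for one reef."""

    reef_id: str
    lat: float  # degrees south, positive southward
    lon: float = np.nan
    sst_av_pre: float = np.nan
    sst_av_post: float = np.nan
    sst_stdev: float = np.nan
    dtr: float = np.nan
    ssta_freq_stdev: float = np.nan
    tsa_dhw_stdev: float = np.nan

    def as_row(self) -> dict:
        return {
            "reef_id": self.reef_id,
            "lat": self.lat,
            "lon": self.lon,
            "SST_av.pre": self.sst_av_pre,
            "SST_av.post": self.sst_av_post,
            "SST_stdev": self.sst_stdev,
            "DTR": self.dtr,
            "SSTA_Freq_stdev": self.ssta_freq_stdev,
            "TSA_DHW_stdev": self.tsa_dhw_stdev,
        }

    def features(self) -> dict:
        row = self.as_row()
        out = {"LAT": row["lat"]}
        out.update({k: row[k] for k in FEATURES if k != "LAT"})
        return out


def _window_values(series: SSTSeries, window, column: str = "sst_mean") -> np.ndarray:
    sub = series.window(*window)
    if sub.empty:
        raise ValueError(f"window {window[0]}..{window[1]} does not intersect the series")
    return sub[column].to_numpy(float)


def average_sst(series: SSTSeries, window) -> float:
    """Arithmetic mean of SST means within the half-open window (°C)."""
    return float(np.nanmean(_window_values(series, window)))


def sst_stdev(series: SSTSeries, window) -> float:
    """Sample (n−1) standard deviation of SST means within the window (°C)."""
    v = _window_values(series, window)
    v = v[~np.isnan(v)]
    return float(np.std(v, ddof=1))


def daily_temperature_range(series: SSTSeries, window) -> float:
    """Mean of per-day (max − min) SST within the window (°C)."""
    if series.cadence != "daily" or not series.has_minmax:
        raise ValueError("DTR requires a daily series with sst_min and sst_max")
    sub = series.window(*window)
    if sub.empty:
        raise ValueError(f"window {window[0]}..{window[1]} does not intersect the series")
    rng = sub["sst_max"].to_numpy(float) - sub["sst_min"].to_numpy(float)
    return float(np.nanmean(rng))


def build_climatology(series: SSTSeries, baseline_years: tuple) -> Climatology:
    """Monthly and ISO-week climatological means over ``[y0, y1)`` years.

    The baseline must span at least two full years; a shorter baseline cannot
    separate the seasonal cycle from single-year anomalies.
    """
    y0, y1 = int(baseline_years[0]), int(baseline_years[1])
    if y1 - y0 < 2:
        raise ValueError(f"baseline_years {baseline_years} spans < 2 full years")
    sub = series.window(f"{y0}-01-01", f"{y1}-01-01")
    if sub.empty:
        raise ValueError(f"series has no data within baseline years {baseline_years}")
    idx = pd.DatetimeIndex(sub.index)
    monthly = sub["sst_mean"].groupby(idx.month).mean()
    weekly = sub["sst_mean"].groupby(idx.isocalendar().week.to_numpy()).mean()
    return Climatology(monthly_means=monthly, weekly_means=weekly, baseline_years=(y0, y1))


def dhw(series_weekly: SSTSeries, clim: Climatology, at, *,
        weeks: int = 12, hotspot_threshold: float = 1.0) -> float:
    """Degree heating weeks at date ``at`` (°C-weeks).

    Trailing-``weeks`` sum of HotSpots (weekly SST minus the MMM) that reach
    the counting threshold.
    """
    at = pd.Timestamp(at)
    sst = series_weekly.data.loc[series_weekly.data.index <= at, "sst_mean"].to_numpy(float)
    if sst.size < weeks:
        raise ValueError(f"need {weeks} trailing weeks of data ending at {at.date()}, have {sst.size}")
    hot = sst[-weeks:] - clim.mmm
    return float(hot[hot >= hotspot_threshold].sum())


def _trailing_threshold_sums(values: np.ndarray, baseline: float, weeks: int,
                             threshold: float) -> np.ndarray:
    """Rolling trailing-window sums of above-threshold excesses.

    Entry ``i`` covers weeks ``i-weeks+1 .. i``; the first ``weeks-1`` entries
    are NaN (incomplete window).
    """
    excess = values - baseline
    contrib = np.where(excess >= threshold, excess, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(contrib)])
    out = np.full(values.size, np.nan)
    if values.size >= weeks:
        out[weeks - 1:] = csum[weeks:] - csum[:-weeks]
    return out


def tsa_dhw_series(series_weekly: SSTSeries, clim: Climatology, *,
                   weeks: int = 12, tsa_threshold: float = 1.0) -> pd.Series:
    """Trailing-window accumulated thermal stress anomaly per week (°C-weeks).

    The TSA baseline is the warmest calendar-week climatological mean; weekly
    excesses of at least ``tsa_threshold`` accumulate over ``weeks`` weeks.
    """
    v = series_weekly.data["sst_mean"].to_numpy(float)
    sums = _trailing_threshold_sums(v, clim.max_weekly_mean, weeks, tsa_threshold)
    return pd.Series(sums, index=series_weekly.data.index)


def tsa_dhw_stdev(series_weekly: SSTSeries, clim: Climatology, window, *,
                  weeks: int = 12, tsa_threshold: float = 1.0) -> float:
    """Sample stdev over the window of the accumulated-TSA series (°C-weeks)."""
    s = tsa_dhw_series(series_weekly, clim, weeks=weeks, tsa_threshold=tsa_threshold)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    vals = s[(s.index >= start) & (s.index < end)].dropna().to_numpy()
    if vals.size < 2:
        raise ValueError("window contains fewer than 2 valid trailing sums")
    return float(np.std(vals, ddof=1))


def ssta_frequencies(series_weekly: SSTSeries, clim: Climatology, window, *,
                     threshold: float = 1.0) -> pd.Series:
    """Anomalous weeks per complete calendar year within the window.

    A week is anomalous when its SST exceeds its calendar-week climatological
    mean by at least ``threshold`` °C. Only years fully contained in the
    half-open window are counted.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    df = series_weekly.data
    sub = df[(df.index >= start) & (df.index < end)]
    idx = pd.DatetimeIndex(sub.index)
    weekly_clim = clim.weekly_means.reindex(idx.isocalendar().week.to_numpy()).to_numpy()
    ssta = sub["sst_mean"].to_numpy(float) - weekly_clim
    years = idx.year.to_numpy()
    counts = {}
    for y in np.unique(years):
        if pd.Timestamp(f"{y}-01-01") >= start and pd.Timestamp(f"{y + 1}-01-01") <= end:
            counts[int(y)] = int(np.sum(ssta[years == y] >= threshold))
    return pd.Series(counts, dtype=float)


def ssta_freq_stdev(series_weekly: SSTSeries, clim: Climatology, window, *,
                    threshold: float = 1.0) -> float:
    """Sample stdev of yearly anomalous-week frequencies (weeks/yr)."""
    freqs = ssta_frequencies(series_weekly, clim, window, threshold=threshold)
    if freqs.size < 2:
        raise ValueError("window contains fewer than 2 whole calendar years")
    return float(np.std(freqs.to_numpy(), ddof=1))


def experiment_dhw(treatment_temp: float, mmm: float, duration_days: float) -> float:
    """Heat dose of a constant-temperature exposure, in °C-weeks.

    Linear accumulation of the excess over the MMM across the exposure:
    ``max(0, treatment − MMM) × days/7``. This is a stated convention — a
    constant-excess analogue of satellite DHW without the 1 °C HotSpot gate,
    appropriate for a controlled ramp-and-hold experiment.
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    return max(0.0, treatment_temp - mmm) * duration_days / 7.0


def profile_reef(series: SSTSeries, latitude: float, lon: float = np.nan,
                 config: MetricConfig | None = None) -> ReefEnvProfile:
    """Assemble all seven predictors for one reef from a daily series.

    Metrics whose window the series does not cover are reported as NaN with a
    warning naming the metric; the remaining metrics are still populated.
    """
    cfg = config or MetricConfig()
    prof = ReefEnvProfile(reef_id=series.reef_id, lat=latitude, lon=lon)

    def attempt(name, fn):
        try:
            return fn()
        except ValueError as exc:
            warnings.warn(f"{name} unavailable for reef {series.reef_id}: {exc}", stacklevel=3)
            return np.nan

    prof.sst_av_pre = attempt("SST_av.pre", lambda: average_sst(series, cfg.window_pre))
    prof.sst_av_post = attempt("SST_av.post", lambda: average_sst(series, cfg.window_post))
    prof.sst_stdev = attempt("SST_stdev", lambda: sst_stdev(series, cfg.window_post))
    prof.dtr = attempt("DTR", lambda: daily_temperature_range(series, cfg.window_post))
    try:
        weekly = to_weekly(series)
        clim = build_climatology(weekly, cfg.baseline_years)
    except ValueError as exc:
        warnings.warn(f"anomaly metrics unavailable for reef {series.reef_id}: {exc}", stacklevel=2)
        return prof
    prof.ssta_freq_stdev = attempt(
        "SSTA_Freq_stdev",
        lambda: ssta_freq_stdev(weekly, clim, cfg.window_post, threshold=cfg.ssta_threshold),
    )
    prof.tsa_dhw_stdev = attempt(
        "TSA_DHW_stdev",
        lambda: tsa_dhw_stdev(weekly, clim, cfg.window_post,
                              weeks=cfg.dhw_weeks, tsa_threshold=cfg.tsa_threshold),
    )
    return prof


def write_profiles(profiles: list[ReefEnvProfile] | pd.DataFrame, path) -> None:
    if isinstance(profiles, pd.DataFrame):
        df = profiles.reindex(columns=PROFILE_COLUMNS)
    else:
        df = pd.DataFrame([p.as_row() for p in profiles], columns=list(PROFILE_COLUMNS))
    df.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def feature_frame(profiles: pd.DataFrame) -> pd.DataFrame:
    """Seven-column feature matrix indexed by reef_id (LAT taken from lat)."""
    df = profiles.set_index("reef_id") if "reef_id" in profiles.columns else profiles.copy()
    out = pd.DataFrame(index=df.index)
    out["LAT"] = df["LAT"] if "LAT" in df.columns else df["lat"]
    for k in FEATURES:
        if k != "LAT":
            out[k] = df[k]
    return out
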