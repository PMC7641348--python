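"""Relative and absolute extreme-heat exposure from daily climate series.

Two families of exposure metric are computed per census tract from daily
Tmax / Tmin / minimum-relative-humidity series of downscaled climate-model
output (four CMIP5 models under a moderate-emissions scenario):

* **Relative (heat waves).**  A tract-local threshold is the 95th percentile
  of seasonal (Apr 1 – Oct 31) daily Tmax (daytime) or Tmin (nighttime) over
  the historical period 1950–1999.  A heat wave is a run of at least two
  consecutive days whose value surpasses that threshold; each maximal run
  counts as one event.
* **Absolute (heat-index days).**  The NWS heat index combines temperature
  and humidity into an apparent temperature; a day whose heat index (from
  daily Tmax and minimum relative humidity) reaches at least 91 °F — the
  lower bound of the "extreme caution" band — counts as a heat-index day,
  using one statewide threshold.

Event counts are annualized per model over the current (2006–2025) and
projected (2040–2059) periods, averaged across models, and differenced
(projected − current) to give per-tract exposure deltas.

Temperatures are carried in °C; conversion to °F happens only inside the
heat-index computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Climate models averaged in the multi-model summaries.
DEFAULT_MODELS = ("HadGEM2-ES", "CNRM-CM5", "CanESM2", "MIROC5")

HISTORICAL_PERIOD = (1950, 1999)
CURRENT_PERIOD = (2006, 2025)
PROJECTED_PERIOD = (2040, 2059)

#: Extreme-heat season: April 1 through October 31, inclusive (214 days).
SEASON_START = (4, 1)
SEASON_END = (10, 31)

#: Heat-index day cutoff: lower bound of the NWS "extreme caution" band.
HI_THRESHOLD_F = 91.0

METRICS = ("daytime_hw", "nighttime_hw", "heat_index_days")

CLIMATE_COLUMNS = ["tract_id", "model_id", "scenario", "date", "tmax_c", "tmin_c", "rhmin_pct"]


def celsius_to_fahrenheit(temp_c):
    return np.asarray(temp_c, dtype=float) * 9.0 / 5.0 + 32.0


def seasonal_subset(series: pd.DataFrame,
                    season_start: tuple[int, int] = SEASON_START,
                    season_end: tuple[int, int] = SEASON_END) -> pd.DataFrame:
    """Restrict a daily series to the heat season and tag the season-year.

    Keeps rows whose (month, day) lies in [season_start, season_end]
    inclusive.  Because the season sits inside one calendar year, the
    season-year is simply the calendar year.
    """
    if series.empty:
        out = series.copy()
        out["season_year"] = pd.Series(dtype=int)
        return out
    dates = pd.to_datetime(series["date"])
    md = list(zip(dates.dt.month, dates.dt.day))
    keep = np.array([season_start <= x <= season_end for x in md])
    out = series.loc[keep].copy()
    out["season_year"] = pd.to_datetime(out["date"]).dt.year.to_numpy()
    return out


def historical_thresholds(seasonal: pd.DataFrame,
                          period: tuple[int, int] = HISTORICAL_PERIOD,
                          q: float = 0.95,
                          min_days: int = 100) -> pd.Series:
    """95th-percentile Tmax/Tmin thresholds for one tract.

    Quantiles are taken over the pooled seasonal daily values of all
    historical years (and all models present), with the linear-interpolation
    quantile definition.  Returns a Series with ``tmax_p95`` and ``tmin_p95``.
    """
    years = seasonal["season_year"].to_numpy()
    sel = (years >= period[0]) & (years <= period[1])
    sub = seasonal.loc[sel]
    if len(sub) < min_days:
        raise ValueError(
            f"only {len(sub)} seasonal days in {period[0]}-{period[1]}; "
            f"need at least {min_days} to estimate thresholds")
    return pd.Series({
        "tmax_p95": float(np.quantile(sub["tmax_c"].to_numpy(float), q)),
        "tmin_p95": float(np.quantile(sub["tmin_c"].to_numpy(float), q)),
    })


def historical_thresholds_table(seasonal: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-tract threshold table (rows indexed by tract_id)."""
    rows = {tract: historical_thresholds(g, **kwargs)
            for tract, g in seasonal.groupby("tract_id", observed=True, sort=True)}
    out = pd.DataFrame(rows).T
    out.index.name = "tract_id"
    return out


def count_heat_waves(values,
                     threshold: float,
                     min_duration: int = 2,
                     strict: bool = True,
                     dates=None) -> int:
    """Number of heat-wave events in an ordered daily series.

    An exceedance day surpasses the threshold (strictly by default); each
    maximal run of consecutive exceedance days of length >= ``min_duration``
    counts as exactly one event, however long.  If ``dates`` is given, a gap
    of more than one day breaks a run (runs never span the off-season).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be at least 1")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 0
    exceed = v > threshold if strict else v >= threshold
    brk = np.zeros(v.size, dtype=bool)
    brk[0] = True
    if dates is not None:
        d = pd.to_datetime(np.asarray(dates)).to_numpy()
        if np.any(np.diff(d) < np.timedelta64(0, "D")):
            raise ValueError("dates must be sorted ascending")
        brk[1:] = np.diff(d) > np.timedelta64(1, "D")
    prev = np.concatenate(([False], exceed[:-1]))
    starts = exceed & (~prev | brk)
    run_id = np.cumsum(starts)
    if run_id[-1] == 0:
        return 0
    lengths = np.bincount(run_id[exceed])[1:]
    return int(np.count_nonzero(lengths >= min_duration))


def heat_index(temp_f, rh):
    """NWS heat index (°F) from air temperature (°F) and relative humidity (%).

    Follows the National Weather Service algorithm: a simple Steadman-style
    average ``0.5*(T + 61 + (T-68)*1.2 + RH*0.094)`` is used when it falls
    below 80 °F; otherwise the Rothfusz regression applies, with the standard
    low-humidity adjustment (RH < 13 %, 80–112 °F) and high-humidity
    adjustment (RH > 85 %, 80–87 °F).
    """
    t, r = np.broadcast_arrays(np.asarray(temp_f, float), np.asarray(rh, float))
    scalar = t.ndim == 0
    t, r = np.atleast_1d(t), np.atleast_1d(r)
    valid = ~np.isnan(r)
    if np.any((r[valid] < 0) | (r[valid] > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + r * 0.094)
    hi = simple.copy()
    hot = simple >= 80.0
    if np.any(hot):
        T, R = t[hot], r[hot]
        full = (-42.379 + 2.04901523 * T + 10.14333127 * R
                - 0.22475541 * T * R - 6.83783e-3 * T ** 2
                - 5.481717e-2 * R ** 2 + 1.22874e-3 * T ** 2 * R
                + 8.5282e-4 * T * R ** 2 - 1.99e-6 * T ** 2 * R ** 2)
        low = (R < 13) & (T >= 80) & (T <= 112)
        full[low] -= ((13.0 - R[low]) / 4.0) * np.sqrt((17.0 - np.abs(T[low] - 95.0)) / 17.0)
        high = (R > 85) & (T >= 80) & (T <= 87)
        full[high] += ((R[high] - 85.0) / 10.0) * ((87.0 - T[high]) / 5.0)
        hi[hot] = full
    hi[~valid] = np.nan
    return float(hi[0]) if scalar else hi


def count_heat_index_days(season_year_series: pd.DataFrame,
                          hi_threshold_f: float = HI_THRESHOLD_F) -> int:
    """Days in a series whose heat index reaches the threshold (inclusive).

    Pairs each day's Tmax (converted to °F) with the same day's minimum
    relative humidity.  Days with missing humidity are skipped and their
    count logged.
    """
    tmax_f = celsius_to_fahrenheit(season_year_series["tmax_c"].to_numpy(float))
    rh = season_year_series["rhmin_pct"].to_numpy(float)
    missing = int(np.isnan(rh).sum())
    if missing:
        logger.info("count_heat_index_days: skipped %d days with missing humidity", missing)
    hi = heat_index(tmax_f, rh)
    return int(np.nansum(hi >= hi_threshold_f))


def annualized_rate(counts_per_year: Sequence[float]) -> float:
    """Average events per year over a period (mean of per-season-year counts)."""
    arr = np.asarray(counts_per_year, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one season-year of counts")
    return float(arr.mean())


def multi_model_summary(per_model_rates: pd.DataFrame) -> pd.DataFrame:
    """Average per-model annual rates across models and difference the periods.

    Input columns: ``tract_id, metric, period, model_id, rate`` with periods
    ``current`` and ``projected``.  The same model set must appear in both
    periods for every tract and metric.  Returns one row per (tract, metric)
    with ``current_rate``, ``projected_rate`` (means over models) and
    ``delta = projected_rate - current_rate``.
    """
    required = {"tract_id", "metric", "period", "model_id", "rate"}
    if not required.issubset(per_model_rates.columns):
        raise ValueError(f"per-model rate table must have columns {sorted(required)}")
    models = (per_model_rates.groupby(["tract_id", "metric", "period"], observed=True)
              ["model_id"].agg(lambda s: frozenset(s)))
    if models.groupby(level=["tract_id", "metric"], observed=True).nunique().gt(1).any():
        raise ValueError("model sets differ between periods")
    means = (per_model_rates.groupby(["tract_id", "metric", "period"], observed=True)["rate"]
             .mean().unstack("period"))
    for period in ("current", "projected"):
        if period not in means.columns:
            raise ValueError(f"missing period {period!r} in per-model rates")
    out = means.rename(columns={"current": "current_rate", "projected": "projected_rate"})
    out["delta"] = out["projected_rate"] - out["current_rate"]
    return out.reset_index()[["tract_id", "metric", "current_rate", "projected_rate", "delta"]]


@dataclass
class ExposureResult:
    """Bundle of exposure outputs: per-tract summary, per-model rates, thresholds."""
    summary: pd.DataFrame
    per_model: pd.DataFrame
    thresholds: pd.DataFrame


def _yearly_period_rate_hw(dates, values, years, threshold, period, min_duration, strict):
    y0, y1 = period
    sel = (years >= y0) & (years <= y1)
    n_years = y1 - y0 + 1
    events = count_heat_waves(values[sel], threshold,
                              min_duration=min_duration, strict=strict, dates=dates[sel])
    # runs cannot span season-years (the off-season gap breaks them), so the
    # period total divided by the year count equals the mean of yearly counts
    return events / n_years


def compute_exposure(climate: pd.DataFrame,
                     periods: Mapping[str, tuple[int, int]] | None = None,
                     historical: tuple[int, int] = HISTORICAL_PERIOD,
                     season_start: tuple[int, int] = SEASON_START,
                     season_end: tuple[int, int] = SEASON_END,
                     q: float = 0.95,
                     hi_threshold_f: float = HI_THRESHOLD_F,
                     min_duration: int = 2,
                     strict: bool = True,
                     thresholds: pd.DataFrame | None = None) -> ExposureResult:
    """Full exposure computation for a long-format daily climate table.

    For every tract and model: seasonal subset, tract-local historical
    thresholds (pooled across models unless precomputed ``thresholds`` are
    supplied), annualized heat-wave and heat-index-day rates per period, then
    the multi-model mean and the projected-minus-current delta per metric.
    """
    if periods is None:
        periods = {"current": CURRENT_PERIOD, "projected": PROJECTED_PERIOD}
    seasonal = seasonal_subset(climate, season_start, season_end)
    if thresholds is None:
        thresholds = historical_thresholds_table(seasonal, period=historical, q=q)
    records = []
    for (tract, model), g in seasonal.groupby(["tract_id", "model_id"],
                                              observed=True, sort=True):
        g = g.sort_values("date")
        thr = thresholds.loc[tract]
        dates = pd.to_datetime(g["date"]).to_numpy()
        years = g["season_year"].to_numpy()
        tmax = g["tmax_c"].to_numpy(float)
        tmin = g["tmin_c"].to_numpy(float)
        rh = g["rhmin_pct"].to_numpy(float)
        hi = heat_index(celsius_to_fahrenheit(tmax), rh)
        hi_day = hi >= hi_threshold_f  # NaN humidity -> False (skipped day)
        for pname, period in periods.items():
            y0, y1 = period
            n_years = y1 - y0 + 1
            sel = (years >= y0) & (years <= y1)
            rates = {
                "daytime_hw": _yearly_period_rate_hw(
                    dates, tmax, years, float(thr["tmax_p95"]), period, min_duration, strict),
                "nighttime_hw": _yearly_period_rate_hw(
                    dates, tmin, years, float(thr["tmin_p95"]), period, min_duration, strict),
                "heat_index_days": float(np.count_nonzero(hi_day[sel])) / n_years,
            }
            for metric, rate in rates.items():
                records.append((tract, model, pname, metric, rate))
    per_model = pd.DataFrame(records,
                             columns=["tract_id", "model_id", "period", "metric", "rate"])
    summary = multi_model_summary(per_model)
    return ExposureResult(summary=summary, per_model=per_model, thresholds=thresholds)
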