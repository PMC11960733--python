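"""De-seasonalized anomalies, bay-wide averaging, and trend estimation.

The seasonal cycle at each station/layer is the climatological mean of each
calendar month over the multiyear record; subtracting it month-by-month
yields de-seasonalized monthly anomalies whose linear trend against decimal
time is the long-term change.  Anomalies are averaged unweighted across
stations to form the bay-wide series.  Trends are ordinary least squares;
the Durbin-Watson statistic is attached as an autocorrelation screen but
never used to adjust the inference.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "TrendResult",
    "AnomalyRegression",
    "compute_climatology",
    "deseasonalize",
    "baywide_average",
    "decimal_year",
    "fit_trend",
    "fit_trends_table",
    "regress_anomalies",
]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of a monthly anomaly series, in units per year."""

    slope: float
    intercept: float
    p_value: float
    n_months: int
    ci_low: float
    ci_high: float
    durbin_watson: float
    durbin_watson_p: float
    parameter: str = ""
    layer: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AnomalyRegression:
    """OLS fit between two bay-wide anomaly series on matched months."""

    response: str
    predictor: str
    slope: float
    intercept: float
    p_value: float
    r_value: float
    n_months: int
    ci_low: float
    ci_high: float
    layer_mode: str

    def to_dict(self) -> dict:
        return asdict(self)


def compute_climatology(monthly: pd.DataFrame, min_years: int = 1) -> pd.DataFrame:
    """Multiyear mean per (station, layer, month, parameter).

    Calendar months represented in fewer than ``min_years`` distinct years
    are omitted.  Input is the long monthly table from the QA/QC stage.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    grouped = monthly.groupby(["station", "layer", "month", "parameter"],
                              sort=True)["value"]
    clim = grouped.agg(climatology="mean", n_years="count").reset_index()
    return clim[clim["n_years"] >= min_years].reset_index(drop=True)


def deseasonalize(monthly: pd.DataFrame, climatology: pd.DataFrame) -> pd.DataFrame:
    """Monthly anomalies: value minus the station/layer/month climatology.

    Months lacking a climatology entry are omitted.  By construction the
    mean anomaly over contributing years is zero for every
    (station, layer, month, parameter).
    """
    merged = monthly.merge(
        climatology[["station", "layer", "month", "parameter", "climatology"]],
        on=["station", "layer", "month", "parameter"], how="inner")
    merged["anomaly"] = merged["value"] - merged["climatology"]
    return merged[["station", "layer", "year", "month", "parameter",
                   "anomaly"]].reset_index(drop=True)


def baywide_average(anomalies: pd.DataFrame,
                    station_set: Sequence[str] | None = None) -> pd.DataFrame:
    """Unweighted mean anomaly across stations per (layer, year, month, parameter).

    ``station_set`` restricts the average (e.g. excluding a low-salinity
    river station from a bay-wide mean); stations with no value that month
    simply drop out of the denominator.  The contributing-station count is
    attached as ``n_stations``.
    """
    frame = anomalies
    if station_set is not None:
        station_set = list(station_set)
        if not station_set:
            raise ValueError("station_set must be non-empty")
        frame = frame[frame["station"].isin(station_set)]
    grouped = frame.groupby(["layer", "year", "month", "parameter"],
                            sort=True)["anomaly"]
    return grouped.agg(anomaly="mean", n_stations="count").reset_index()


def decimal_year(year, month):
    """Month-centered decimal time axis: year + (month - 0.5)/12."""
    return np.asarray(year, dtype=float) + (np.asarray(month, dtype=float) - 0.5) / 12.0


def _dw_pvalue(dw: float, n: int) -> float:
    """Two-sided p-value for the Durbin-Watson statistic.

    Normal approximation DW ~ N(2, 4/n) under the no-autocorrelation null;
    adequate for the screening role the statistic plays here.
    """
    if n < 3:
        return float("nan")
    z = (dw - 2.0) / (2.0 / np.sqrt(n))
    return float(2.0 * stats.norm.sf(abs(z)))


def fit_trend(anomaly_series: pd.DataFrame, parameter: str = "",
              layer: str = "", min_months: int = 24,
              months: Sequence[int] | None = None) -> TrendResult:
    """OLS trend of monthly anomalies on decimal time, units per year.

    ``anomaly_series`` needs columns year, month, anomaly (one row per
    month).  ``months`` optionally restricts to a seasonal subset (e.g.
    ``range(6, 10)`` for a summer-only fit).  At least ``min_months``
    observations are required; the two-sided slope p-value, its 95% CI and
    the Durbin-Watson screen accompany the estimate.
    """
    frame = anomaly_series.dropna(subset=["anomaly"])
    if months is not None:
        frame = frame[frame["month"].isin(list(months))]
    n = len(frame)
    if n < min_months:
        raise ValueError(f"trend needs >= {min_months} months, got {n}")
    t = decimal_year(frame["year"], frame["month"])
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    y = frame["anomaly"].to_numpy(float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    model = sm.OLS(y, sm.add_constant(t - t.mean())).fit()
    # a perfect fit leaves no residual variance for the DW statistic
    dw = (float(durbin_watson(model.resid))
          if np.sum(model.resid ** 2) > 0 else float("nan"))
    ci = model.conf_int(alpha=0.05)
    return TrendResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]), n_months=n,
        ci_low=float(ci[1][0]), ci_high=float(ci[1][1]),
        durbin_watson=dw, durbin_watson_p=_dw_pvalue(dw, n),
        parameter=parameter, layer=layer)


def fit_trends_table(baywide: pd.DataFrame, min_months: int = 24,
                     months: Sequence[int] | None = None) -> list[TrendResult]:
    """Fit a trend for every (layer, parameter) series in a bay-wide table."""
    results = []
    for (layer, parameter), group in baywide.groupby(["layer", "parameter"], sort=True):
        try:
            results.append(fit_trend(group, parameter=parameter, layer=layer,
                                     min_months=min_months, months=months))
        except ValueError:
            continue
    return results


def regress_anomalies(baywide: pd.DataFrame, response: str, predictor: str,
                      layer_mode: str = "mean-of-layers",
                      min_months: int = 24) -> AnomalyRegression:
    """OLS between two bay-wide anomaly series on matched (year, month) pairs.

    ``layer_mode``: ``"surface"`` or ``"bottom"`` match within one layer;
    ``"mean-of-layers"`` averages the two layers per month before matching
    (the natural choice when surface and bottom share driving processes);
    ``"pooled"`` stacks both layers' matched pairs into one fit.
    """
    def series(parameter: str) -> pd.DataFrame:
        sub = baywide[baywide["parameter"] == parameter]
        if layer_mode in ("surface", "bottom"):
            sub = sub[sub["layer"] == layer_mode]
            return sub[["year", "month", "anomaly"]]
        if layer_mode == "mean-of-layers":
            return (sub.groupby(["year", "month"])["anomaly"].mean().reset_index())
        if layer_mode == "pooled":
            return sub[["layer", "year", "month", "anomaly"]]
        raise ValueError(f"unknown layer_mode {layer_mode!r}")

    keys = ["layer", "year", "month"] if layer_mode == "pooled" else ["year", "month"]
    pairs = series(response).merge(series(predictor), on=keys,
                                   suffixes=("_y", "_x")).dropna()
    n = len(pairs)
    if n < min_months:
        raise ValueError(f"regression needs >= {min_months} matched months, got {n}")
    x = pairs["anomaly_x"].to_numpy(float)
    y = pairs["anomaly_y"].to_numpy(float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return AnomalyRegression(
        response=response, predictor=predictor,
        slope=float(model.params[1]), intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_value=float(np.sign(model.params[1]) * np.sqrt(model.rsquared)),
        n_months=n, ci_low=float(ci[1][0]), ci_high=float(ci[1][1]),
        layer_mode=layer_mode)
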