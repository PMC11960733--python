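"""Daily averaging and iterative IQR outlier screening.

Raw sub-daily readings are collapsed to daily means per station/layer.  A
day is then an outlier for a parameter when its value lies beyond
Q1 - 1.5*IQR or Q3 + 1.5*IQR, with quartiles computed per station, layer
and parameter over the full multi-year daily series.  Because short extreme
events (episodic blooms, transient hypoxia) contaminate every simultaneously
measured parameter, the entire day's row is removed when any one of
temperature, salinity, DO or pH is flagged; fences are then recomputed and
the screen repeated until no parameter flags any day.  Chlorophyll is never
screened: the bottom layer carries no chlorophyll sensor and filtering only
the surface would bias the layers against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .seawater import do_mgL_to_umolkg

__all__ = [
    "FILTERED_PARAMETERS",
    "PARAMETERS",
    "IqrFences",
    "OutlierReport",
    "daily_means",
    "iqr_fences",
    "remove_outliers_cascade",
    "monthly_means",
]

#: Parameters subject to the row-cascade outlier rule.
FILTERED_PARAMETERS = ("temperature", "salinity", "do_umolkg", "pH_nbs")
#: All daily parameters carried through to monthly means.
PARAMETERS = FILTERED_PARAMETERS + ("chl",)

#: Default multiplier on the interquartile range defining the fences.
IQR_MULTIPLIER = 1.5


@dataclass(frozen=True)
class IqrFences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float


@dataclass
class OutlierReport:
    """Per station/layer/parameter fence diagnostics and removal accounting."""

    fences: dict = field(default_factory=dict)          # (station, layer, param) -> IqrFences (final pass)
    removed: list = field(default_factory=list)         # dicts: station, layer, date, parameters
    iterations: dict = field(default_factory=dict)      # (station, layer) -> passes until fixed point
    n_days_in: int = 0
    n_days_removed: int = 0

    @property
    def removed_fraction(self) -> float:
        return self.n_days_removed / self.n_days_in if self.n_days_in else 0.0

    def to_dict(self) -> dict:
        return {
            "n_days_in": self.n_days_in,
            "n_days_removed": self.n_days_removed,
            "removed_fraction": self.removed_fraction,
            "iterations": {f"{s}/{l}": n for (s, l), n in self.iterations.items()},
            "fences": {f"{s}/{l}/{p}": asdict(f) for (s, l, p), f in self.fences.items()},
            "removed": [
                {**r, "date": str(r["date"])} for r in self.removed],
        }


def iqr_fences(values, multiplier: float = IQR_MULTIPLIER,
               method: str = "linear") -> IqrFences:
    """Quartiles and Tukey fences for a 1-D sample.

    Quartiles use linear interpolation between order statistics by default
    (numpy's ``method="linear"``, the common "type 7" convention); the
    estimator is configurable.  Requires at least 4 finite values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError(f"iqr_fences needs >= 4 finite values, got {arr.size}")
    q1, q3 = np.percentile(arr, [25, 75], method=method)
    iqr = q3 - q1
    return IqrFences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                     lower=float(q1 - multiplier * iqr),
                     upper=float(q3 + multiplier * iqr))


def daily_means(records: pd.DataFrame, min_samples: int = 1) -> pd.DataFrame:
    """Collapse raw readings to daily means per station/layer/calendar date.

    DO is converted from mg/L to umol/kg reading-by-reading at in-situ
    temperature and salinity before averaging, so the daily mean tracks
    oxygen content of the sampled water masses.  A parameter with fewer than
    ``min_samples`` valid readings on a date is reported absent (NaN) for
    that day; the day itself is kept as long as any parameter reports.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    frame = records.copy()
    convertible = frame[["do_mgL", "temperature", "salinity"]].notna().all(axis=1)
    frame["do_umolkg"] = np.nan
    if convertible.any():
        sub = frame.loc[convertible]
        frame.loc[convertible, "do_umolkg"] = do_mgL_to_umolkg(
            sub["do_mgL"].to_numpy(float), sub["temperature"].to_numpy(float),
            sub["salinity"].to_numpy(float))
    frame["date"] = pd.to_datetime(frame["timestamp"]).dt.normalize()

    grouped = frame.groupby(["station_id", "layer", "date"], sort=True)
    means = grouped[list(PARAMETERS)].mean()
    counts = grouped[list(PARAMETERS)].count()
    means = means.where(counts >= min_samples)
    counts = counts.rename(columns={p: f"n_{p}" for p in PARAMETERS})
    daily = pd.concat([means, counts], axis=1).reset_index()
    return daily.dropna(subset=list(PARAMETERS), how="all").reset_index(drop=True)


def remove_outliers_cascade(
        daily: pd.DataFrame,
        parameters: Sequence[str] = FILTERED_PARAMETERS,
        multiplier: float = IQR_MULTIPLIER,
        method: str = "linear",
        max_iterations: int = 50,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Iteratively remove whole days whose value for any parameter is an outlier.

    Fences are recomputed from the surviving days on every pass, per station,
    layer and parameter over the full multi-year series; the cascade stops at
    the fixed point where no parameter flags any day.  A day missing a
    parameter is simply not tested on it.  Chlorophyll may not be included.

    Returns the clean daily frame and an :class:`OutlierReport`.  Raises
    ``RuntimeError`` (carrying the partial report) if ``max_iterations`` is
    exceeded.
    """
    bad = set(parameters) - set(FILTERED_PARAMETERS)
    if bad:
        raise ValueError(f"parameters not eligible for outlier screening: {sorted(bad)}")

    report = OutlierReport(n_days_in=len(daily))
    pieces = []
    for (station, layer), group in daily.groupby(["station_id", "layer"], sort=True):
        current = group
        for iteration in range(1, max_iterations + 1):
            flagged = pd.Series(False, index=current.index)
            triggers: dict[int, list[str]] = {}
            for param in parameters:
                values = current[param]
                if values.notna().sum() < 4:
                    continue
                fences = iqr_fences(values.dropna(), multiplier, method)
                report.fences[(station, layer, param)] = fences
                out = values.notna() & ((values < fences.lower) | (values > fences.upper))
                for idx in current.index[out]:
                    triggers.setdefault(idx, []).append(param)
                flagged |= out
            if not flagged.any():
                report.iterations[(station, layer)] = iteration
                break
            for idx in current.index[flagged]:
                report.removed.append({
                    "station": station, "layer": layer,
                    "date": current.at[idx, "date"],
                    "parameters": triggers[idx]})
            current = current[~flagged]
        else:
            report.n_days_removed = len(report.removed)
            raise RuntimeError(
                f"outlier cascade did not converge within {max_iterations} passes "
                f"for {station}/{layer}; partial report: "
                f"{report.n_days_removed} days removed")
        pieces.append(current)

    clean = (pd.concat(pieces).sort_index().reset_index(drop=True)
             if pieces else daily.iloc[0:0].copy())
    report.n_days_removed = len(report.removed)
    return clean, report


def monthly_means(clean_daily: pd.DataFrame) -> pd.DataFrame:
    """Monthly means of clean daily values, long format.

    One row per (station, layer, year, month, parameter) with the arithmetic
    mean of the contributing days and their count; parameter-months with no
    clean days are absent rather than NaN.
    """
    frame = clean_daily.copy()
    dates = pd.to_datetime(frame["date"])
    frame["year"] = dates.dt.year
    frame["month"] = dates.dt.month
    long = frame.melt(
        id_vars=["station_id", "layer", "year", "month"],
        value_vars=list(PARAMETERS), var_name="parameter", value_name="value",
    ).dropna(subset=["value"])
    grouped = long.groupby(["station_id", "layer", "year", "month", "parameter"],
                           sort=True)["value"]
    monthly = grouped.agg(value="mean", n_days="count").reset_index()
    return monthly.rename(columns={"station_id": "station"})
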