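"""End-to-end convenience wiring: raw records -> QA/QC -> anomalies -> trends."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import qaqc, trends
from .qaqc import OutlierReport
from .trends import TrendResult

__all__ = ["PipelineResult", "run_trend_pipeline"]


@dataclass
class PipelineResult:
    daily: pd.DataFrame
    clean_daily: pd.DataFrame
    outlier_report: OutlierReport
    monthly: pd.DataFrame
    climatology: pd.DataFrame
    anomalies: pd.DataFrame
    baywide: pd.DataFrame
    trends: list[TrendResult]

    def trend(self, layer: str, parameter: str) -> TrendResult:
        for t in self.trends:
            if t.layer == layer and t.parameter == parameter:
                return t
        raise KeyError(f"no trend for {layer}/{parameter}")


def run_trend_pipeline(records: pd.DataFrame,
                       analysis_stations: Sequence[str] | None = None,
                       min_samples: int = 1, min_years: int = 3,
                       months: Sequence[int] | None = None,
                       skip_outlier_screen: bool = False) -> PipelineResult:
    """Run the standard analysis chain on a reader-layout record frame.

    ``records`` as returned by :func:`baycarb.io.read_sensor_csv` (canonical
    column names).  ``analysis_stations`` restricts the bay-wide average
    (e.g. excluding a river-dominated station); ``months`` restricts trend
    fits to a seasonal subset.
    """
    daily = qaqc.daily_means(records, min_samples=min_samples)
    if skip_outlier_screen:
        clean, report = daily, OutlierReport(n_days_in=len(daily))
    else:
        clean, report = qaqc.remove_outliers_cascade(daily)
    monthly = qaqc.monthly_means(clean)
    climatology = trends.compute_climatology(monthly, min_years=min_years)
    anomalies = trends.deseasonalize(monthly, climatology)
    baywide = trends.baywide_average(anomalies, analysis_stations)
    fitted = trends.fit_trends_table(baywide, months=months)
    return PipelineResult(daily=daily, clean_daily=clean, outlier_report=report,
                          monthly=monthly, climatology=climatology,
                          anomalies=anomalies, baywide=baywide, trends=fitted)
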