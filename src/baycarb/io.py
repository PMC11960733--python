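"""Reading and writing monitoring-network sensor tables.

The network distributes delimited text: one row per timestamped reading at a
station/layer, blank fields meaning "not measured".  The reader normalizes
column names through a user-supplied mapping, validates physical ranges,
counts (never silently drops) unparseable rows, and emits records in
timestamp order per station.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "SensorRecord",
    "StationInfo",
    "IngestReport",
    "DEFAULT_COLUMN_MAP",
    "read_sensor_csv",
    "write_sensor_csv",
    "write_monthly_table",
    "read_monthly_table",
]


class Layer(str, Enum):
    SURFACE = "surface"
    BOTTOM = "bottom"


_LAYER_ALIASES = {
    "surface": Layer.SURFACE, "s": Layer.SURFACE, "surf": Layer.SURFACE,
    "bottom": Layer.BOTTOM, "b": Layer.BOTTOM, "bot": Layer.BOTTOM,
}

#: Physical validity ranges (inclusive) applied on ingest.
_RANGES = {
    "temperature": (-3.0, 40.0),
    "salinity": (0.0, 40.0),
    "do_mgL": (0.0, np.inf),
    "pH_nbs": (5.0, 10.0),
}

#: Canonical column name -> default header name in network files.
DEFAULT_COLUMN_MAP = {
    "station_id": "station",
    "timestamp": "timestamp",
    "layer": "layer",
    "temperature": "temperature",
    "salinity": "salinity",
    "do_mgL": "do_mgL",
    "pH_nbs": "pH",
    "chl": "chl",
    "depth": "depth",
}

_REQUIRED = ("station_id", "timestamp", "layer")
_NUMERIC = ("temperature", "salinity", "do_mgL", "pH_nbs", "chl", "depth")


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped multi-parameter observation at a station/layer.

    Missing parameters are ``None`` (distinct from zero).
    """

    station_id: str
    timestamp: datetime
    layer: Layer
    temperature: float | None = None
    salinity: float | None = None
    do_mgL: float | None = None
    pH_nbs: float | None = None
    chl: float | None = None
    depth: float | None = None


@dataclass(frozen=True)
class StationInfo:
    station_id: str
    name: str = ""
    years_available: frozenset[int] = field(default_factory=frozenset)
    samples_year_round: bool = False


@dataclass
class IngestReport:
    """Accounting of a read: emitted + rejected + deduplicated = data rows."""

    n_rows: int = 0
    n_emitted: int = 0
    n_rejected: int = 0
    n_deduplicated: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _parse_value(name: str, raw) -> float | None:
    """Parse one numeric field; '' -> None; out-of-range or junk -> ValueError."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    value = float(text)  # raises ValueError on junk
    if name in _RANGES:
        lo, hi = _RANGES[name]
        if not (lo <= value <= hi):
            raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
    return value


def read_sensor_csv(path, column_map: dict[str, str] | None = None,
                    ) -> tuple[pd.DataFrame, IngestReport]:
    """Read a sensor CSV into a tidy frame, with full row accounting.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    column_map : dict, optional
        Maps canonical names (keys of :data:`DEFAULT_COLUMN_MAP`) to the
        file's header names.  Unmapped optional parameters are treated as
        absent columns.

    Returns
    -------
    (frame, report)
        ``frame`` has canonical columns, one row per accepted record,
        sorted by (station, layer, timestamp); duplicated timestamps within
        a station/layer keep the first occurrence.  ``report`` counts rows
        in, rows out, rejects (with reasons) and dedups.

    Raises
    ------
    KeyError
        If a required column is missing from the file (configuration error).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    report = IngestReport(n_rows=len(raw))

    for key in _REQUIRED:
        if cmap[key] not in raw.columns:
            raise KeyError(f"required column {cmap[key]!r} (for {key}) missing in {path}")

    present_numeric = [k for k in _NUMERIC if cmap[k] in raw.columns]

    rows = []
    for idx, row in raw.iterrows():
        try:
            station = str(row[cmap["station_id"]]).strip()
            if not station:
                raise ValueError("empty station id")
            ts = pd.Timestamp(row[cmap["timestamp"]])
            if pd.isna(ts):
                raise ValueError("unparseable timestamp")
            layer_raw = str(row[cmap["layer"]]).strip().lower()
            if layer_raw not in _LAYER_ALIASES:
                raise ValueError(f"unknown layer label {layer_raw!r}")
            rec = {"station_id": station, "timestamp": ts,
                   "layer": _LAYER_ALIASES[layer_raw].value}
            for key in _NUMERIC:
                rec[key] = _parse_value(key, row[cmap[key]]) if key in present_numeric else None
            rows.append(rec)
        except (ValueError, TypeError) as exc:
            report.n_rejected += 1
            report.rejections.append((int(idx), str(exc)))

    frame = pd.DataFrame(
        rows, columns=["station_id", "timestamp", "layer", *_NUMERIC])
    frame[list(_NUMERIC)] = frame[list(_NUMERIC)].astype(float)
    if len(frame):
        frame = frame.sort_values(["station_id", "layer", "timestamp"],
                                  kind="stable")
        dup = frame.duplicated(["station_id", "layer", "timestamp"], keep="first")
        if dup.any():
            report.n_deduplicated = int(dup.sum())
            report.warnings.append(
                f"{report.n_deduplicated} duplicated station/layer/timestamp "
                "rows dropped (keep-first policy)")
            frame = frame[~dup]
        frame = frame.reset_index(drop=True)
    report.n_emitted = len(frame)
    return frame, report


def iter_records(frame: pd.DataFrame) -> Iterator[SensorRecord]:
    """Yield :class:`SensorRecord` objects from a reader frame."""
    for row in frame.itertuples(index=False):
        yield SensorRecord(
            station_id=row.station_id,
            timestamp=row.timestamp.to_pydatetime(),
            layer=Layer(row.layer),
            temperature=row.temperature, salinity=row.salinity,
            do_mgL=row.do_mgL, pH_nbs=row.pH_nbs,
            chl=row.chl, depth=row.depth)


def write_sensor_csv(frame: pd.DataFrame, path) -> None:
    """Write a record frame in the layout :func:`read_sensor_csv` expects."""
    out = frame.rename(columns={"station_id": "station", "pH_nbs": "pH"})
    out.to_csv(path, index=False, float_format="%.6g")


_MONTHLY_COLUMNS = ["station", "layer", "year", "month", "parameter", "value", "n_days"]


def write_monthly_table(monthly: pd.DataFrame, path) -> None:
    """Write a long-format monthly table, sorted by (station, layer, year, month).

    Columns: station, layer, year, month, parameter, value, n_days.  Values
    are written to 6 significant digits; absent values stay blank.
    """
    if monthly.empty:
        raise ValueError("refusing to write an empty monthly table")
    out = monthly.loc[:, _MONTHLY_COLUMNS].sort_values(
        ["station", "layer", "year", "month", "parameter"], kind="stable")
    out.to_csv(path, index=False, float_format="%.6g")


def read_monthly_table(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_monthly_table` output."""
    frame = pd.read_csv(path)
    missing = set(_MONTHLY_COLUMNS) - set(frame.columns)
    if missing:
        raise KeyError(f"monthly table {path} lacks columns {sorted(missing)}")
    return frame
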