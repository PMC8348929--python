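"""Reading, validation and regularization of sensor time series.

A :class:`TimeSeries` is a uniformly sampled scalar record (e.g. dissolved
oxygen in mg/L or electrical conductivity in µS/cm at a 15-minute cadence).
Gaps longer than a configurable maximum are kept as explicit NaN markers so
that local variance statistics downstream are never diluted by long imputed
stretches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TimeSeries", "GapReport", "read_series", "write_series", "regularize"]


class ConfigurationError(ValueError):
    """A named column or config entry is missing or invalid."""


class EmptyInputError(ValueError):
    """No usable data rows."""


@dataclass
class GapReport:
    """Bookkeeping of what :func:`regularize` did to the record."""

    n_interpolated: int = 0
    n_gap_markers: int = 0
    n_duplicates_collapsed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_interpolated": self.n_interpolated,
            "n_gap_markers": self.n_gap_markers,
            "n_duplicates_collapsed": self.n_duplicates_collapsed,
        }


@dataclass
class TimeSeries:
    """Uniformly sampled scalar series with site/parameter metadata.

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Strictly increasing, timezone-naive.
    values : numpy.ndarray
        Same length as ``timestamps``; NaN marks an explicit gap.
    step_minutes : float
        Nominal sampling interval.
    parameter : str
        Measured quantity with units, e.g. ``"dissolved_oxygen mg/L"``.
    site : str
        Monitoring-site label, e.g. ``"BH"``.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    step_minutes: float = 15.0
    parameter: str = ""
    site: str = ""
    gap_report: GapReport = field(default_factory=GapReport)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_regular(self) -> bool:
        if len(self) < 2:
            return True
        deltas = np.diff(self.timestamps.asi8) / (60 * 1e9)
        return bool(np.allclose(deltas, self.step_minutes))

    def finite_values(self) -> np.ndarray:
        """Values with gap markers removed."""
        return self.values[np.isfinite(self.values)]


def read_series(
    path,
    timestamp_column: str = "timestamp",
    value_column: str = "value",
    parameter: str = "",
    site: str = "",
) -> TimeSeries:
    """Read a CSV sensor record into a :class:`TimeSeries`.

    Rows are sorted by time; duplicate timestamps are collapsed by their mean
    (sensor re-transmissions) with a logged warning.
    """
    df = pd.read_csv(path)
    for col in (timestamp_column, value_column):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (have {list(df.columns)})"
            )
    df = df[[timestamp_column, value_column]].copy()
    df[timestamp_column] = pd.to_datetime(df[timestamp_column], errors="coerce")
    df = df.dropna(subset=[timestamp_column])
    df[value_column] = pd.to_numeric(df[value_column], errors="coerce")
    if len(df) == 0:
        raise EmptyInputError(f"no parseable rows in {path}")
    df = df.sort_values(timestamp_column)

    n_dup = int(df[timestamp_column].duplicated().sum())
    if n_dup:
        logger.warning("collapsing %d duplicate timestamps by mean", n_dup)
        df = df.groupby(timestamp_column, as_index=False)[value_column].mean()

    ts = pd.DatetimeIndex(df[timestamp_column])
    step = 15.0
    if len(ts) > 1:
        step = float(np.median(np.diff(ts.asi8)) / (60 * 1e9))
    series = TimeSeries(
        timestamps=ts,
        values=df[value_column].to_numpy(dtype=float),
        step_minutes=step,
        parameter=parameter,
        site=site,
    )
    series.gap_report.n_duplicates_collapsed = n_dup
    return series


def write_series(series: TimeSeries, path, metadata_path=None) -> None:
    """Write a series as two-column CSV plus an optional JSON metadata sidecar."""
    pd.DataFrame(
        {"timestamp": series.timestamps, "value": series.values}
    ).to_csv(path, index=False)
    if metadata_path is not None:
        meta = {
            "site": series.site,
            "parameter": series.parameter,
            "step_minutes": series.step_minutes,
            "n_samples": len(series),
            "gap_report": series.gap_report.to_dict(),
        }
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def regularize(
    series: TimeSeries, step_minutes: float = 15.0, max_gap_minutes: float = 60.0
) -> TimeSeries:
    """Place a series on a uniform time grid.

    Gaps of at most ``max_gap_minutes`` are filled by linear interpolation;
    longer gaps are retained as NaN markers so that windows overlapping them
    can be excluded downstream. Values at grid-aligned original timestamps are
    never altered.
    """
    if step_minutes <= 0:
        raise ConfigurationError("step_minutes must be positive")
    if len(series) == 0:
        raise EmptyInputError("cannot regularize an empty series")

    step = pd.Timedelta(minutes=step_minutes)
    grid = pd.date_range(series.timestamps[0], series.timestamps[-1], freq=step)
    s = pd.Series(series.values, index=series.timestamps)
    # snap observations to the nearest grid point, then interpolate short gaps
    on_grid = s.reindex(grid, method="nearest", tolerance=step / 2)
    missing_before = on_grid.isna()
    limit = max(int(max_gap_minutes // step_minutes), 0)
    filled = on_grid.interpolate(method="linear", limit=limit, limit_area="inside")

    # revert fills inside gaps that exceed max_gap
    gap_id = (~missing_before).cumsum()
    gap_sizes = missing_before.groupby(gap_id).transform("sum")
    too_long = missing_before & (gap_sizes * step_minutes > max_gap_minutes)
    filled[too_long] = np.nan

    n_interp = int((missing_before & filled.notna()).sum())
    n_markers = int(filled.isna().sum())
    if n_markers == len(filled):
        raise EmptyInputError("regularization produced an all-gap series")

    out = TimeSeries(
        timestamps=grid,
        values=filled.to_numpy(),
        step_minutes=step_minutes,
        parameter=series.parameter,
        site=series.site,
    )
    out.gap_report = GapReport(
        n_interpolated=n_interp,
        n_gap_markers=n_markers,
        n_duplicates_collapsed=series.gap_report.n_duplicates_collapsed,
    )
    logger.info(
        "regularize: %d interpolated, %d gap markers kept", n_interp, n_markers
    )
    return out
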