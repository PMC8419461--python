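"""Core time-series containers and CSV/JSON plumbing.

The pipeline operates on a contiguous hourly grid aligned to clock hours
(12 a.m., 1 a.m., ...). Missing data is represented by an explicit boolean
mask, never by absent rows, so spectral and filtering stages always see a
regular grid. Timestamps are timezone-naive local clock time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

HOUR = pd.Timedelta(hours=1)


class SeriesError(ValueError):
    """Raised for malformed or inconsistent series inputs."""


@dataclass
class EventRateSeries:
    """Hourly counts of machine-detected epileptiform events.

    Parameters
    ----------
    start_time : pd.Timestamp
        First clock hour of the recording (must fall exactly on an hour).
    counts : np.ndarray
        Non-negative integer event count per hour. Values at masked hours
        are carried but ignored by every statistic.
    missing : np.ndarray
        Boolean mask, True where the device recorded no data.
    """

    start_time: pd.Timestamp
    counts: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time != self.start_time.floor("h"):
            raise SeriesError(
                f"start_time {self.start_time} is not aligned to a clock hour"
            )
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise SeriesError("counts must be a non-empty 1-D sequence")
        if self.counts.shape != self.missing.shape:
            raise SeriesError("counts and missing must have identical length")
        if (self.counts < 0).any():
            bad = int(np.argmax(self.counts < 0))
            raise SeriesError(f"negative count at hour index {bad}")

    @property
    def n_hours(self) -> int:
        return int(self.counts.size)

    @property
    def end_time(self) -> pd.Timestamp:
        """One hour past the last contained hour (exclusive bound)."""
        return self.start_time + self.n_hours * HOUR

    def hours(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_hours, freq="h")

    def hour_index_of(self, timestamp) -> int:
        return hour_index_of(self, timestamp)


@dataclass
class SeizureTimes:
    """Strictly increasing electrographic seizure onset timestamps."""

    onsets: pd.DatetimeIndex

    def __post_init__(self) -> None:
        self.onsets = pd.DatetimeIndex(self.onsets)
        if len(self.onsets) > 1 and not self.onsets.is_monotonic_increasing:
            raise SeriesError("seizure onsets must be sorted increasing")
        if self.onsets.has_duplicates:
            raise SeriesError("seizure onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    def hour_indices(self, series: EventRateSeries) -> np.ndarray:
        """Clock-hour index of each onset within ``series``."""
        return np.array(
            [hour_index_of(series, t) for t in self.onsets], dtype=np.int64
        )


def hour_index_of(series: EventRateSeries, timestamp) -> int:
    """Index of the clock hour containing ``timestamp`` (floor to hour).

    Monotone non-decreasing in its timestamp argument; raises for
    timestamps outside ``[start_time, end_time)``.
    """
    ts = pd.Timestamp(timestamp)
    if ts < series.start_time or ts >= series.end_time:
        raise SeriesError(
            f"timestamp {ts} outside series span "
            f"[{series.start_time}, {series.end_time})"
        )
    return int((ts - series.start_time) // HOUR)


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_event_series(path) -> EventRateSeries:
    """Read an hourly event-rate CSV with columns timestamp,count,missing.

    The hourly grid must be contiguous; a skipped hour is rejected with an
    error naming the first missing hour (gaps are encoded with missing=1
    rows, not absent rows).
    """
    df = pd.read_csv(path)
    expected = ["timestamp", "count", "missing"]
    if list(df.columns) != expected:
        raise SeriesError(f"expected columns {expected}, got {list(df.columns)}")
    try:
        times = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesError(f"malformed timestamp in {path}: {exc}") from exc
    if len(times) == 0:
        raise SeriesError(f"{path} contains no rows")
    deltas = times.diff().dropna()
    bad = deltas[deltas != HOUR]
    if not bad.empty:
        i = bad.index[0]
        raise SeriesError(
            f"hourly grid not contiguous: expected {times[i - 1] + HOUR}, "
            f"found {times[i]}"
        )
    counts = pd.to_numeric(df["count"], errors="raise").to_numpy()
    if (counts < 0).any():
        raise SeriesError("negative count in event-rate CSV")
    return EventRateSeries(
        start_time=times.iloc[0],
        counts=counts.astype(np.int64),
        missing=df["missing"].to_numpy().astype(bool),
    )


def write_event_series(series: EventRateSeries, path) -> None:
    pd.DataFrame(
        {
            "timestamp": series.hours(),
            "count": series.counts,
            "missing": series.missing.astype(int),
        }
    ).to_csv(path, index=False)


def read_seizure_times(path) -> SeizureTimes:
    """Read seizure onset timestamps (one per row, column ``timestamp``).

    Rows are sorted; exact duplicates are dropped with a warning.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise SeriesError("seizure CSV requires a 'timestamp' column")
    try:
        onsets = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise SeriesError(f"malformed timestamp in {path}: {exc}") from exc
    onsets = onsets.sort_values()
    if onsets.has_duplicates:
        n_dup = len(onsets) - len(onsets.unique())
        warnings.warn(f"dropped {n_dup} duplicate seizure onset(s)", stacklevel=2)
        logger.warning("dropped %d duplicate seizure onsets from %s", n_dup, path)
        onsets = onsets.unique()
    return SeizureTimes(onsets=onsets)


def write_seizure_times(seizures: SeizureTimes, path) -> None:
    pd.DataFrame({"timestamp": seizures.onsets}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Tunable constants of the forecasting pipeline.

    Defaults reproduce the published operating point: an 80-tree random
    forest with minimum leaf size 15, a 14-day warm-start window,
    wavelet-peak significance at 99% confidence, seizure-cycle criteria
    SI >= 0.4 and omnibus p < 0.05, and +/-33% band-pass fractions.
    """

    initial_train_days: int = 14
    rf_trees: int = 80
    rf_min_leaf: int = 15
    significance_confidence: float = 0.99
    si_threshold: float = 0.4
    omnibus_alpha: float = 0.05
    bandpass_fraction: float = 0.33
    random_seed: int = 0
    background: str = "red"  # red (AR1) or white noise significance background
    causal_cycles: bool = False  # restrict cycle *selection* to the warm start

    def __post_init__(self) -> None:
        for name in ("initial_train_days", "rf_trees", "rf_min_leaf"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "significance_confidence",
            "si_threshold",
            "omnibus_alpha",
            "bandpass_fraction",
        ):
            v = float(getattr(self, name))
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.background not in ("red", "white"):
            raise ValueError("background must be 'red' or 'white'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Report:
    """Structured run summary: cycles found, thresholds, evaluation metrics.

    Serializes losslessly to JSON (write then read yields identical content).
    """

    cycles: list[dict[str, Any]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    metrics: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Report":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
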