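"""Heat-wave detection and the heat wave intensity index (HWII).

A heat-wave *definition* is a rule combining a temperature metric (daily
mean, maximum or minimum), a threshold (absolute degrees Celsius or an
empirical percentile of the reference record) and a minimum consecutive-day
duration. Under a resolved definition, a heat-wave *event* is a maximal run
of consecutive days whose metric exceeds the threshold, lasting at least the
minimum duration. The event's HWII is the sum of daily exceedances over the
threshold (degree-days):

    HWII = sum_{t=1..dur} (Tmetric_t - thr)

The daily exposure series assigns each event day the *total* HWII of its
covering event, and 0 to every non-event day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HWDefinition",
    "HeatWaveEvent",
    "resolve_threshold",
    "detect_events",
    "compute_hwii",
    "daily_hwii_series",
    "annual_stats",
    "crude_rate",
    "load_catalogue",
    "default_catalogue",
]

_METRIC_COLUMNS = {"mean": "tmean", "max": "tmax", "min": "tmin"}


@dataclass(frozen=True)
class HWDefinition:
    """One heat-wave definition: metric + threshold rule + minimum duration.

    ``strict_exceedance`` selects ``>`` (default, as definitions are usually
    printed) versus ``>=``. ``strict_duration`` interprets "for over N
    consecutive days" as duration > N rather than the default duration >= N.
    """

    id: str
    metric: str  # {"mean", "max", "min"}
    threshold_kind: str  # {"absolute_celsius", "percentile"}
    threshold_value: float
    min_duration: int = 1
    strict_exceedance: bool = True
    strict_duration: bool = False

    def __post_init__(self) -> None:
        if self.metric not in _METRIC_COLUMNS:
            raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}, got {self.metric!r}")
        if self.threshold_kind not in ("absolute_celsius", "percentile"):
            raise ValueError(f"unknown threshold_kind {self.threshold_kind!r}")
        if self.threshold_kind == "percentile" and not 0 < self.threshold_value < 100:
            raise ValueError(f"percentile threshold must lie in (0, 100), got {self.threshold_value}")
        if self.min_duration < 1:
            raise ValueError(f"min_duration must be >= 1, got {self.min_duration}")

    @property
    def metric_column(self) -> str:
        return _METRIC_COLUMNS[self.metric]

    @property
    def effective_min_duration(self) -> int:
        return self.min_duration + 1 if self.strict_duration else self.min_duration


@dataclass(frozen=True)
class HeatWaveEvent:
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration: int
    hwii: float
    year: int

    def __post_init__(self) -> None:
        if self.duration != (self.end_date - self.start_date).days + 1:
            raise ValueError("duration inconsistent with start/end dates")
        if self.hwii <= 0:
            raise ValueError("hwii must be strictly positive")


def _metric_values(series: pd.DataFrame, defn: HWDefinition) -> pd.Series:
    col = defn.metric_column
    if col not in series.columns:
        raise ValueError(f"series lacks required metric column {col!r}")
    values = series[col]
    if values.isna().any():
        bad = series.index[values.isna()].tolist()
        raise ValueError(f"missing {col} values on dates: {bad}")
    return values


def resolve_threshold(series: pd.DataFrame, defn: HWDefinition) -> float:
    """Resolve a definition's threshold against a reference record (deg C).

    Absolute thresholds are returned as-is; percentile thresholds are the
    linear-interpolation empirical quantile of the chosen metric over the
    *entire* reference record supplied (the reference period is an explicit
    caller choice, not an internal default).
    """
    if len(series) == 0:
        raise ValueError("cannot resolve a threshold on an empty series")
    if defn.threshold_kind == "absolute_celsius":
        return float(defn.threshold_value)
    values = _metric_values(series, defn)
    return float(np.quantile(values.to_numpy(), defn.threshold_value / 100.0))


def detect_events(
    series: pd.DataFrame,
    defn: HWDefinition,
    threshold: float | None = None,
) -> list[HeatWaveEvent]:
    """Detect heat-wave events: maximal qualifying runs of consecutive days.

    ``series`` must carry a DatetimeIndex of consecutive calendar days and
    the definition's metric column. Missing values are a hard error (a gap
    would silently split or merge runs). Events are chronologically ordered,
    non-overlapping and assigned to the calendar year of their start day.
    """
    if len(series) == 0:
        return []
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by calendar date")
    gaps = np.diff(series.index.to_numpy()) != np.timedelta64(1, "D")
    if gaps.any():
        raise ValueError("series has calendar gaps; detection requires consecutive days")
    if threshold is None:
        threshold = resolve_threshold(series, defn)
    values = _metric_values(series, defn).to_numpy(dtype=float)
    if defn.strict_exceedance:
        hot = values > threshold
    else:
        hot = values >= threshold

    events: list[HeatWaveEvent] = []
    min_dur = defn.effective_min_duration
    n = len(values)
    i = 0
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        dur = j - i + 1
        if dur >= min_dur:
            hwii = float(np.sum(values[i : j + 1] - threshold))
            start = series.index[i]
            end = series.index[j]
            events.append(
                HeatWaveEvent(
                    start_date=start,
                    end_date=end,
                    duration=dur,
                    hwii=hwii,
                    year=int(start.year),
                )
            )
        i = j + 1
    return events


def compute_hwii(event: HeatWaveEvent, series: pd.DataFrame, defn: HWDefinition, threshold: float) -> float:
    """Re-derive an event's HWII by direct per-day summation (degree-days)."""
    window = series.loc[event.start_date : event.end_date]
    if len(window) != event.duration:
        raise ValueError("event window not fully covered by the series")
    values = _metric_values(window, defn).to_numpy(dtype=float)
    hwii = float(np.sum(values - threshold))
    if hwii <= 0:
        raise ValueError("HWII must be strictly positive for a valid event")
    return hwii


def daily_hwii_series(series: pd.DataFrame, events: list[HeatWaveEvent]) -> pd.Series:
    """Daily HWII exposure: the covering event's total HWII on its days, else 0."""
    out = pd.Series(0.0, index=series.index, name="hwii")
    for ev in events:
        out.loc[ev.start_date : ev.end_date] = ev.hwii
    return out


def annual_stats(events: list[HeatWaveEvent], period: tuple[int, int]) -> tuple[pd.Series, np.ndarray]:
    """Per-year event counts over ``period`` (inclusive; zero years kept) and
    the pooled list of event intensities."""
    first, last = period
    if last < first:
        raise ValueError("period end precedes period start")
    years = np.arange(first, last + 1)
    counts = pd.Series(0, index=years, name="n_events")
    for ev in events:
        if first <= ev.year <= last:
            counts.loc[ev.year] += 1
    intensities = np.array([ev.hwii for ev in events if first <= ev.year <= last])
    return counts, intensities


def crude_rate(deaths, population):
    """Crude mortality rate: deaths divided by resident population (Eq. of
    record: deaths per person per day when applied to daily counts)."""
    deaths = np.asarray(deaths, dtype=float)
    pop = np.asarray(population, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be positive")
    if np.any(deaths < 0):
        raise ValueError("death counts must be non-negative")
    return deaths / pop


def load_catalogue(path) -> list[HWDefinition]:
    """Load a YAML catalogue of heat-wave definitions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [HWDefinition(**entry) for entry in raw]


def default_catalogue() -> list[HWDefinition]:
    """The packaged 16-definition catalogue spanning the mean/max/min metrics,
    absolute and percentile thresholds, and 2-4 day minimum durations."""
    ref = resources.files("heatrisk.data").joinpath("hw_catalogue.yaml")
    raw = yaml.safe_load(ref.read_text())
    return [HWDefinition(**entry) for entry in raw]
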