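"""Synthetic area-day datasets with known hazard and vulnerability truth.

The generator emulates the structure of a single surveillance area: a daily
weather record (seasonal temperature cycle with AR(1) noise plus injected
hot spells), confounded non-accidental death counts for two age groups
(0-64, 65+), relative humidity, an air-pollution index and a holiday flag.
Hot spells are injected explicitly — rather than emerging from the noise —
so the ground-truth heat-wave calendar is known and parameter-recovery
tests can be exact.

Mortality follows a Poisson count model whose rate rises with the heat-wave
intensity index (HWII) of the covering event, distributed over lags 0-3:

    deaths_g(t) ~ Poisson(P * share_g * rate_g(t))
    rate_g(t)   = baseline_g * dow * holiday * trend * (1 + season)
                  + sum_l lag_weights[l] * vuln_g(HWII_{t-l})

where ``vuln_g`` is the injected vulnerability function (linear, quadratic
or hockey-stick in HWII) and ``HWII_t`` is the daily exposure series of the
truth heat-wave definition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .detection import HWDefinition, daily_hwii_series, detect_events, resolve_threshold

__all__ = [
    "VulnTruth",
    "SimConfig",
    "SyntheticDataset",
    "demo_config",
    "holiday_indicator",
    "generate_temperature",
    "generate_mortality",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

AGE_GROUPS = ("0_64", "65plus")

# mid-July peak of the seasonal temperature cycle; mid-January mortality peak
_TEMP_PEAK_DOY = 196
_MORT_PEAK_DOY = 15


@dataclass(frozen=True)
class VulnTruth:
    """Ground-truth vulnerability: excess per-person-day death rate as a
    function of event HWII (degree-days).

    kind "linear":   slope * h
    kind "quadratic": slope * h**2
    kind "hockey":   slope * max(h - breakpoint, 0)
    """

    kind: str = "linear"
    slope: float = 0.0
    breakpoint: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic", "hockey"):
            raise ValueError(f"vuln_truth.kind must be linear/quadratic/hockey, got {self.kind!r}")
        if self.slope < 0:
            raise ValueError("vuln_truth.slope must be non-negative")

    def __call__(self, hwii) -> np.ndarray:
        h = np.asarray(hwii, dtype=float)
        if self.kind == "linear":
            return self.slope * h
        if self.kind == "quadratic":
            return self.slope * h**2
        return self.slope * np.clip(h - self.breakpoint, 0.0, None)


def _default_truth() -> tuple[VulnTruth, VulnTruth]:
    return (VulnTruth("linear", 5e-7), VulnTruth("linear", 1.0e-5))


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic area.

    Rates are per person-day; temperatures in Celsius; `lag_weights` are the
    shares of the injected excess realised at lags 0..3 and must sum to 1.
    """

    n_years: int = 6
    start_year: int = 2007
    # weather
    t_mean_annual: float = 17.0
    t_seasonal_amplitude: float = 10.5
    ar1_coef: float = 0.7
    noise_sd: float = 1.2  # innovation SD of the AR(1) term
    spell_rate: float = 2.0  # expected injected hot spells per year
    spell_excess: float = 4.0
    spell_duration_mean: float = 4.0
    diurnal_half_range: float = 4.5
    rh_mean: float = 74.0
    rh_sd: float = 12.0
    # mortality
    baseline_rate: tuple[float, float] = (4e-6, 1.4e-4)
    dow_effects: tuple[float, ...] = (1.00, 0.99, 0.98, 0.98, 0.99, 1.01, 1.02)
    holiday_effect: float = 1.05
    trend_slope: float = 0.005  # multiplicative drift per year
    season_amplitude: float = 0.10  # winter-peaking mortality seasonality
    vuln_truth: tuple[VulnTruth, VulnTruth] = field(default_factory=_default_truth)
    lag_weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    # population
    population: int = 650_000
    age_shares: tuple[float, float] = (0.85, 0.15)
    # truth heat-wave definition driving the injected vulnerability
    truth_definition: HWDefinition = field(
        default_factory=lambda: HWDefinition(
            id="truth", metric="max", threshold_kind="absolute_celsius",
            threshold_value=35.0, min_duration=3,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError(f"ar1_coef must lie in [0, 1), got {self.ar1_coef}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.spell_rate < 0:
            raise ValueError("spell_rate must be non-negative")
        if self.spell_duration_mean < 1:
            raise ValueError("spell_duration_mean must be >= 1 day")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if len(self.lag_weights) != 4:
            raise ValueError("lag_weights must have 4 entries (lags 0..3)")
        if any(w < 0 for w in self.lag_weights):
            raise ValueError("lag_weights must be non-negative")
        if abs(sum(self.lag_weights) - 1.0) > 1e-12:
            raise ValueError("lag_weights must sum to 1")
        if abs(sum(self.age_shares) - 1.0) > 1e-12:
            raise ValueError("age_shares must sum to 1")
        if any(not 0 < s < 1 for s in self.age_shares):
            raise ValueError("age_shares must lie in (0, 1)")
        if self.population <= 0:
            raise ValueError("population must be positive")
        if any(b < 0 for b in self.baseline_rate):
            raise ValueError("baseline_rate must be non-negative")


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """The packaged demo configuration (single subtropical-like area)."""
    return replace(SimConfig(seed=seed), **overrides)


def holiday_indicator(dates: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic pseudo-holiday calendar: New Year (Jan 1-3), Labour
    week (May 1-3) and National week (Oct 1-7)."""
    m, d = dates.month, dates.day
    hol = ((m == 1) & (d <= 3)) | ((m == 5) & (d <= 3)) | ((m == 10) & (d <= 7))
    return hol.astype(int).to_numpy() if hasattr(hol, "to_numpy") else np.asarray(hol, dtype=int)


def _dates(cfg: SimConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=cfg.start_year, month=1, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.n_years - 1, month=12, day=31)
    return pd.date_range(start, end, freq="D")


def generate_temperature(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[dict]]:
    """Daily tmean/tmax/tmin: sinusoid peaking mid-July + AR(1) noise +
    injected hot spells (Poisson count per year, geometric durations).

    Returns the temperature frame and the realised spell calendar.
    """
    dates = _dates(cfg)
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.t_mean_annual + cfg.t_seasonal_amplitude * np.cos(
        2 * np.pi * (doy - _TEMP_PEAK_DOY) / 365.25
    )

    eps = rng.normal(0.0, cfg.noise_sd, size=n)
    noise = lfilter([1.0], [1.0, -cfg.ar1_coef], eps)

    spell_excess = np.zeros(n)
    spells: list[dict] = []
    year_index = dates.year.to_numpy()
    for year in range(cfg.start_year, cfg.start_year + cfg.n_years):
        n_spells = rng.poisson(cfg.spell_rate)
        year_start = int(np.searchsorted(year_index, year))
        for _ in range(n_spells):
            start_doy = int(rng.integers(166, 236))  # mid-June .. late August
            dur = int(rng.geometric(1.0 / cfg.spell_duration_mean))
            i0 = year_start + start_doy - 1
            i1 = min(i0 + dur, n)
            if i0 >= n:
                continue
            spell_excess[i0:i1] = cfg.spell_excess  # overlaps apply once
            spells.append(
                {"start": str(dates[i0].date()), "duration": int(i1 - i0)}
            )

    tmean = seasonal + noise + spell_excess
    frame = pd.DataFrame(
        {
            "tmean": tmean,
            "tmax": tmean + cfg.diurnal_half_range,
            "tmin": tmean - cfg.diurnal_half_range,
        },
        index=dates,
    )
    return frame, spells


def _baseline_rates(cfg: SimConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    """Confounded baseline rate per group, shape (n_days, 2)."""
    doy = dates.dayofyear.to_numpy()
    dow = dates.dayofweek.to_numpy()  # Monday=0
    hol = holiday_indicator(dates)
    years_elapsed = (dates.year - cfg.start_year).to_numpy(dtype=float)

    dowf = np.asarray(cfg.dow_effects)[dow]
    holf = np.where(hol == 1, cfg.holiday_effect, 1.0)
    trendf = (1.0 + cfg.trend_slope) ** years_elapsed
    seasonf = 1.0 + cfg.season_amplitude * np.cos(
        2 * np.pi * (doy - _MORT_PEAK_DOY) / 365.25
    )
    shared = dowf * holf * trendf * seasonf
    return np.outer(shared, np.asarray(cfg.baseline_rate))


def expected_rates(cfg: SimConfig, tseries: pd.DataFrame, hw_events) -> pd.DataFrame:
    """Noise-free expected per-person-day death rate per age group, including
    the lag-distributed HWII excess. Exposed for closed-form oracle tests."""
    dates = tseries.index
    rates = _baseline_rates(cfg, dates)
    hwii = daily_hwii_series(tseries, hw_events).to_numpy()
    for g, truth in enumerate(cfg.vuln_truth):
        excess = np.zeros(len(dates))
        for lag, w in enumerate(cfg.lag_weights):
            if w == 0:
                continue
            shifted = np.concatenate([np.zeros(lag), hwii[: len(hwii) - lag]])
            excess += w * truth(shifted)
        rates[:, g] = rates[:, g] + excess
    if np.any(rates < 0):
        warnings.warn("negative expected rates clipped to 0", RuntimeWarning)
        rates = np.clip(rates, 0.0, None)
    return pd.DataFrame(rates, index=dates, columns=list(AGE_GROUPS))


def generate_mortality(
    cfg: SimConfig,
    tseries: pd.DataFrame,
    hw_events,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson death counts per age group given the weather and the truth
    heat-wave events (detected from ``tseries`` under the truth definition)."""
    rates = expected_rates(cfg, tseries, hw_events)
    means = rates.to_numpy() * cfg.population * np.asarray(cfg.age_shares)
    counts = rng.poisson(means)
    return pd.DataFrame(
        counts, index=tseries.index, columns=[f"deaths_{g}" for g in AGE_GROUPS]
    )


@dataclass
class SyntheticDataset:
    """One synthetic area: the daily records plus the generating truth."""

    records: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        idx = self.records.index
        if len(idx) > 1 and (np.diff(idx.to_numpy()) != np.timedelta64(1, "D")).any():
            raise ValueError("records must be consecutive calendar days")


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Compose weather, confounders and mortality into one area dataset."""
    rng = np.random.default_rng(cfg.seed)
    tseries, spells = generate_temperature(cfg, rng)
    dates = tseries.index

    threshold = resolve_threshold(tseries, cfg.truth_definition)
    events = detect_events(tseries, cfg.truth_definition, threshold=threshold)

    rh = np.clip(rng.normal(cfg.rh_mean, cfg.rh_sd, size=len(dates)), 0.0, 100.0)
    doy = dates.dayofyear.to_numpy()
    api = np.clip(
        60 + 25 * np.cos(2 * np.pi * (doy - _MORT_PEAK_DOY) / 365.25)
        + rng.normal(0, 10, size=len(dates)),
        5.0,
        300.0,
    )
    deaths = generate_mortality(cfg, tseries, events, rng)

    records = pd.DataFrame(index=dates)
    records.index.name = "date"
    records["tmax"] = tseries["tmax"]
    records["tmean"] = tseries["tmean"]
    records["tmin"] = tseries["tmin"]
    records["rh"] = rh
    records["api"] = api
    records["holiday"] = holiday_indicator(dates)
    for g in AGE_GROUPS:
        records[f"deaths_{g}"] = deaths[f"deaths_{g}"]
    records["population"] = cfg.population

    truth = {
        "config": _config_dict(cfg),
        "spells": spells,
        "truth_threshold": threshold,
        "truth_events": [
            {
                "start": str(ev.start_date.date()),
                "end": str(ev.end_date.date()),
                "duration": ev.duration,
                "hwii": ev.hwii,
                "year": ev.year,
            }
            for ev in events
        ],
    }
    return SyntheticDataset(records=records, truth=truth)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["truth_definition"] = asdict(cfg.truth_definition)
    d["vuln_truth"] = [asdict(v) for v in cfg.vuln_truth]
    return d


def write_dataset(ds: SyntheticDataset, csv_path, truth_path=None) -> None:
    """Write the area CSV (ISO-8601 dates) and the JSON truth sidecar."""
    ds.records.to_csv(csv_path, date_format="%Y-%m-%d", float_format="%.6f")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(ds.truth, fh, indent=1)


def read_dataset(csv_path) -> pd.DataFrame:
    """Read an area CSV back into a date-indexed frame."""
    df = pd.read_csv(csv_path, parse_dates=["date"], index_col="date")
    return df
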