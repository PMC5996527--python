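"""Event-based Monte Carlo heat-wave risk assessment.

Annual losses are simulated by compounding the fitted hazard (Poisson
annual event counts, Gamma event intensities) through the vulnerability
curves: each simulated event contributes the curve's cumulative excess
crude mortality rate at its HWII, floored at zero, once per event. Losses
are expressed as deaths per million persons per year. From the simulated
annual losses the module derives the empirical exceedance-probability (EP)
curve, the average annual loss (AAL) and the probable maximum loss (PML)
at given return periods, per vulnerability band (lower / central / upper
95% CI envelope) with common random numbers across bands.

Crude rates (group deaths over *total* population, CMR) convert to
age-specific rates (group deaths over *group* population, ASMR) by
dividing by the group's population share; the inverse reconstitutes the
crude loss as the share-weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import HWDefinition, annual_stats, detect_events
from .dlnm import VulnerabilityCurve
from .hazard import FrequencyModel, IntensityModel, fit_gamma, fit_poisson

__all__ = [
    "AgeStructure",
    "RiskResult",
    "event_loss",
    "simulate_losses",
    "ep_curve",
    "ep_integral",
    "aal",
    "pml",
    "cmr_to_asmr",
    "asmr_to_cmr",
    "project_future",
]

PER_MILLION = 1e6
BANDS = ("lower", "central", "upper")


@dataclass(frozen=True)
class AgeStructure:
    """Population shares per age group (must sum to 1)."""

    shares: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        vals = list(self.shares.values())
        if any(not 0 < s < 1 for s in vals):
            raise ValueError("shares must lie in (0, 1)")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError(f"shares must sum to 1, got {sum(vals)}")


@dataclass
class RiskResult:
    """Simulated annual losses and derived risk metrics for one age group.

    ``annual_losses[band]`` holds n_sim_years losses in deaths per million
    per year; ``metric_kind`` is CMR (per million total population) or ASMR
    (per million group population).
    """

    annual_losses: dict[str, np.ndarray]
    aal: dict[str, float]
    pml: dict[int, dict[str, float]]
    age_group: str
    metric_kind: str = "CMR"
    n_sim_years: int = 0
    seed: int | None = None

    def ep(self, band: str = "central") -> tuple[np.ndarray, np.ndarray]:
        return ep_curve(self.annual_losses[band])


def event_loss(hwii, curve: VulnerabilityCurve, band: str = "central") -> np.ndarray:
    """Excess crude-rate loss per event at intensity ``hwii`` (per person).

    The selected band is interpolated linearly on the curve grid; beyond the
    observed range it extrapolates with the boundary-segment slope (natural
    splines are linear outside their boundary knots). Negative values —
    sampling noise around the minimum-mortality center — are floored at 0.
    """
    h = np.atleast_1d(np.asarray(hwii, dtype=float))
    if np.any(h <= 0):
        raise ValueError("event HWII must be strictly positive")
    g, y = curve.grid, curve.band(band)
    out = np.interp(h, g, y)
    if len(g) >= 2:
        left = h < g[0]
        right = h > g[-1]
        out[left] = y[0] + (h[left] - g[0]) * (y[1] - y[0]) / (g[1] - g[0])
        out[right] = y[-1] + (h[right] - g[-1]) * (y[-1] - y[-2]) / (g[-1] - g[-2])
    return np.clip(out, 0.0, None)


def simulate_losses(
    freq: FrequencyModel,
    intens: IntensityModel,
    curves: dict[str, VulnerabilityCurve],
    n_years: int = 10_000,
    seed: int | None = None,
    return_periods: tuple[int, ...] = (50, 100),
) -> dict[str, RiskResult]:
    """Monte Carlo simulation of ``n_years`` of heat-wave seasons.

    One common event stream (annual Poisson counts, Gamma intensities) is
    shared by every age group and vulnerability band, so bands are ordered
    and cross-group aggregation is exact.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(freq.lam, size=n_years)
    total = int(counts.sum())
    intensities = rng.gamma(intens.shape, intens.scale, size=total)
    year_of_event = np.repeat(np.arange(n_years), counts)

    results: dict[str, RiskResult] = {}
    for group, curve in curves.items():
        losses = {}
        for band in BANDS:
            if total:
                per_event = event_loss(intensities, curve, band) * PER_MILLION
                annual = np.bincount(year_of_event, weights=per_event,
                                     minlength=n_years)
            else:
                annual = np.zeros(n_years)
            losses[band] = annual
        results[group] = RiskResult(
            annual_losses=losses,
            aal={b: aal(losses[b]) for b in BANDS},
            pml={T: {b: pml(losses[b], T) for b in BANDS} for T in return_periods},
            age_group=group,
            metric_kind="CMR",
            n_sim_years=n_years,
            seed=seed,
        )
    return results


def ep_curve(annual_losses) -> tuple[np.ndarray, np.ndarray]:
    """Empirical exceedance probabilities at the sorted unique losses:
    EP(x) = #{years with loss > x} / n_years (non-increasing in x)."""
    x = np.asarray(annual_losses, dtype=float)
    levels = np.unique(x)
    ep = np.array([np.mean(x > lv) for lv in levels])
    return levels, ep


def ep_integral(levels, ep, low: float = 0.0) -> float:
    """Exact integral of the EP step function from ``low`` to max loss.

    EP is right-continuous and piecewise constant: EP(x) = ep[k] on
    [levels[k], levels[k+1]). For non-negative losses the integral from 0
    equals the mean annual loss."""
    levels = np.asarray(levels, dtype=float)
    ep = np.asarray(ep, dtype=float)
    total = (levels[0] - low) * 1.0 if levels.size else 0.0
    widths = np.diff(levels)
    total += float(np.sum(widths * ep[:-1]))
    return total


def aal(annual_losses) -> float:
    """Average annual loss: the arithmetic mean of simulated annual losses."""
    return float(np.mean(np.asarray(annual_losses, dtype=float)))


def pml(annual_losses, return_period: float) -> float:
    """Probable maximum loss at return period T: the smallest simulated
    loss level x whose exceedance probability is at most 1/T (the lower
    limit on the loss at that probability; the empirical (1 - 1/T)
    quantile under the lower-limit convention)."""
    if return_period < 1:
        raise ValueError("return_period must be >= 1")
    x = np.sort(np.asarray(annual_losses, dtype=float))
    n = x.size
    k = int(np.ceil(n * (1.0 - 1.0 / return_period)))  # 1-indexed order stat
    k = min(max(k, 1), n)
    return float(x[k - 1])


def cmr_to_asmr(group_cmr_loss, structure: AgeStructure, group: str):
    """Convert a crude-scale loss of one group (group deaths per total
    population) to the age-specific scale (group deaths per group
    population)."""
    share = structure.shares[group]
    return np.asarray(group_cmr_loss, dtype=float) / share


def asmr_to_cmr(group_asmr_loss, structure: AgeStructure, group: str):
    share = structure.shares[group]
    return np.asarray(group_asmr_loss, dtype=float) * share


def asmr_results(
    results: dict[str, RiskResult], structure: AgeStructure
) -> dict[str, RiskResult]:
    """Re-express per-group CMR results on the ASMR scale."""
    out = {}
    for group, res in results.items():
        losses = {b: cmr_to_asmr(res.annual_losses[b], structure, group)
                  for b in BANDS}
        out[group] = RiskResult(
            annual_losses=losses,
            aal={b: aal(losses[b]) for b in BANDS},
            pml={T: {b: pml(losses[b], T) for b in BANDS} for T in res.pml},
            age_group=group,
            metric_kind="ASMR",
            n_sim_years=res.n_sim_years,
            seed=res.seed,
        )
    return out


def crude_total(results: dict[str, RiskResult]) -> RiskResult:
    """Aggregate the per-group CMR losses into the all-ages crude loss
    (exact under the common event stream)."""
    groups = list(results)
    n = results[groups[0]].n_sim_years
    losses = {
        b: np.sum([results[g].annual_losses[b] for g in groups], axis=0)
        for b in BANDS
    }
    rps = list(results[groups[0]].pml)
    return RiskResult(
        annual_losses=losses,
        aal={b: aal(losses[b]) for b in BANDS},
        pml={T: {b: pml(losses[b], T) for b in BANDS} for T in rps},
        age_group="all",
        metric_kind="CMR",
        n_sim_years=n,
        seed=results[groups[0]].seed,
    )


def project_future(
    curves: dict[str, VulnerabilityCurve],
    future_structure: AgeStructure,
    n_years: int = 10_000,
    seed: int | None = None,
    future_series=None,
    definition: HWDefinition | None = None,
    historical_threshold: float | None = None,
    period: tuple[int, int] | None = None,
    hazard_params: tuple[float, float, float] | None = None,
    return_periods: tuple[int, ...] = (50, 100),
) -> dict[str, dict[str, RiskResult]]:
    """Future-scenario risk: new hazard, unchanged vulnerability, new age
    structure.

    The future hazard comes either from a future daily series — events are
    re-detected with the *historical* resolved threshold, then the Poisson
    and Gamma models are refitted — or directly as (lambda, shape, scale).
    The vulnerability curves are held at their baseline estimates and
    losses are converted with the future age structure.

    Returns ``{"cmr": per-group CMR results, "asmr": per-group ASMR
    results}``.
    """
    if (future_series is None) == (hazard_params is None):
        raise ValueError("supply exactly one of future_series or hazard_params")
    if future_series is not None:
        if definition is None or historical_threshold is None:
            raise ValueError("future_series requires the definition and its "
                             "historical resolved threshold")
        events = detect_events(future_series, definition,
                               threshold=historical_threshold)
        if period is None:
            years = future_series.index.year
            period = (int(years.min()), int(years.max()))
        counts, intensities = annual_stats(events, period)
        freq = fit_poisson(counts.to_numpy())
        if intensities.size >= 3:
            intens = fit_gamma(intensities)
        else:
            raise ValueError("future series yields too few events to fit a Gamma")
    else:
        lam, shape, scale = hazard_params
        freq = FrequencyModel(lam=lam, n_years=0)
        intens = IntensityModel(shape=shape, scale=scale, n_events=0)

    cmr = simulate_losses(freq, intens, curves, n_years=n_years, seed=seed,
                          return_periods=return_periods)
    return {"cmr": cmr, "asmr": asmr_results(cmr, future_structure)}
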