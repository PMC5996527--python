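"""Frequency-severity hazard model for heat-wave events.

Annual event counts are modelled as Poisson (lambda = mean count over the
reference period, zero-count years included); event intensities (HWII,
degree-days) as Gamma. The Gamma fit is maximum likelihood: the shape
solves the profile score equation

    log(shape) - digamma(shape) = log(mean(x)) - mean(log(x))

by Newton iteration from the method-of-moments start, with
scale = mean / shape. A method-of-moments fit is available for comparison.
Goodness of fit uses a Pearson chi-square on equal-probability bins under
the fitted model, merged until every expected count is at least 5, with
dof = bins - 1 - number of fitted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "FrequencyModel",
    "IntensityModel",
    "GOFResult",
    "fit_poisson",
    "fit_gamma",
    "gof_chisq",
    "sample_year",
]


@dataclass(frozen=True)
class FrequencyModel:
    lam: float  # events per year
    n_years: int

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")


@dataclass(frozen=True)
class IntensityModel:
    shape: float
    scale: float  # degree-days
    n_events: int
    method: str = "mle"

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class GOFResult:
    statistic: float
    dof: int
    p_value: float
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    passed: bool


def fit_poisson(annual_counts) -> FrequencyModel:
    """Poisson MLE: lambda is the arithmetic mean of the annual counts
    (zero-count years count toward the denominator)."""
    counts = np.asarray(annual_counts)
    if counts.size == 0:
        raise ValueError("need at least one year of counts")
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("annual counts must be non-negative integers")
    lam = float(np.mean(counts))
    if lam == 0:
        warnings.warn("all annual counts are zero; frequency model is degenerate",
                      RuntimeWarning)
    return FrequencyModel(lam=lam, n_years=int(counts.size))


def gamma_mom(intensities) -> tuple[float, float]:
    """Method-of-moments Gamma estimates (mean^2/var, var/mean)."""
    x = np.asarray(intensities, dtype=float)
    m, v = float(np.mean(x)), float(np.var(x))
    if v <= 0:
        raise ValueError("zero-variance sample has no moment-matched Gamma")
    return m * m / v, v / m


def fit_gamma(intensities, method: str = "mle", max_iter: int = 100,
              tol: float = 1e-10) -> IntensityModel:
    """Gamma fit to event intensities.

    MLE (default): Newton iteration on the profile log-likelihood score for
    the shape, started at the method-of-moments estimate; the scale is
    mean/shape. Near-constant samples, whose MoM shape is enormous and whose
    score equation is numerically flat, are returned at the moment-matched
    point (shape -> infinity limit preserves the mean).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intensities to fit a Gamma")
    if np.any(x <= 0):
        raise ValueError("all intensities must be strictly positive")
    if method not in ("mle", "mom"):
        raise ValueError(f"unknown method {method!r}")

    mean_x = float(np.mean(x))
    if np.ptp(x) == 0:
        warnings.warn("constant intensities: returning a near-degenerate Gamma",
                      RuntimeWarning)
        shape = 1e8
        return IntensityModel(shape=shape, scale=mean_x / shape,
                              n_events=int(x.size), method=method)

    shape0, scale0 = gamma_mom(x)
    if method == "mom":
        return IntensityModel(shape=shape0, scale=scale0, n_events=int(x.size),
                              method="mom")

    # profile score: f(a) = log(a) - digamma(a) - (log(mean) - mean(log x))
    c = np.log(mean_x) - float(np.mean(np.log(x)))
    a = shape0
    for _ in range(max_iter):
        f = np.log(a) - special.digamma(a) - c
        fprime = 1.0 / a - special.polygamma(1, a)
        step = f / fprime
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < tol * max(1.0, a):
            a = a_new
            break
        a = a_new
    else:
        raise RuntimeError(
            f"Gamma MLE did not converge in {max_iter} iterations; last shape={a}"
        )
    return IntensityModel(shape=float(a), scale=mean_x / float(a),
                          n_events=int(x.size), method="mle")


def _poisson_bins(lam: float, n: int) -> tuple[list[tuple[int, float]], np.ndarray]:
    """Group integer support into consecutive bins with expected >= 5."""
    upper = int(stats.poisson.ppf(1 - 1e-10, lam)) + 1 if lam > 0 else 1
    pmf = stats.poisson.pmf(np.arange(upper + 1), lam)
    edges = [0]
    probs = []
    acc = 0.0
    for k in range(upper + 1):
        acc += pmf[k]
        if acc * n >= 5.0:
            edges.append(k + 1)
            probs.append(acc)
            acc = 0.0
    # sweep the tail (including P(X > upper)) into the last bin
    tail = 1.0 - float(np.sum(probs))
    if probs:
        probs[-1] += tail
        edges[-1] = np.inf
    else:
        probs = [1.0]
        edges = [0, np.inf]
    return list(zip(edges[:-1], probs)), np.asarray(edges, dtype=float)


def gof_chisq(model, data, alpha: float = 0.01, n_params: int | None = None) -> GOFResult:
    """Pearson chi-square goodness of fit with equal-probability binning.

    Continuous (Gamma) models: bin edges at model quantiles of equal
    probability, starting from ``min(15, n // 10)`` bins, merged until every
    expected count is >= 5. Discrete (Poisson) models: consecutive integer
    bins grouped until expected >= 5. Pass iff p_value > alpha.
    """
    x = np.asarray(data, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations for a chi-square GOF")

    if isinstance(model, FrequencyModel):
        n_params = 1 if n_params is None else n_params
        bins, edges = _poisson_bins(model.lam, n)
        probs = np.array([p for _, p in bins])
        cdf_edges = np.concatenate([[ -0.5], edges[1:] - 0.5])
        observed, _ = np.histogram(x, bins=cdf_edges)
    elif isinstance(model, IntensityModel):
        n_params = 2 if n_params is None else n_params
        k = max(4, min(15, n // 10))
        qs = np.linspace(0, 1, k + 1)
        edges = stats.gamma.ppf(qs, a=model.shape, scale=model.scale)
        edges[0], edges[-1] = -np.inf, np.inf
        probs = np.full(k, 1.0 / k)
        observed, _ = np.histogram(x, bins=np.nan_to_num(edges, neginf=-1e300, posinf=1e300))
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")

    expected = probs * n
    observed, expected, probs = _merge_small_bins(observed, expected, probs)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    dof = len(observed) - 1 - n_params
    if dof < 1:
        warnings.warn("too few bins for the fitted parameters; GOF dof floored at 1",
                      RuntimeWarning)
        dof = 1
    p = float(stats.chi2.sf(stat, dof))
    return GOFResult(
        statistic=stat, dof=dof, p_value=p,
        bin_edges=np.asarray(edges), observed=observed, expected=expected,
        passed=bool(p > alpha),
    )


def _merge_small_bins(observed, expected, probs):
    """Merge adjacent bins (left to right) until every expected >= 5."""
    obs, exp = list(observed), list(expected)
    i = 0
    while i < len(exp):
        if exp[i] < 5.0 and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            if j < i:
                i = j
        else:
            i += 1
    return np.asarray(obs, dtype=float), np.asarray(exp, dtype=float), None


def sample_year(
    freq: FrequencyModel, intens: IntensityModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw one simulated year: N ~ Poisson(lambda) event intensities,
    i.i.d. Gamma(shape, scale)."""
    n = rng.poisson(freq.lam)
    if n == 0:
        return np.empty(0)
    return rng.gamma(intens.shape, intens.scale, size=n)
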