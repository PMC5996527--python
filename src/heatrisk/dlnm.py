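"""Distributed lag non-linear model (DLNM) for the HWII-mortality relation.

The exposure-lag-response surface is modelled through a *cross-basis*: the
tensor product of a natural cubic spline basis in the exposure dimension
(the daily heat-wave intensity index, HWII) and a basis in the lag
dimension. The cross-basis enters an ordinary least-squares regression of
the daily crude mortality rate alongside the confounders: daily mean
temperature, relative humidity, a linear time trend, day-of-week indicators
and a holiday flag:

    Yr_t = alpha + cb(HWII_t, lag) + b1*Tmean_t + b2*Rh_t + b3*Time_t
           + b4*Dow_t + b5*Holiday_t

Defaults follow the epidemiological convention for acute heat effects:
2 basis dimensions for HWII, 3 for lag, maximum lag 3 days. The exposure
basis is *centered* at the minimum-mortality HWII so the cumulative curve
is an excess rate relative to that reference intensity.

Basis conventions
-----------------
* Exposure (var) dimension: natural cubic spline with ``df_var`` columns,
  intercept excluded; boundary knots at the observed HWII min/max, interior
  knots at equally spaced quantiles of the *positive* (event-day) values.
* Lag dimension: dimension ``df_lag`` made of a constant column plus a
  natural cubic spline of dimension ``df_lag - 1`` with knots equally
  spaced on ``[0, max_lag]``. The constant column lets a uniform lag
  profile be represented; with ``df_lag = 1`` the cross-basis reduces to a
  moving sum of the exposure basis over the lag window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detection import HWDefinition, daily_hwii_series, detect_events, resolve_threshold
from .splines import natural_spline_basis

__all__ = [
    "CrossBasisSpec",
    "CrossBasis",
    "DLNMFit",
    "VulnerabilityCurve",
    "lag_basis",
    "build_crossbasis",
    "fit_dlnm",
    "find_center",
    "cumulative_curve",
    "fit_vulnerability",
    "select_definition",
    "sensitivity_sweep",
    "percentile_axis",
]


@dataclass(frozen=True)
class CrossBasisSpec:
    df_var: int = 2
    df_lag: int = 3
    max_lag: int = 3
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.df_var < 1:
            raise ValueError("df_var must be >= 1")
        if self.df_lag < 1:
            raise ValueError("df_lag must be >= 1")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.max_lag == 0 and self.df_lag != 1:
            raise ValueError("max_lag=0 admits only df_lag=1")


def lag_basis(max_lag: int, df_lag: int) -> np.ndarray:
    """Basis over integer lags 0..max_lag, shape (max_lag+1, df_lag):
    a constant column plus a natural spline of dimension df_lag-1."""
    lags = np.arange(max_lag + 1, dtype=float)
    if df_lag == 1:
        return np.ones((max_lag + 1, 1))
    if df_lag > max_lag + 1:
        raise ValueError(f"df_lag={df_lag} exceeds the {max_lag + 1} lag points")
    knots = np.linspace(0.0, float(max_lag), df_lag)
    ns = natural_spline_basis(lags, knots)
    return np.column_stack([np.ones(max_lag + 1), ns])


def _var_knots(hwii: np.ndarray, df_var: int) -> np.ndarray:
    """Boundary knots at observed min/max; interior at equally spaced
    quantiles of the positive (event-day) HWII values."""
    lo, hi = float(np.min(hwii)), float(np.max(hwii))
    if hi <= lo:  # degenerate (e.g. all-zero exposure): any increasing knots do
        return np.linspace(lo, lo + 1.0, df_var + 1)
    if df_var == 1:
        return np.array([lo, hi])
    pos = np.unique(hwii[hwii > 0])
    if pos.size == 0:
        pos = np.unique(hwii)
    probs = np.linspace(0, 1, df_var + 1)[1:-1]
    interior = np.atleast_1d(np.quantile(pos, probs))
    knots = np.concatenate([[lo], interior, [hi]])
    if np.any(np.diff(knots) <= 0):
        # too few distinct event intensities for quantile placement:
        # fall back to equally spaced knots on the observed range
        knots = np.linspace(lo, hi, df_var + 1)
    return knots


@dataclass
class CrossBasis:
    """A built cross-basis: the design block plus everything needed to
    re-evaluate predictions (knots, center, lag basis)."""

    matrix: np.ndarray  # (n_days, df_var * df_lag)
    spec: CrossBasisSpec
    var_knots: np.ndarray
    lag_matrix: np.ndarray  # (max_lag+1, df_lag)
    valid: np.ndarray  # False on the first max_lag rows (incomplete window)
    observed_range: tuple[float, float]
    positive_min: float  # smallest positive exposure (= obs max if none)

    def var_basis_centered(self, x) -> np.ndarray:
        b = natural_spline_basis(np.atleast_1d(x), self.var_knots)
        b0 = natural_spline_basis([self.spec.center], self.var_knots)
        return b - b0

    def cumulative_weights(self, grid) -> np.ndarray:
        """Weight matrix W so that W @ beta_cb is the lag-cumulative excess
        at each grid exposure, relative to the center."""
        V = self.var_basis_centered(grid)  # (m, df_var)
        S = self.lag_matrix.sum(axis=0)  # (df_lag,)
        return np.einsum("mj,l->mjl", V, S).reshape(V.shape[0], -1)


def build_crossbasis(hwii_series, spec: CrossBasisSpec) -> CrossBasis:
    """Build the cross-basis matrix for a daily HWII exposure series.

    Entry (t, j*df_lag + l) = sum_{lag} Bvar_j(hwii_{t-lag}) * Blag_l(lag),
    with the var basis centered at ``spec.center`` (so a series constant at
    the center yields an all-zero matrix). Rows with an incomplete lag
    window (the first ``max_lag`` days) are flagged via ``valid``.
    """
    h = np.asarray(hwii_series, dtype=float)
    n = h.size
    if n <= spec.max_lag:
        raise ValueError("series must be longer than max_lag")
    lo, hi = float(np.min(h)), float(np.max(h))
    if not lo <= spec.center <= hi:
        raise ValueError(
            f"center {spec.center} lies outside the observed HWII range [{lo}, {hi}]"
        )
    knots = _var_knots(h, spec.df_var)
    C = lag_basis(spec.max_lag, spec.df_lag)
    b0 = natural_spline_basis([spec.center], knots)
    V = natural_spline_basis(h, knots) - b0  # (n, df_var)

    dv, dl = spec.df_var, spec.df_lag
    Z = np.zeros((n, dv * dl))
    for lag in range(spec.max_lag + 1):
        Vs = np.zeros_like(V)
        Vs[lag:] = V[: n - lag]
        Z += np.einsum("tj,l->tjl", Vs, C[lag]).reshape(n, dv * dl)

    valid = np.ones(n, dtype=bool)
    valid[: spec.max_lag] = False
    pos = h[h > 0]
    pos_min = float(pos.min()) if pos.size else hi
    return CrossBasis(
        matrix=Z,
        spec=spec,
        var_knots=knots,
        lag_matrix=C,
        valid=valid,
        observed_range=(lo, hi),
        positive_min=pos_min,
    )


@dataclass
class DLNMFit:
    """A fitted DLNM: coefficients, covariance and the cross-basis that
    produced the design block."""

    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    cb_slice: slice
    crossbasis: CrossBasis
    aic: float
    n_obs: int
    sigma2: float
    age_group: str
    definition_id: str | None = None

    @property
    def cb_params(self) -> np.ndarray:
        return self.params[self.cb_slice]

    @property
    def cb_cov(self) -> np.ndarray:
        return self.cov[self.cb_slice, self.cb_slice]


@dataclass
class VulnerabilityCurve:
    """Cumulative (lag 0..max_lag) excess crude-mortality-rate curve in
    HWII, centered at the minimum-mortality HWII, with 95% CI bands.

    Rates are per person-day on the *crude* scale (group deaths over total
    population); ``percentiles`` re-expresses the grid as area-specific
    percentiles of the observed event HWIIs when available.
    """

    grid: np.ndarray
    central: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    age_group: str
    center: float
    observed_range: tuple[float, float]
    percentiles: np.ndarray | None = None

    def band(self, which: str) -> np.ndarray:
        return {"lower": self.lower95, "central": self.central, "upper": self.upper95}[which]


_DOW_COLS = ["dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat", "dow_sun"]


def _design(
    records: pd.DataFrame,
    cb: CrossBasis,
    extra_confounders: tuple[str, ...] = (),
    time_spline_df: int | None = None,
) -> tuple[np.ndarray, list[str], slice]:
    n = len(records)
    dates = records.index
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]

    cb_start = 1
    for j in range(cb.matrix.shape[1]):
        cols.append(cb.matrix[:, j])
        names.append(f"cb_{j}")
    cb_stop = cb_start + cb.matrix.shape[1]

    cols.append(records["tmean"].to_numpy(dtype=float))
    names.append("tmean")
    cols.append(records["rh"].to_numpy(dtype=float))
    names.append("rh")

    time = (dates - dates[0]).days.to_numpy(dtype=float) / 365.25
    if time_spline_df is None:
        cols.append(time)
        names.append("time")
    else:
        knots = np.linspace(time.min(), time.max(), time_spline_df + 1)
        B = natural_spline_basis(time, knots)
        for j in range(B.shape[1]):
            cols.append(B[:, j])
            names.append(f"time_ns{j}")

    dow = dates.dayofweek.to_numpy()  # Monday=0 is the reference
    for d, name in enumerate(_DOW_COLS, start=1):
        cols.append((dow == d).astype(float))
        names.append(name)
    cols.append(records["holiday"].to_numpy(dtype=float))
    names.append("holiday")

    for extra in extra_confounders:
        if extra not in records.columns:
            raise ValueError(f"confounder column {extra!r} not in records")
        cols.append(records[extra].to_numpy(dtype=float))
        names.append(extra)

    X = np.column_stack(cols)
    return X, names, slice(cb_start, cb_stop)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
    if bad:
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC for the Gaussian OLS model, n*log(RSS/n) + 2*(k+1), with the
    additive constants dropped (valid for comparisons at fixed n and
    outcome)."""
    return float(n * np.log(rss / n) + 2 * (k + 1))


def fit_dlnm(
    records: pd.DataFrame,
    events,
    spec: CrossBasisSpec,
    age_group: str = "65plus",
    extra_confounders: tuple[str, ...] = (),
    time_spline_df: int | None = None,
    definition_id: str | None = None,
    crossbasis: CrossBasis | None = None,
) -> DLNMFit:
    """OLS fit of the daily crude mortality rate of one age group on the
    cross-basis plus confounders. The first ``max_lag`` rows (incomplete lag
    window) are dropped so all models over a shared spec see identical
    observations."""
    deaths_col = f"deaths_{age_group}"
    for col in ("tmean", "rh", "holiday", deaths_col, "population"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")

    if crossbasis is None:
        hwii = daily_hwii_series(records, events)
        crossbasis = build_crossbasis(hwii.to_numpy(), spec)

    y = (
        records[deaths_col].to_numpy(dtype=float)
        / records["population"].to_numpy(dtype=float)
    )
    X, names, cb_slice = _design(records, crossbasis, extra_confounders, time_spline_df)

    keep = crossbasis.valid
    X, y = X[keep], y[keep]
    _check_rank(X, names)

    res = sm.OLS(y, X).fit()
    n, k = X.shape
    rss = float(res.ssr)
    return DLNMFit(
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        columns=names,
        cb_slice=cb_slice,
        crossbasis=crossbasis,
        aic=gaussian_aic(rss, n, k),
        n_obs=n,
        sigma2=rss / (n - k),
        age_group=age_group,
        definition_id=definition_id,
    )


def cumulative_curve(
    fit: DLNMFit, grid=None, n_grid: int = 50
) -> VulnerabilityCurve:
    """Extract the lag-cumulative excess-rate curve with 95% CI bands.

    central(x) = w(x)' beta_cb with w(x) the cross-basis weights at x summed
    over lags 0..max_lag, relative to the center; the curve passes through
    zero at the center exactly.
    """
    cb = fit.crossbasis
    lo, hi = cb.observed_range
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.union1d(np.asarray(grid, dtype=float), [cb.spec.center])
    W = cb.cumulative_weights(grid)
    central = W @ fit.cb_params
    var = np.einsum("ij,jk,ik->i", W, fit.cb_cov, W)
    se = np.sqrt(np.clip(var, 0.0, None))
    return VulnerabilityCurve(
        grid=grid,
        central=central,
        lower95=central - 1.96 * se,
        upper95=central + 1.96 * se,
        age_group=fit.age_group,
        center=cb.spec.center,
        observed_range=cb.observed_range,
    )


def find_center(fit: DLNMFit, grid=None, n_grid: int = 50) -> float:
    """Minimum-mortality HWII: argmin of the cumulative curve over a grid on
    the observed positive-HWII range (leftmost argmin on ties). The argmin
    does not depend on the center the fit was built with, since re-centering
    only shifts the curve vertically."""
    cb = fit.crossbasis
    if grid is None:
        grid = np.linspace(cb.positive_min, cb.observed_range[1], n_grid)
    grid = np.asarray(grid, dtype=float)
    W = cb.cumulative_weights(grid)
    central = W @ fit.cb_params
    return float(grid[np.argmin(central)])


def fit_vulnerability(
    records: pd.DataFrame,
    events,
    spec: CrossBasisSpec,
    age_group: str = "65plus",
    n_grid: int = 50,
    **fit_kwargs,
) -> tuple[DLNMFit, VulnerabilityCurve]:
    """Two-pass fit: locate the minimum-mortality HWII with an uncentered
    fit, re-fit centered there, and extract the curve (grid re-expressed as
    event-HWII percentiles when events exist)."""
    fit0 = fit_dlnm(records, events, spec, age_group=age_group, **fit_kwargs)
    center = find_center(fit0, n_grid=n_grid)
    fit = fit_dlnm(
        records, events, replace(spec, center=center), age_group=age_group, **fit_kwargs
    )
    curve = cumulative_curve(fit, n_grid=n_grid)
    hwiis = np.array([ev.hwii for ev in events])
    if hwiis.size >= 2:
        curve = percentile_axis(curve, hwiis)
    return fit, curve


def select_definition(
    records: pd.DataFrame,
    catalogue: list[HWDefinition],
    spec: CrossBasisSpec,
    age_group: str = "65plus",
) -> tuple[HWDefinition, pd.DataFrame]:
    """Fit one DLNM per catalogued definition on identical observations and
    return the minimum-AIC definition plus the full AIC table.

    Definitions yielding no events (or an un-fittable design) are recorded
    as non-fittable and excluded from the argmin. Ties break in catalogue
    order.
    """
    missing = [c for c in ("tmean", "rh", "holiday", f"deaths_{age_group}",
                           "population") if c not in records.columns]
    if missing:
        raise ValueError(f"records lack required columns: {missing}")
    rows = []
    fittable: list[tuple[int, float]] = []
    for i, defn in enumerate(catalogue):
        thr = resolve_threshold(records, defn)
        events = detect_events(records, defn, threshold=thr)
        if len(events) == 0:
            rows.append(
                {"id": defn.id, "threshold": thr, "n_events": 0, "aic": np.nan,
                 "note": "no events"}
            )
            continue
        try:
            fit = fit_dlnm(records, events, spec, age_group=age_group,
                           definition_id=defn.id)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append(
                {"id": defn.id, "threshold": thr, "n_events": len(events),
                 "aic": np.nan, "note": f"not fittable: {exc}"}
            )
            continue
        rows.append(
            {"id": defn.id, "threshold": thr, "n_events": len(events),
             "aic": fit.aic, "note": ""}
        )
        fittable.append((i, fit.aic))
    if not fittable:
        raise ValueError("no catalogued definition is fittable on this dataset")
    best_idx = min(fittable, key=lambda t: t[1])[0]  # stable: first minimum wins
    return catalogue[best_idx], pd.DataFrame(rows)


def sensitivity_sweep(
    records: pd.DataFrame,
    events,
    age_group: str = "65plus",
    df_var_grid=(2, 3, 4),
    df_lag_grid=(3, 4, 5),
    max_lag_grid=(3, 5, 7, 10),
    confounder_addons=((),),
    n_grid: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Cartesian sensitivity sweep over the DLNM's key parameters, plus
    optional extra confounder columns (e.g. ("api",), ("tmax",)). Returns
    the AIC table and the curves keyed by (df_var, df_lag, max_lag, addons).

    AIC values are comparable within a fixed max_lag (each fit drops its own
    incomplete-lag rows)."""
    rows = []
    curves: dict = {}
    for dv, dl, ml, addons in itertools.product(
        df_var_grid, df_lag_grid, max_lag_grid, confounder_addons
    ):
        label = "+".join(addons) if addons else "base"
        if dl > ml + 1:  # more lag-basis columns than lag points
            rows.append({"df_var": dv, "df_lag": dl, "max_lag": ml,
                         "confounders": label, "aic": np.nan, "center": np.nan})
            continue
        spec = CrossBasisSpec(df_var=dv, df_lag=dl, max_lag=ml)
        try:
            fit, curve = fit_vulnerability(
                records, events, spec, age_group=age_group, n_grid=n_grid,
                extra_confounders=tuple(addons),
            )
        except (ValueError, np.linalg.LinAlgError):
            # e.g. too few distinct event intensities to support df_var
            rows.append({"df_var": dv, "df_lag": dl, "max_lag": ml,
                         "confounders": label, "aic": np.nan, "center": np.nan})
            continue
        rows.append(
            {"df_var": dv, "df_lag": dl, "max_lag": ml,
             "confounders": label,
             "aic": fit.aic, "center": fit.crossbasis.spec.center}
        )
        curves[(dv, dl, ml, tuple(addons))] = curve
    return pd.DataFrame(rows), curves


def percentile_axis(curve: VulnerabilityCurve, event_hwiis) -> VulnerabilityCurve:
    """Re-express the curve's HWII grid as area-specific percentiles of the
    observed event HWIIs (min -> 0th, max -> 100th, linear in between;
    monotone, so curve ordering is preserved)."""
    v = np.sort(np.asarray(event_hwiis, dtype=float))
    if v.size < 2:
        raise ValueError("need at least two event HWIIs for a percentile axis")
    ranks = np.linspace(0.0, 100.0, v.size)
    pct = np.interp(curve.grid, v, ranks, left=0.0, right=100.0)
    return replace(curve, percentiles=pct)
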