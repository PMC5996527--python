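"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: event detection is a
window scan over every (start, end) pair, the cross-basis is an explicit
triple loop with scalar spline evaluation, and quantiles come from a full
sort. They exist to cross-check the implementation, never to stand in for
it.
"""

from __future__ import annotations

import numpy as np

from heatrisk.splines import natural_spline_basis


def brute_force_events(values: np.ndarray, threshold: float, min_duration: int,
                       strict: bool = True) -> list[tuple[int, int, float]]:
    """All maximal qualifying windows, by checking every (start, length)
    window against: all days exceed, both neighbours do not, length >=
    min_duration. Returns (start_idx, end_idx, hwii) triples in order."""
    n = len(values)
    hot = values > threshold if strict else values >= threshold
    c = np.concatenate([[0], np.cumsum(hot)])
    out = []
    for L in range(min_duration, n + 1):
        starts = np.arange(0, n - L + 1)
        all_hot = (c[starts + L] - c[starts]) == L
        left_cold = np.empty(starts.size, dtype=bool)
        left_cold[0] = True
        left_cold[1:] = ~hot[: n - L]
        right_cold = np.empty(starts.size, dtype=bool)
        right_cold[-1] = True
        right_cold[:-1] = ~hot[L:]
        for s in starts[all_hot & left_cold & right_cold]:
            hwii = float(np.sum(values[s : s + L] - threshold))
            out.append((int(s), int(s + L - 1), hwii))
    out.sort()
    return out


def sort_quantile(values: np.ndarray, pct: float) -> float:
    """Linear-interpolation empirical quantile via an explicit full sort."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (v.size - 1) * pct / 100.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def naive_crossbasis(hwii: np.ndarray, var_knots: np.ndarray,
                     lag_matrix: np.ndarray, center: float) -> np.ndarray:
    """Explicit triple-loop cross-basis construction with scalar spline
    evaluation. Column order (j, l) -> j * df_lag + l; exposures before the
    series start contribute nothing (matching the flagged-invalid rows)."""
    n = len(hwii)
    max_lag = lag_matrix.shape[0] - 1
    df_lag = lag_matrix.shape[1]
    b_center = natural_spline_basis([center], var_knots)[0]
    df_var = b_center.size
    Z = np.zeros((n, df_var * df_lag))
    for t in range(n):
        for lag in range(max_lag + 1):
            if t - lag < 0:
                continue
            bv = natural_spline_basis([hwii[t - lag]], var_knots)[0] - b_center
            for j in range(df_var):
                for l in range(df_lag):
                    Z[t, j * df_lag + l] += bv[j] * lag_matrix[lag, l]
    return Z


def naive_cumulative(grid: np.ndarray, beta: np.ndarray, var_knots: np.ndarray,
                     lag_matrix: np.ndarray, center: float) -> np.ndarray:
    """Lag-cumulative prediction by explicit summation over lags."""
    max_lag = lag_matrix.shape[0] - 1
    df_lag = lag_matrix.shape[1]
    b_center = natural_spline_basis([center], var_knots)[0]
    df_var = b_center.size
    out = np.zeros(len(grid))
    for i, x in enumerate(grid):
        bv = natural_spline_basis([x], var_knots)[0] - b_center
        acc = 0.0
        for lag in range(max_lag + 1):
            for j in range(df_var):
                for l in range(df_lag):
                    acc += beta[j * df_lag + l] * bv[j] * lag_matrix[lag, l]
        out[i] = acc
    return out
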