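"""Natural cubic spline bases.

A natural cubic spline is a piecewise cubic polynomial that is C2-continuous
at its knots and constrained to be *linear* beyond the two boundary knots.
The basis here follows the classic truncated-power construction: with knots
``xi_1 < ... < xi_K`` the functions

    N_1(x) = 1,   N_2(x) = x,   N_{k+2}(x) = d_k(x) - d_{K-1}(x)

with ``d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)`` span the
space of natural cubic splines on those knots. Dropping the constant leaves
``K - 1`` columns, so a basis of dimension ``df`` uses ``df + 1`` knots.

The dimension convention throughout this package counts *columns of the
design block, intercept excluded* — a model using the basis supplies its own
intercept.
"""

from __future__ import annotations

import numpy as np

__all__ = ["natural_spline_basis", "ns_design", "default_knots"]


def _truncated_cubed(x: np.ndarray, knot: float) -> np.ndarray:
    return np.clip(x - knot, 0.0, None) ** 3


def natural_spline_basis(x, knots) -> np.ndarray:
    """Evaluate the natural cubic spline basis (intercept excluded).

    Parameters
    ----------
    x : array-like
        Points at which to evaluate.
    knots : array-like
        All knots, boundary included, strictly increasing, length >= 2.

    Returns
    -------
    ndarray of shape ``(len(x), len(knots) - 1)``
        First column is ``x`` itself; the remaining ``K - 2`` columns are the
        curvature terms ``d_k - d_{K-1}``. Together with a constant they span
        every natural cubic spline on these knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2:
        raise ValueError("need at least two knots (boundary knots)")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {knots!r}")

    K = knots.size
    cols = [x]
    if K > 2:
        denom_last = knots[K - 1] - knots[K - 2]
        d_last = (
            _truncated_cubed(x, knots[K - 2]) - _truncated_cubed(x, knots[K - 1])
        ) / denom_last
        for k in range(K - 2):
            denom = knots[K - 1] - knots[k]
            d_k = (
                _truncated_cubed(x, knots[k]) - _truncated_cubed(x, knots[K - 1])
            ) / denom
            cols.append(d_k - d_last)
    return np.column_stack(cols)


def default_knots(x, df: int) -> np.ndarray:
    """Knot placement rule: boundary knots at min/max of ``x``, interior
    knots at equally spaced quantiles of ``x``.

    ``df`` columns require ``df + 1`` knots, hence ``df - 1`` interior knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if x.size == 0:
        raise ValueError("cannot place knots on an empty sample")
    lo, hi = float(np.min(x)), float(np.max(x))
    if df == 1:
        if hi <= lo:
            hi = lo + 1.0  # degenerate sample: any increasing pair gives a linear basis
        return np.array([lo, hi])
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(x, probs)
    knots = np.concatenate([[lo], np.atleast_1d(interior), [hi]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "quantile knots are not distinct; reduce df or provide knots explicitly"
        )
    return knots


def ns_design(x, df: int, knots=None) -> tuple[np.ndarray, np.ndarray]:
    """Natural spline basis of dimension ``df`` with automatic knots.

    Returns ``(basis, knots)`` so a fitted model can re-evaluate the exact
    same basis at new points.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = default_knots(x, df)
    else:
        knots = np.asarray(knots, dtype=float)
        if knots.size != df + 1:
            raise ValueError(
                f"df={df} requires {df + 1} knots, got {knots.size}"
            )
    return natural_spline_basis(x, knots), knots
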