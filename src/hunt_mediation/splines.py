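"""Restricted cubic spline (natural spline) bases for flexible age adjustment.

A restricted cubic spline with :math:`k` knots :math:`t_1 < \\dots < t_k` is a
piecewise cubic that is constrained to be *linear* beyond the boundary knots.
It contributes :math:`k-1` design columns: the identity (linear) term plus
:math:`k-2` nonlinear truncated-power terms

.. math::

    d_j(x) = \\Big[(x-t_j)_+^3
             - (x-t_{k-1})_+^3 \\frac{t_k - t_j}{t_k - t_{k-1}}
             + (x-t_k)_+^3 \\frac{t_{k-1} - t_j}{t_k - t_{k-1}}\\Big]
             \\, / \\, (t_k - t_1)^2,

for :math:`j = 1, \\dots, k-2`.  The divisor keeps the nonlinear columns on a
scale comparable to the linear term.  Every nonlinear column is exactly zero
below the first knot and exactly linear above the last one, so the fitted
curve never explodes in the sparse tails of an age distribution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SplineBasis", "rcs_basis", "HARRELL_QUANTILES"]

#: Default knot-placement quantiles, by number of knots (Harrell's choices,
#: as used by default in the rms package and most epidemiological software).
HARRELL_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.18333, 0.34167, 0.65833, 0.81667, 0.975),
}


class SplineBasis:
    """Evaluable restricted cubic spline basis with fixed knots.

    Parameters
    ----------
    knots
        Strictly increasing sequence of at least three knot locations
        (years of age, in this package's use).
    """

    def __init__(self, knots) -> None:
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise ValueError("need at least 3 one-dimensional knots")
        if not np.all(np.isfinite(knots)):
            raise ValueError("knots must be finite")
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def basis_dim(self) -> int:
        """Number of design columns (k - 1, including the linear term)."""
        return self.knots.size - 1

    def transform(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; returns shape ``(n, k - 1)``.

        Column 0 is ``x`` itself; columns ``1 .. k-2`` are the nonlinear
        restricted truncated-power terms.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("spline evaluation requires finite inputs")
        t = self.knots
        k = t.size
        scale = (t[-1] - t[0]) ** 2
        cols = [x]
        for j in range(k - 2):
            term = (
                np.clip(x - t[j], 0.0, None) ** 3
                - np.clip(x - t[-2], 0.0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
                + np.clip(x - t[-1], 0.0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
            )
            cols.append(term / scale)
        return np.column_stack(cols)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SplineBasis(knots={np.round(self.knots, 2).tolist()})"


def rcs_basis(ages, n_knots: int = 5) -> SplineBasis:
    """Place knots at Harrell's default quantiles of the observed ages.

    Parameters
    ----------
    ages
        Observed ages; must contain at least ``n_knots`` distinct finite
        values.
    n_knots
        Number of knots (3-7 supported; 5 is the package default).
    """
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if n_knots not in HARRELL_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(HARRELL_QUANTILES)}")
    if np.unique(ages).size < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct ages, got {np.unique(ages).size}"
        )
    knots = np.quantile(ages, HARRELL_QUANTILES[n_knots])
    if np.unique(knots).size < n_knots:
        raise ValueError("quantile knots are not distinct; age distribution too coarse")
    return SplineBasis(knots)
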