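"""Growth-curve fitting and slope extraction.

Each plot's height series is fit with a least-squares piecewise-polynomial
B-spline on equal-width pieces (default 20 cubic pieces, following the
heavily over-parameterized spline the method was built around).  When the
basis has more coefficients than observations the system is regularized by
a tiny second-divided-difference penalty on the coefficients (null space =
exactly the linear functions), giving a deterministic smooth interpolant
that reproduces polynomial trends; over-determined systems use plain least
squares.  The first derivative -- the growth-rate curve -- is the exact
piecewise-polynomial derivative, sampled on a grid of 100 equidistant
timepoints common to all plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import DomainError, InsufficientDataError

#: relative weight of the coefficient-smoothness penalty used only when the
#: basis is larger than the data (selects among exact interpolants)
DEFAULT_SMOOTHING = 1e-9


@dataclass
class GrowthSpline:
    plot_id: str
    spline: BSpline
    t_min: float
    t_max: float
    n_pieces: int
    order: int  # polynomial order (degree + 1)
    rss: float

    def __call__(self, t) -> np.ndarray:
        self._check_domain(t)
        return self.spline(t)

    def slope(self, t) -> np.ndarray:
        """First derivative (m/day); extrapolation is refused."""
        self._check_domain(t)
        return self.spline.derivative()(t)

    def _check_domain(self, t) -> None:
        t = np.asarray(t, dtype=float)
        eps = 1e-9 * max(1.0, abs(self.t_max))
        if np.any(t < self.t_min - eps) or np.any(t > self.t_max + eps):
            raise DomainError(
                f"evaluation outside fitted domain [{self.t_min}, {self.t_max}]"
            )


def _divided_diff_penalty(knots: np.ndarray, degree: int, n_coef: int) -> np.ndarray:
    """Second-divided-difference operator on coefficients w.r.t. Greville
    abscissae; D @ c vanishes iff the spline is a straight line."""
    grev = np.array([knots[i + 1 : i + degree + 1].mean() for i in range(n_coef)])
    rows = []
    for j in range(n_coef - 2):
        h1 = grev[j + 1] - grev[j]
        h2 = grev[j + 2] - grev[j + 1]
        r = np.zeros(n_coef)
        r[j] = 1.0 / h1
        r[j + 1] = -(1.0 / h1 + 1.0 / h2)
        r[j + 2] = 1.0 / h2
        rows.append(r / (grev[j + 2] - grev[j]))
    return np.array(rows)


def fit_spline(
    days: Sequence[float],
    heights: Sequence[float],
    n_pieces: int = 20,
    order: int = 4,
    plot_id: str = "",
    smoothing: float = DEFAULT_SMOOTHING,
) -> GrowthSpline:
    """Least-squares B-spline fit of a height series.

    ``n_pieces`` equal-width polynomial pieces of the given ``order``
    (degree + 1).  Requires >= 4 strictly increasing observation days.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(heights, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("spline fit needs >= 4 observations")
    if np.any(np.diff(t) <= 0):
        raise ValueError("observation days must be strictly increasing")
    degree = order - 1
    t0, t1 = float(t[0]), float(t[-1])
    breaks = np.linspace(t0, t1, n_pieces + 1)
    knots = np.r_[[t0] * degree, breaks, [t1] * degree]
    B = BSpline.design_matrix(t, knots, degree).toarray()
    n_coef = B.shape[1]
    if t.size >= n_coef:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    else:
        D = _divided_diff_penalty(knots, degree, n_coef)
        BtB = B.T @ B
        DtD = D.T @ D
        lam = smoothing * np.trace(BtB) / max(np.trace(DtD), 1e-300)
        coef = np.linalg.solve(BtB + lam * DtD, B.T @ y)
    resid = y - B @ coef
    return GrowthSpline(
        plot_id=plot_id,
        spline=BSpline(knots, coef, degree),
        t_min=t0,
        t_max=t1,
        n_pieces=n_pieces,
        order=order,
        rss=float(resid @ resid),
    )


def differentiate(gs: GrowthSpline):
    """Domain-guarded slope function of a fitted growth curve."""
    deriv = gs.spline.derivative()

    def slope(t):
        gs._check_domain(t)
        return deriv(t)

    return slope


def sample_slopes(splines: Sequence[GrowthSpline], n: int = 100) -> pd.DataFrame:
    """Growth rate at ``n`` equidistant times on the common domain.

    The grid spans the intersection of all plot domains and is identical
    across plots.  Long-format output: plot_id, timepoint_index (0-based),
    day, slope_m_per_day.
    """
    if not splines:
        raise InsufficientDataError("no fitted splines")
    lo = max(s.t_min for s in splines)
    hi = min(s.t_max for s in splines)
    if lo >= hi:
        raise DomainError("plot time domains do not overlap")
    grid = np.linspace(lo, hi, n)
    frames = []
    for s in splines:
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": s.plot_id,
                    "timepoint_index": np.arange(n),
                    "day": grid,
                    "slope_m_per_day": s.slope(grid),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fit_plots(
    records: pd.DataFrame,
    value_col: str = "ph_m",
    time_col: str = "days_after_sowing",
    n_pieces: int = 20,
    order: int = 4,
    smoothing: float = DEFAULT_SMOOTHING,
) -> list[GrowthSpline]:
    """Fit one growth spline per plot from a long-format height table."""
    out = []
    for plot_id, grp in records.groupby("plot_id", sort=False):
        grp = grp.sort_values(time_col)
        out.append(
            fit_spline(
                grp[time_col].to_numpy(),
                grp[value_col].to_numpy(),
                n_pieces=n_pieces,
                order=order,
                plot_id=str(plot_id),
                smoothing=smoothing,
            )
        )
    return out
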