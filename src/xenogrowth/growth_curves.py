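"""B-spline growth curves for longitudinal tumor-size data.

Functional data analysis with a small, fixed B-spline basis is well
suited to cohorts of only a few animals per group: fitting a single
smooth curve to the pooled measurements of a strain damps individual
measurement fluctuation while preserving the shape of the trajectory,
and the fitted spline is analytically differentiable, giving growth
velocity (first derivative) and acceleration (second derivative)
directly rather than by finite-differencing noisy data.

The default basis has ``n_basis = 6`` cubic (order 4) B-splines on a
clamped, equally spaced knot vector spanning the observed day range.
The fit is unpenalized least squares over all individual measurements
pooled per strain; per-day means and standard errors are computed only
for display and for downstream simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import ValidationError

DEFAULT_N_BASIS = 6
DEFAULT_ORDER = 4  # cubic

#: Reporting grid spacing in days (plot smoothness only).
DEFAULT_GRID_STEP = 0.5


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped B-spline basis: knot vector plus spline order.

    ``order`` is polynomial degree + 1 (4 = cubic).  The knot vector has
    ``n_basis + order`` entries with the domain endpoints repeated
    ``order`` times, so the basis functions form a partition of unity on
    the closed domain.
    """

    knots: tuple[float, ...]
    order: int

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.order

    @property
    def domain(self) -> tuple[float, float]:
        return (self.knots[0], self.knots[-1])

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        _check_in_domain(x, self.domain)
        t = np.asarray(self.knots)
        return BSpline.design_matrix(x, t, self.degree).toarray()


def _check_in_domain(x: np.ndarray, domain: tuple[float, float]) -> None:
    lo, hi = domain
    if np.any(x < lo) or np.any(x > hi):
        bad = np.asarray(x)[(np.asarray(x) < lo) | (np.asarray(x) > hi)]
        raise ValidationError(
            f"evaluation points {bad.tolist()} outside fitted domain "
            f"[{lo}, {hi}]; extrapolation is not supported"
        )


def build_basis(
    domain: tuple[float, float],
    n_basis: int = DEFAULT_N_BASIS,
    order: int = DEFAULT_ORDER,
) -> BSplineBasis:
    """Construct a clamped B-spline basis with equally spaced interior knots.

    ``n_basis`` functions of the given order on ``domain`` require
    ``n_basis - order`` interior knots; these are placed uniformly.
    """
    t_min, t_max = float(domain[0]), float(domain[1])
    if not t_min < t_max:
        raise ValidationError(f"degenerate domain [{t_min}, {t_max}]")
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    if n_basis < order:
        raise ValidationError(
            f"n_basis ({n_basis}) must be >= order ({order})"
        )
    n_interior = n_basis - order
    interior = np.linspace(t_min, t_max, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(order, t_min), interior, np.full(order, t_max)]
    )
    return BSplineBasis(knots=tuple(knots.tolist()), order=order)


@dataclass(frozen=True)
class GrowthSeries:
    """Pooled longitudinal size measurements for one strain and metric.

    ``days`` and ``values`` are parallel per-measurement arrays (several
    mice may contribute values on the same day).  ``metric`` names the
    size measure, e.g. ``"surface_area"`` or ``"volume"``.
    """

    strain: str
    metric: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, float)
        values = np.asarray(self.values, float)
        if days.shape != values.shape or days.ndim != 1:
            raise ValidationError("days and values must be equal-length 1-D arrays")
        if len(days) == 0:
            raise ValidationError("empty growth series")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_sizes(
        cls, sizes: pd.DataFrame, strain: str, metric: str = "surface_area"
    ) -> "GrowthSeries":
        """Build a series from a :func:`geometry.measurements_to_sizes` table."""
        col = {"surface_area": "surface_area_cm2", "volume": "volume_cm3"}[metric]
        sub = sizes.loc[sizes["strain"] == strain]
        if sub.empty:
            raise ValidationError(f"no rows for strain {strain!r}")
        return cls(
            strain=strain,
            metric=metric,
            days=sub["day"].to_numpy(float),
            values=sub[col].to_numpy(float),
        )

    def summarize(self) -> pd.DataFrame:
        """Per-day mean, SE (sample SD / sqrt(n); 0 when n = 1) and n."""
        df = pd.DataFrame({"day": self.days, "value": self.values})
        g = df.groupby("day")["value"]
        out = pd.DataFrame(
            {
                "day": np.sort(df["day"].unique()),
                "mean": g.mean().to_numpy(),
                "se": (g.std(ddof=1) / np.sqrt(g.count())).fillna(0.0).to_numpy(),
                "n": g.count().to_numpy(),
            }
        )
        if (out["n"] == 1).any():
            warnings.warn(
                f"strain {self.strain}: some days have n = 1; their SE is 0",
                stacklevel=2,
            )
        return out

    @property
    def domain(self) -> tuple[float, float]:
        return (float(self.days.min()), float(self.days.max()))


@dataclass(frozen=True)
class SplineFit:
    """A fitted B-spline growth curve, differentiable to order 2."""

    basis: BSplineBasis
    coefficients: np.ndarray
    strain: str = ""
    metric: str = ""
    rss: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, float)
        if coef.shape != (self.basis.n_basis,):
            raise ValidationError(
                f"expected {self.basis.n_basis} coefficients, got {coef.shape}"
            )
        object.__setattr__(self, "coefficients", coef)

    @property
    def domain(self) -> tuple[float, float]:
        return self.basis.domain

    def _bspline(self) -> BSpline:
        return BSpline(
            np.asarray(self.basis.knots), self.coefficients, self.basis.degree
        )

    def __call__(self, grid, deriv: int = 0) -> np.ndarray:
        return evaluate(self, grid, deriv)

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "metric": self.metric,
            "order": self.basis.order,
            "knots": list(self.basis.knots),
            "coefficients": self.coefficients.tolist(),
            "domain": list(self.domain),
            "rss": self.rss,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SplineFit":
        basis = BSplineBasis(knots=tuple(d["knots"]), order=int(d["order"]))
        return cls(
            basis=basis,
            coefficients=np.asarray(d["coefficients"], float),
            strain=d.get("strain", ""),
            metric=d.get("metric", ""),
            rss=float(d.get("rss", float("nan"))),
        )


def fit_spline(series: GrowthSeries, basis: BSplineBasis | None = None) -> SplineFit:
    """Least-squares B-spline fit to all pooled measurements of a series.

    The coefficients minimize the unpenalized sum of squared residuals
    over every individual measurement (all mice pooled), not over per-day
    means.  Requires at least ``n_basis`` distinct observation days.
    """
    if basis is None:
        basis = build_basis(series.domain)
    n_distinct = len(np.unique(series.days))
    if n_distinct < basis.n_basis:
        raise ValidationError(
            f"only {n_distinct} distinct days for {basis.n_basis} basis "
            "functions; the fit is underdetermined — lower n_basis"
        )
    X = basis.design_matrix(series.days)
    coef, _, _, _ = np.linalg.lstsq(X, series.values, rcond=None)
    rss = float(np.sum((X @ coef - series.values) ** 2))
    return SplineFit(
        basis=basis,
        coefficients=coef,
        strain=series.strain,
        metric=series.metric,
        rss=rss,
    )


def evaluate(fit: SplineFit, grid, deriv: int = 0) -> np.ndarray:
    """Evaluate a fitted curve (deriv 0), its velocity (1) or acceleration (2).

    Derivatives are exact spline differentiation, not finite differences.
    Grid points outside the fitted domain raise; there is no extrapolation.
    """
    if deriv not in (0, 1, 2):
        raise ValidationError(f"deriv must be 0, 1 or 2, got {deriv}")
    grid = np.atleast_1d(np.asarray(grid, float))
    _check_in_domain(grid, fit.domain)
    spl = fit._bspline()
    if deriv:
        spl = spl.derivative(deriv)
    # extrapolate=True keeps the right endpoint exact; domain already checked
    return spl(grid)


def curve_bundle(fit: SplineFit, grid=None) -> pd.DataFrame:
    """Tidy table of smoothed value, velocity and acceleration on a grid.

    Columns: ``strain, metric, day, value, velocity, acceleration``.
    Default grid spans the fitted domain at 0.5-day spacing.
    """
    if grid is None:
        lo, hi = fit.domain
        grid = np.arange(lo, hi + DEFAULT_GRID_STEP / 2, DEFAULT_GRID_STEP)
        grid = grid[grid <= hi]
    grid = np.atleast_1d(np.asarray(grid, float))
    return pd.DataFrame(
        {
            "strain": fit.strain,
            "metric": fit.metric,
            "day": grid,
            "value": evaluate(fit, grid, 0),
            "velocity": evaluate(fit, grid, 1),
            "acceleration": evaluate(fit, grid, 2),
        }
    )
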