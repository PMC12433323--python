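"""Cohort validation statistics: linear growth fits and two-sample t-tests.

Once a strain is selected and expanded to a larger cohort, its growth is
summarized by an ordinary least-squares line of size against day, and
the cohort is compared with the original small tested group by a
two-sample t-test on final-day sizes.  The classical pooled-variance
Student test is the default; Welch's unequal-variance variant is
available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

T_VARIANTS = ("student_pooled", "welch")


@dataclass(frozen=True)
class LinearFit:
    """OLS line of best fit: slope (size-units/day), intercept, R^2, n."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass(frozen=True)
class TTestResult:
    """Two-sided two-sample t-test result."""

    statistic: float
    df: float
    p_value: float
    variant: str
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n1": self.n1,
            "n2": self.n2,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def linear_fit(x, y) -> LinearFit:
    """Ordinary least-squares line through (x, y).

    ``r_squared = 1 - SSres/SStot``; when y has zero variance the fit is
    the constant line and R^2 is defined as 0 (with a warning) to avoid
    0/0.  Requires at least two distinct x values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValidationError("need at least 2 points for a line")
    if len(np.unique(x)) < 2:
        raise ValidationError("all x values identical; slope undefined")
    if np.ptp(y) == 0:
        warnings.warn(
            "y has zero variance; R^2 defined as 0 for the constant fit",
            stacklevel=2,
        )
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=len(x))
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def two_sample_t(x, y, variant: str = "student_pooled") -> TTestResult:
    """Two-sided two-sample t-test.

    ``student_pooled`` uses the pooled-variance statistic with
    ``n1 + n2 - 2`` degrees of freedom; ``welch`` uses the
    Welch-Satterthwaite approximation.  Two degenerate zero-variance
    cases are defined explicitly: equal means give statistic 0 / p 1,
    unequal means are an error (the statistic is undefined).
    """
    if variant not in T_VARIANTS:
        raise ValidationError(f"variant must be one of {T_VARIANTS}, got {variant!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(len(x), len(y)) < 2:
        raise ValidationError("each sample needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            df = len(x) + len(y) - 2 if variant == "student_pooled" else float("nan")
            return TTestResult(0.0, float(df), 1.0, variant, len(x), len(y))
        raise ValidationError(
            "both samples have zero variance with unequal means; "
            "the t statistic is undefined"
        )
    res = stats.ttest_ind(x, y, equal_var=(variant == "student_pooled"))
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
        n1=len(x),
        n2=len(y),
    )


def percent_larger(a: float, b: float) -> tuple[float, int]:
    """How much larger ``a`` is than ``b``, as (raw percent, rounded integer).

    100 * (a - b) / b.  ``b`` must be positive.
    """
    if not b > 0:
        raise ValidationError(f"reference value must be > 0, got {b}")
    raw = 100.0 * (a - b) / b
    return raw, int(round(raw))


def strain_size_comparison(final_means: dict[str, float]) -> pd.DataFrame:
    """Pairwise percent-larger comparisons from per-strain final-day means.

    Every ordered pair where the first strain's mean exceeds the
    second's yields a row ``strain_a, strain_b, pct_larger_raw,
    pct_larger`` (integer-rounded).
    """
    rows = []
    for sa, ma in final_means.items():
        for sb, mb in final_means.items():
            if sa == sb or ma <= mb:
                continue
            raw, rounded = percent_larger(ma, mb)
            rows.append(
                {
                    "strain_a": sa,
                    "strain_b": sb,
                    "pct_larger_raw": raw,
                    "pct_larger": rounded,
                }
            )
    return pd.DataFrame(rows, columns=["strain_a", "strain_b", "pct_larger_raw", "pct_larger"])


def final_day_values(sizes: pd.DataFrame, metric: str = "surface_area") -> np.ndarray:
    """Per-mouse size at each mouse's last measurement day.

    The comparison unit for tested-vs-selected group tests: one value per
    mouse, taken at that mouse's final observed day.
    """
    col = {"surface_area": "surface_area_cm2", "volume": "volume_cm3"}[metric]
    idx = sizes.groupby("mouse_id")["day"].idxmax()
    return sizes.loc[idx, col].to_numpy(float)


def tested_vs_selected(
    tested_sizes: pd.DataFrame,
    selected_sizes: pd.DataFrame,
    metric: str = "surface_area",
    variant: str = "student_pooled",
) -> TTestResult:
    """t-test of final-day sizes: tested group vs selected cohort."""
    return two_sample_t(
        final_day_values(tested_sizes, metric),
        final_day_values(selected_sizes, metric),
        variant=variant,
    )
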