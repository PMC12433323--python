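"""Monte-Carlo AUC comparison of strain growth curves.

With only two mice per strain, a formal test on the raw trajectories has
essentially no power.  Instead, strains are compared on the area under
the size-vs-time curve (AUC) over a late-growth window (default Days
30-41), using simulated paired observations: each iteration draws one
simulated trajectory per strain from per-day Normal(mean, SE) summaries
(truncated at zero), computes each trajectory's trapezoid AUC, and
records which strain had the largest.  The win proportion of a strain is
the fraction of iterations it won; iterations are paired by a shared
iteration index so every strain faces the same number of comparisons.

Draws use common random numbers per strain (value = mean + SE * z), so
raising one strain's means with a fixed seed can never lower its win
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_WINDOW = (30.0, 41.0)
DEFAULT_N_ITER = 10_000


@dataclass(frozen=True)
class AUCWindow:
    """Day interval over which AUC is computed."""

    start_day: float
    end_day: float

    def __post_init__(self) -> None:
        if not self.start_day < self.end_day:
            raise ValidationError(
                f"window start ({self.start_day}) must precede end ({self.end_day})"
            )


@dataclass(frozen=True)
class AUCSimConfig:
    """Monte-Carlo design: iteration count, seed, window and sampling days."""

    seed: int
    n_iter: int = DEFAULT_N_ITER
    window: AUCWindow = field(default_factory=lambda: AUCWindow(*DEFAULT_WINDOW))
    sampling_days: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError(f"n_iter must be >= 1, got {self.n_iter}")
        if self.sampling_days is not None:
            days = tuple(float(d) for d in self.sampling_days)
            if len(days) == 0:
                raise ValidationError("sampling_days must not be empty")
            if list(days) != sorted(days):
                raise ValidationError("sampling_days must be increasing")
            object.__setattr__(self, "sampling_days", days)


@dataclass(frozen=True)
class AUCWinResult:
    """Win proportions and mean AUC per strain from one simulation run."""

    strains: tuple[str, ...]
    win_proportion: dict
    mean_auc: dict
    n_iter: int
    seed: int
    n_ties: int
    window: AUCWindow
    sampling_days: tuple[float, ...]

    @property
    def winner(self) -> str:
        return max(self.strains, key=lambda s: self.win_proportion[s])

    def to_dict(self) -> dict:
        return {
            "window": [self.window.start_day, self.window.end_day],
            "sampling_days": list(self.sampling_days),
            "n_iter": self.n_iter,
            "seed": self.seed,
            "n_ties": self.n_ties,
            "strains": list(self.strains),
            "win_proportion": dict(self.win_proportion),
            "mean_auc": dict(self.mean_auc),
            "winner": self.winner,
        }

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": list(self.strains),
                "mean_auc": [self.mean_auc[s] for s in self.strains],
                "win_proportion": [self.win_proportion[s] for s in self.strains],
            }
        )


def trapezoid_auc(days, values) -> float:
    """Trapezoid-rule area under (days, values); exact for piecewise-linear."""
    days = np.asarray(days, float)
    values = np.asarray(values, float)
    if days.ndim != 1 or len(days) < 2:
        raise ValidationError("need at least 2 points for an AUC")
    if np.any(np.diff(days) <= 0):
        raise ValidationError("days must be strictly increasing")
    if values.shape[-1] != len(days):
        raise ValidationError("values length must match days")
    return np.trapezoid(values, days, axis=-1)


def window_summaries(
    summary: pd.DataFrame, window: AUCWindow
) -> dict[str, pd.DataFrame]:
    """Restrict per-strain (day, mean, se) summaries to an AUC window.

    ``summary`` has columns ``strain, day, mean, se``.  Observed days
    inside the window are kept; if no observation falls exactly on a
    window endpoint, the endpoint is added by linear interpolation of
    mean and SE (both endpoints must lie inside the observed day range).
    Returns one (day, mean, se) frame per strain.
    """
    out: dict[str, pd.DataFrame] = {}
    for strain, sub in summary.groupby("strain", sort=False):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(float)
        if window.start_day < days.min() or window.end_day > days.max():
            raise ValidationError(
                f"window [{window.start_day}, {window.end_day}] outside the "
                f"observed day range [{days.min()}, {days.max()}] for {strain!r}"
            )
        keep = days[(days >= window.start_day) & (days <= window.end_day)]
        grid = np.unique(
            np.concatenate([[window.start_day], keep, [window.end_day]])
        )
        out[strain] = pd.DataFrame(
            {
                "day": grid,
                "mean": np.interp(grid, days, sub["mean"].to_numpy(float)),
                "se": np.interp(grid, days, sub["se"].to_numpy(float)),
            }
        )
    return out


def simulate_paired_auc(
    strain_summaries: dict[str, pd.DataFrame], config: AUCSimConfig
) -> AUCWinResult:
    """Monte-Carlo win proportions from per-strain per-day (mean, SE) summaries.

    Per iteration and per strain one trajectory is drawn, each day's value
    sampled from Normal(mean_day, SE_day) clamped at 0, and its trapezoid
    AUC over the window computed; the strain with the largest AUC wins the
    iteration.  Fully reproducible given ``config.seed``.  Ties (possible
    only when SEs vanish) are broken by lowest strain index and counted.
    """
    strains = tuple(strain_summaries)
    if not strains:
        raise ValidationError("no strain summaries supplied")
    if config.sampling_days is not None:
        days = np.asarray(config.sampling_days, float)
    else:
        days = None
    rng = np.random.default_rng(config.seed)
    aucs = np.empty((len(strains), config.n_iter))
    for i, strain in enumerate(strains):
        sub = strain_summaries[strain].sort_values("day")
        d = sub["day"].to_numpy(float)
        mean = sub["mean"].to_numpy(float)
        se = sub["se"].to_numpy(float)
        if days is not None:
            mean = np.interp(days, d, mean)
            se = np.interp(days, d, se)
            d = days
        if np.any(se < 0):
            raise ValidationError(f"negative SE for strain {strain!r}")
        z = rng.standard_normal((config.n_iter, len(d)))
        draws = np.clip(mean + se * z, 0.0, None)
        # a single sampling day degenerates to comparing the day's values,
        # which is equivalent to comparing AUCs of flat trajectories
        aucs[i] = draws[:, 0] if len(d) == 1 else trapezoid_auc(d, draws)
    winner_idx = np.argmax(aucs, axis=0)
    is_tie = (aucs == aucs.max(axis=0)).sum(axis=0) > 1
    wins = np.bincount(winner_idx, minlength=len(strains))
    return AUCWinResult(
        strains=strains,
        win_proportion={s: float(wins[i] / config.n_iter) for i, s in enumerate(strains)},
        mean_auc={s: float(aucs[i].mean()) for i, s in enumerate(strains)},
        n_iter=config.n_iter,
        seed=config.seed,
        n_ties=int(is_tie.sum()),
        window=config.window,
        sampling_days=tuple(
            np.asarray(days if days is not None else d, float).tolist()
        ),
    )


def compare_strains(
    summary: pd.DataFrame,
    seed: int,
    n_iter: int = DEFAULT_N_ITER,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> AUCWinResult:
    """Full comparison: window restriction + paired-AUC simulation.

    ``summary`` has columns ``strain, day, mean, se`` (see
    :meth:`growth_curves.GrowthSeries.summarize`).
    """
    win = AUCWindow(*window)
    summaries = window_summaries(summary, win)
    cfg = AUCSimConfig(seed=seed, n_iter=n_iter, window=win)
    return simulate_paired_auc(summaries, cfg)
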