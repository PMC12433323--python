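"""Synthetic xenograft cohorts and histology count tables.

No raw caliper data are deposited with studies of this kind, so every
pipeline stage is exercised on simulated cohorts whose statistical
structure matches what the analysis assumes:

* Gompertz volume growth ``V(t) = v_max * exp(-exp(-k*(t - lag)))`` —
  sigmoidal, near-flat for the first ~10-15 days after injection,
  accelerating after ~day 20, with no visible plateau inside a 6-week
  study when the inflection day ``lag`` sits in the 30s.
* Mouse-level heterogeneity: mean-one log-normal random effects on both
  ``v_max`` and ``k`` (default 15% CV), reproducing the wide standard
  errors seen with two mice per strain.
* Shape: each tumor keeps a persistent ellipsoid shape; the three
  semi-axes are obtained by splitting the volume-equivalent radius with
  log-normal aspect ratios (dispersion ``aspect_sd``) chosen so the axis
  product, hence the volume, is preserved exactly.
* Measurement noise: independent multiplicative log-normal error per
  caliper dimension (default 10% CV) — caliper error scales with size.

The three built-in strain presets are calibrated so the noiseless mean
trajectory hits day-41 volumes of 0.80 (nsg), 0.51 (nsgs) and 0.40
(nude) cm^3, with nsg > nsgs > nude throughout the late growth phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import CALIPER_COLUMNS

#: Measurement days post-injection: 2-3x weekly from day 10 to day 41.
DEFAULT_SCHEDULE: tuple[int, ...] = (10, 13, 15, 17, 20, 22, 24, 27, 29, 31, 34, 36, 38, 41)

#: Day whose mean volume the presets are calibrated to.
CALIBRATION_DAY = 41

#: Day monitoring starts and the caliper-measurable volume tumors have
#: reached by then (~50 mm^3, the conventional measurable threshold in
#: subcutaneous xenograft protocols).
MEASUREMENT_START_DAY = 10
MEASURABLE_VOLUME_CM3 = 0.05

_PRESET_TABLE = {
    # strain: (day-41 mean volume cm^3, growth rate 1/day)
    "nsg": (0.80, 0.085),
    "nsgs": (0.51, 0.080),
    "nude": (0.40, 0.075),
}


@dataclass(frozen=True)
class StrainGrowthParams:
    """Generative growth parameters for one strain.

    ``v_max`` (cm^3) is the Gompertz plateau, ``k`` (1/day) the growth
    rate, ``lag`` (day) the inflection day at which V = v_max / e.
    ``aspect_sd`` is the SD of log aspect ratios of the ellipsoid axes,
    ``noise_cv`` the CV of multiplicative caliper noise per dimension,
    and ``effect_cv`` the CV of mouse-level random effects on v_max and k.
    """

    strain: str
    v_max: float
    k: float
    lag: float
    aspect_sd: float = 0.15
    noise_cv: float = 0.10
    effect_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k <= 0:
            raise ValidationError("v_max and k must be > 0")
        if min(self.aspect_sd, self.noise_cv, self.effect_cv) < 0:
            raise ValidationError("dispersion parameters must be >= 0")


def preset(name: str, **overrides) -> StrainGrowthParams:
    """Built-in strain presets ``nsg``, ``nsgs``, ``nude``.

    Each preset's ``lag`` and ``v_max`` are solved from two anchors of
    the noiseless trajectory: the measurable volume (0.05 cm^3) at the
    day monitoring begins (day 10), and the strain's mean day-41 volume
    (0.80 / 0.51 / 0.40 cm^3).  The per-strain growth rate ``k`` sets
    how the strains separate in between.
    """
    from scipy.optimize import brentq

    key = name.lower()
    if key not in _PRESET_TABLE:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(_PRESET_TABLE)}"
        )
    target, k = _PRESET_TABLE[key]
    ratio = MEASURABLE_VOLUME_CM3 / target

    def anchor_gap(lag: float) -> float:
        g10 = math.exp(-math.exp(-k * (MEASUREMENT_START_DAY - lag)))
        g41 = math.exp(-math.exp(-k * (CALIBRATION_DAY - lag)))
        return g10 / g41 - ratio

    lag = brentq(anchor_gap, MEASUREMENT_START_DAY, 45.0)
    v_max = target / math.exp(-math.exp(-k * (CALIBRATION_DAY - lag)))
    return StrainGrowthParams(strain=key, v_max=v_max, k=k, lag=lag, **overrides)


def growth_trajectory(params: StrainGrowthParams, day) -> np.ndarray:
    """True (noiseless) Gompertz tumor volume at the given day(s), cm^3."""
    day = np.asarray(day, float)
    if np.any(day < 0):
        raise ValidationError("day must be >= 0")
    out = params.v_max * np.exp(-np.exp(-params.k * (day - params.lag)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CohortDesign:
    """A simulated cohort: strains, group structure, schedule and seed."""

    strains: tuple[StrainGrowthParams, ...]
    seed: int
    n_mice_per_strain: int = 2
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    group_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValidationError("at least one strain required")
        if self.n_mice_per_strain < 1:
            raise ValidationError("n_mice_per_strain must be >= 1")
        if len(self.schedule) == 0:
            raise ValidationError("schedule must not be empty")
        if list(self.schedule) != sorted(set(self.schedule)):
            raise ValidationError("schedule must be strictly increasing")
        if self.group_sizes is not None:
            total = len(self.strains) * self.n_mice_per_strain
            if sum(self.group_sizes) != total:
                raise ValidationError(
                    f"group sizes {self.group_sizes} must sum to {total} mice"
                )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_mice_per_strain": self.n_mice_per_strain,
            "schedule": list(self.schedule),
            "group_sizes": list(self.group_sizes) if self.group_sizes else None,
            "strains": [
                {
                    "strain": p.strain,
                    "v_max": p.v_max,
                    "k": p.k,
                    "lag": p.lag,
                    "aspect_sd": p.aspect_sd,
                    "noise_cv": p.noise_cv,
                    "effect_cv": p.effect_cv,
                }
                for p in self.strains
            ],
        }


def default_design(seed: int, **param_overrides) -> CohortDesign:
    """Three-strain, two-mice-per-strain testing cohort (presets)."""
    return CohortDesign(
        strains=tuple(preset(s, **param_overrides) for s in ("nsg", "nsgs", "nude")),
        seed=seed,
    )


def selected_cohort_design(
    seed: int, n_mice: int = 48, n_groups: int = 6, **param_overrides
) -> CohortDesign:
    """Single-strain expanded cohort (default 48 nsg mice in 6 batches)."""
    base, rem = divmod(n_mice, n_groups)
    sizes = tuple(base + (1 if i < rem else 0) for i in range(n_groups))
    return CohortDesign(
        strains=(preset("nsg", **param_overrides),),
        seed=seed,
        n_mice_per_strain=n_mice,
        group_sizes=sizes,
    )


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Simulate a tidy caliper table (semi-axis convention) for a design.

    Per mouse: random effects perturb v_max and k; a persistent ellipsoid
    shape splits each day's true volume into semi-axes ``a >= b >= c``
    with the exact volume preserved; per-day caliper noise multiplies
    each dimension independently.  Reproducible given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.schedule, float)
    group_labels: list[str] = []
    if design.group_sizes:
        for gi, gsize in enumerate(design.group_sizes, start=1):
            group_labels.extend([f"G{gi}"] * gsize)
    rows = []
    mouse_counter = 0
    for params in design.strains:
        for m in range(design.n_mice_per_strain):
            mouse_id = f"{params.strain}-{m + 1:02d}"
            group = (
                group_labels[mouse_counter] if design.group_sizes else "tested"
            )
            mouse_counter += 1
            vmax_i = params.v_max * _lognormal_mean_one(rng, params.effect_cv, None)
            k_i = params.k * _lognormal_mean_one(rng, params.effect_cv, None)
            mouse_params = StrainGrowthParams(
                strain=params.strain,
                v_max=float(vmax_i),
                k=float(k_i),
                lag=params.lag,
                aspect_sd=params.aspect_sd,
                noise_cv=params.noise_cv,
                effect_cv=params.effect_cv,
            )
            # persistent shape: two log aspect ratios, third balances the
            # product so (4/3)*pi*a*b*c reproduces the true volume exactly
            u = rng.normal(0.0, params.aspect_sd, size=2) if params.aspect_sd else np.zeros(2)
            log_shape = np.array([u[0], u[1], -(u[0] + u[1])])
            volumes = growth_trajectory(mouse_params, days)
            radii = (3.0 * volumes / (4.0 * np.pi)) ** (1.0 / 3.0)
            axes = radii[:, None] * np.exp(log_shape)[None, :]
            noise = _lognormal_mean_one(rng, params.noise_cv, axes.shape)
            axes = axes * noise
            for di, day in enumerate(design.schedule):
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "strain": params.strain,
                        "group": group,
                        "day": int(day),
                        "a_cm": axes[di, 0],
                        "b_cm": axes[di, 1],
                        "c_cm": axes[di, 2],
                    }
                )
    return pd.DataFrame(rows, columns=list(CALIPER_COLUMNS))


def generate_histology(
    n_regions: int,
    cells_per_region: int,
    p_strong_control: float,
    p_strong_treated: float,
    seed: int,
    control_label: str = "0W",
    treated_label: str = "30W",
) -> pd.DataFrame:
    """Simulate a region-counts table for a control and a treated section.

    Per region the total cell count Nt is Poisson(``cells_per_region``)
    (floored at 1) and the strongly positive count Nsp is
    Binomial(Nt, p) with the arm's strong-positive probability.
    """
    for name, p in (
        ("p_strong_control", p_strong_control),
        ("p_strong_treated", p_strong_treated),
    ):
        if not 0 <= p <= 1:
            raise ValidationError(f"{name} must be in [0, 1], got {p}")
    if n_regions < 1 or cells_per_region < 1:
        raise ValidationError("n_regions and cells_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for arm, label, p in (
        ("control", control_label, p_strong_control),
        ("treated", treated_label, p_strong_treated),
    ):
        nt = np.maximum(rng.poisson(cells_per_region, size=n_regions), 1)
        nsp = rng.binomial(nt, p)
        for i in range(n_regions):
            rows.append(
                {
                    "section_id": f"sec-{arm}",
                    "region_id": f"{arm}-r{i:03d}",
                    "treatment": label,
                    "n_strong_positive": int(nsp[i]),
                    "n_total": int(nt[i]),
                }
            )
    return pd.DataFrame(rows)
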