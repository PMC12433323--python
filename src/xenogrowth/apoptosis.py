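"""Apoptotic-index quantification from immunohistochemistry region counts.

A stained tumor section (e.g. cleaved caspase 3 for apoptosis) is tiled
into rectangular regions of identical dimensions.  Each region yields a
count of strongly positive cells (Nsp) and total cells (Nt); the
apoptotic index of a region is the ratio Nsr = Nsp / Nt.  Per section,
the k regions (default 3) with the highest Nsr are averaged to give a
hot-spot index, and treatment arms are compared by the percent increase
of the treated index over the control.

This module consumes per-region count tables; pixel-level image
classification happens upstream in slide-analysis software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_TOP_K = 3
DEFAULT_REGION_DIMS_UM = (500.0, 500.0)

#: Required columns of a tidy region-counts table.
REGION_COLUMNS = (
    "section_id",
    "region_id",
    "treatment",
    "n_strong_positive",
    "n_total",
)


@dataclass(frozen=True)
class RegionCounts:
    """Cell counts for one rectangular region of one section."""

    section_id: str
    region_id: str
    treatment: str
    n_strong_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_strong_positive < 0:
            raise ValidationError("counts must be nonnegative")
        if self.n_strong_positive > self.n_total:
            raise ValidationError(
                f"region {self.region_id!r}: Nsp ({self.n_strong_positive}) "
                f"> Nt ({self.n_total})"
            )

    @property
    def nsr(self) -> float:
        return region_nsr(self.n_strong_positive, self.n_total)


@dataclass(frozen=True)
class ApoptoticIndex:
    """Top-k mean Nsr of one section, with the regions that contributed."""

    section_id: str
    nsr_top_k_mean: float
    k: int
    region_ids_used: tuple[str, ...]


def region_nsr(n_strong_positive: int, n_total: int) -> float:
    """Apoptotic index of one region: Nsr = Nsp / Nt, in [0, 1]."""
    if n_total < 1:
        raise ValidationError("Nt must be >= 1 for Nsr to be defined")
    if not 0 <= n_strong_positive <= n_total:
        raise ValidationError(
            f"need 0 <= Nsp <= Nt, got Nsp={n_strong_positive}, Nt={n_total}"
        )
    return n_strong_positive / n_total


def validate_region_table(regions: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a region-counts table; drop (with warning) Nt = 0 rows."""
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValidationError(f"region table missing columns: {missing}")
    regions = regions.copy()
    for col in ("n_strong_positive", "n_total"):
        regions[col] = pd.to_numeric(regions[col], errors="raise").astype(int)
        if (regions[col] < 0).any():
            raise ValidationError(f"{col} must be nonnegative")
    if (regions["n_strong_positive"] > regions["n_total"]).any():
        bad = regions.loc[
            regions["n_strong_positive"] > regions["n_total"], "region_id"
        ].tolist()
        raise ValidationError(f"Nsp > Nt in regions {bad}")
    empty = regions["n_total"] == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} region(s) with Nt = 0", stacklevel=2
        )
        regions = regions.loc[~empty]
    return regions


def top_k_index(
    regions: pd.DataFrame, k: int = DEFAULT_TOP_K, section_id: str | None = None
) -> ApoptoticIndex:
    """Mean of the k largest region Nsr values of one section.

    If fewer than k valid regions exist, all are used (with a warning).
    Ties at the k-th rank are broken by region_id order; the tie-broken
    choice cannot change the mean.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    regions = validate_region_table(regions)
    if regions.empty:
        raise ValidationError("no valid regions (all empty or none supplied)")
    if section_id is None:
        uniq = regions["section_id"].unique()
        if len(uniq) > 1:
            raise ValidationError(
                f"multiple sections present ({uniq.tolist()}); pass section_id"
            )
        section_id = uniq[0]
    else:
        regions = regions.loc[regions["section_id"] == section_id]
        if regions.empty:
            raise ValidationError(f"no regions for section {section_id!r}")
    nsr = regions["n_strong_positive"] / regions["n_total"]
    order = (
        pd.DataFrame({"region_id": regions["region_id"], "nsr": nsr})
        .sort_values(["nsr", "region_id"], ascending=[False, True])
        .head(k)
    )
    if len(order) < k:
        warnings.warn(
            f"section {section_id!r}: only {len(order)} region(s) for top-{k}",
            stacklevel=2,
        )
    return ApoptoticIndex(
        section_id=str(section_id),
        nsr_top_k_mean=float(order["nsr"].mean()),
        k=k,
        region_ids_used=tuple(order["region_id"].astype(str)),
    )


def percent_increase(control_index: float, treated_index: float) -> tuple[float, int]:
    """Relative increase of the treated index over control, in percent.

    Returns (raw percent, integer-rounded percent).  The control index
    must be positive for a relative increase to be defined.
    """
    if not control_index > 0:
        raise ValidationError(
            f"control index must be > 0, got {control_index}"
        )
    raw = 100.0 * (treated_index - control_index) / control_index
    return raw, int(round(raw))


def tile_section(
    section_extent: tuple[float, float],
    region_dims: tuple[float, float] = DEFAULT_REGION_DIMS_UM,
) -> pd.DataFrame:
    """Tile a rectangular section into identical non-overlapping regions.

    Extents and region dimensions are (width, height) in µm.  The grid
    starts at the origin; rectangles are half-open [x0, x1) x [y0, y1).
    Edge rectangles that extend past the section are clipped and flagged
    ``partial`` (their counts are area-biased and excluded from top-k
    selection by default downstream).

    Returns columns ``region_id, x0, y0, x1, y1, partial``.
    """
    width, height = map(float, section_extent)
    rw, rh = map(float, region_dims)
    if width <= 0 or height <= 0 or rw <= 0 or rh <= 0:
        raise ValidationError("section extent and region dims must be positive")
    if rw > width or rh > height:
        raise ValidationError(
            f"region {region_dims} larger than section {section_extent}"
        )
    nx = int(np.ceil(width / rw))
    ny = int(np.ceil(height / rh))
    rows = []
    for j in range(ny):
        for i in range(nx):
            x0, y0 = i * rw, j * rh
            x1, y1 = min(x0 + rw, width), min(y0 + rh, height)
            rows.append(
                {
                    "region_id": f"r{j:02d}_{i:02d}",
                    "x0": x0,
                    "y0": y0,
                    "x1": x1,
                    "y1": y1,
                    "partial": (x1 - x0 < rw) or (y1 - y0 < rh),
                }
            )
    return pd.DataFrame(rows)


def treatment_report(
    regions: pd.DataFrame,
    control_label: str,
    k: int = DEFAULT_TOP_K,
) -> dict:
    """Per-treatment indices and percent increases versus a control arm.

    Each treatment arm's index is the top-k mean over its pooled regions
    (one section per arm in the simplest design; with several sections,
    per-section indices are reported and the arm index is their mean).
    """
    regions = validate_region_table(regions)
    arms = list(dict.fromkeys(regions["treatment"]))
    if control_label not in arms:
        raise ValidationError(
            f"control label {control_label!r} not among treatments {arms}"
        )
    per_section: dict[str, list[dict]] = {}
    arm_index: dict[str, float] = {}
    for arm in arms:
        sub = regions.loc[regions["treatment"] == arm]
        section_indices = [
            top_k_index(sub.loc[sub["section_id"] == sec], k=k)
            for sec in dict.fromkeys(sub["section_id"])
        ]
        per_section[arm] = [
            {
                "section_id": si.section_id,
                "nsr_top_k_mean": si.nsr_top_k_mean,
                "regions_used": list(si.region_ids_used),
            }
            for si in section_indices
        ]
        arm_index[arm] = float(
            np.mean([si.nsr_top_k_mean for si in section_indices])
        )
    increases = {}
    if len(arms) < 2:
        warnings.warn("single treatment arm; no percent increase computed", stacklevel=2)
    else:
        for arm in arms:
            if arm == control_label:
                continue
            raw, rounded = percent_increase(arm_index[control_label], arm_index[arm])
            increases[arm] = {"raw_percent": raw, "percent": rounded}
    return {
        "k": k,
        "control": control_label,
        "index_by_treatment": arm_index,
        "per_section": per_section,
        "percent_increase_vs_control": increases,
    }
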