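"""Composite leukocyte activation parameter (LAP) and cohort summaries.

Leukocyte activation shows up in shadow parameters as a larger PPD (cell
swelling) and a lower MMD-SD (degranulation, rounding).  LAP condenses
both into one dimensionless score anchored at 1 for a control cohort:

    LAP = (PPD / PPD_ref) / (MMD-SD / MMD-SD_ref)

where the reference locations are control-cohort medians (robust against
the heavy-tailed per-cell distributions).  LAP rises strictly with PPD and
falls strictly with MMD-SD, so activated cells score above resting ones on
both axes at once.  An alternative z-score form,
``LAP_z = z_ctrl(PPD) - z_ctrl(MMD-SD)``, is available as a configurable
policy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceStats",
    "CohortSummary",
    "compute_lap",
    "aggregate_cells",
    "normalize_cohorts",
]

_PARAMS = ("ppd", "mmd_sd", "lap")


@dataclass(frozen=True)
class ReferenceStats:
    """Location and scale of a control cohort's PPD and MMD-SD."""

    ppd_location: float
    ppd_scale: float
    mmdsd_location: float
    mmdsd_scale: float
    n_ref: int

    def __post_init__(self) -> None:
        if self.n_ref < 30:
            raise ValueError("reference cohort needs n >= 30 cells")
        if self.ppd_scale <= 0 or self.mmdsd_scale <= 0:
            raise ValueError("reference scales must be positive")
        if self.ppd_location <= 0 or self.mmdsd_location <= 0:
            raise ValueError("reference locations must be positive")

    @classmethod
    def from_cells(cls, cells: pd.DataFrame) -> "ReferenceStats":
        """Median/SD reference from a per-cell table with ``ppd``/``mmd_sd``
        columns (invalid cells excluded)."""
        ppd = cells["ppd"].to_numpy(dtype=float)
        msd = cells["mmd_sd"].to_numpy(dtype=float)
        keep = np.isfinite(ppd) & np.isfinite(msd) & (msd > 0)
        ppd, msd = ppd[keep], msd[keep]
        return cls(ppd_location=float(np.median(ppd)),
                   ppd_scale=float(np.std(ppd, ddof=1)),
                   mmdsd_location=float(np.median(msd)),
                   mmdsd_scale=float(np.std(msd, ddof=1)),
                   n_ref=int(keep.sum()))


@dataclass
class CohortSummary:
    """Per-group means, SDs and cell counts for the shadow parameters."""

    label: str
    n_cells: int
    mean: dict[str, float]
    sd: dict[str, float]
    n_lap: int = 0
    normalized_mean: dict[str, float] | None = None
    normalized_sd: dict[str, float] | None = None


def compute_lap(ppd: float, mmd_sd: float, ref: ReferenceStats,
                variant: Literal["ratio", "zscore"] = "ratio") -> float:
    """Per-cell LAP from its PPD and MMD-SD against a control reference.

    NaN (undefined, to be excluded listwise from LAP summaries) when the
    inputs are not finite positive quantities.
    """
    if not (math.isfinite(ppd) and math.isfinite(mmd_sd)) or mmd_sd <= 0 \
            or ppd <= 0:
        return math.nan
    if variant == "ratio":
        return (ppd / ref.ppd_location) / (mmd_sd / ref.mmdsd_location)
    if variant == "zscore":
        return ((ppd - ref.ppd_location) / ref.ppd_scale
                - (mmd_sd - ref.mmdsd_location) / ref.mmdsd_scale)
    raise ValueError(f"unknown LAP variant {variant!r}")


def attach_lap(cells: pd.DataFrame, ref: ReferenceStats,
               variant: Literal["ratio", "zscore"] = "ratio") -> pd.DataFrame:
    """Return a copy of the per-cell table with a ``lap`` column."""
    out = cells.copy()
    out["lap"] = [compute_lap(p, m, ref, variant)
                  for p, m in zip(out["ppd"], out["mmd_sd"])]
    return out


def aggregate_cells(cells: pd.DataFrame,
                    grouping: str = "group") -> list[CohortSummary]:
    """Group-level mean/SD/n for each shadow parameter.

    Cells with undefined (NaN) values are excluded per parameter; counts
    of exclusions are logged.  A single-cell group reports SD as NaN.
    """
    summaries: list[CohortSummary] = []
    for label, grp in cells.groupby(grouping, sort=False):
        if len(grp) == 0:
            logger.warning("group %s is empty; dropped", label)
            continue
        mean: dict[str, float] = {}
        sd: dict[str, float] = {}
        n_lap = 0
        for par in _PARAMS:
            if par not in grp:
                continue
            vals = grp[par].to_numpy(dtype=float)
            good = vals[np.isfinite(vals)]
            n_bad = len(vals) - len(good)
            if n_bad:
                logger.info("group %s: %d cells lack %s", label, n_bad, par)
            if par == "lap":
                n_lap = len(good)
            if len(good) == 0:
                mean[par], sd[par] = math.nan, math.nan
            else:
                mean[par] = float(np.mean(good))
                sd[par] = float(np.std(good, ddof=1)) if len(good) > 1 else math.nan
        summaries.append(CohortSummary(label=str(label), n_cells=len(grp),
                                       mean=mean, sd=sd, n_lap=n_lap))
    return summaries


def normalize_cohorts(groups: list[CohortSummary],
                      control_label: str) -> list[CohortSummary]:
    """Scale each group's means by the control group's means.

    The control maps to 1.0 for every parameter; SDs are scaled by the
    same factor, so normalization is idempotent and invariant under a
    global rescaling of the raw values.
    """
    control = next((g for g in groups if g.label == control_label), None)
    if control is None:
        raise ValueError(f"control group {control_label!r} not found")
    if control.n_cells < 30:
        raise ValueError("control group needs n >= 30 cells")
    for g in groups:
        g.normalized_mean = {}
        g.normalized_sd = {}
        for par, ctrl_mean in control.mean.items():
            if not math.isfinite(ctrl_mean) or ctrl_mean == 0:
                g.normalized_mean[par] = math.nan
                g.normalized_sd[par] = math.nan
                continue
            g.normalized_mean[par] = g.mean.get(par, math.nan) / ctrl_mean
            g.normalized_sd[par] = g.sd.get(par, math.nan) / abs(ctrl_mean)
    return groups
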