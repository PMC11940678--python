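"""Cohort statistics, reproducibility QC and pinhole calibration curves.

Group comparisons follow imaging-cytometry practice: the two-sided
non-parametric Mann-Whitney U test with the usual significance-star
convention (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).  Inter-
channel reproducibility is summarised as the coefficient of variation of
per-channel mean parameters.  Bivariate PPD x MMD-SD populations are
summarised as 2D histograms with mean/covariance concentration ellipses.
The pinhole calibration sweep reproduces the mean-gray-value analysis
used to pick the aperture diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .optics import ApertureSpec, OpticsConfig, simulate_illumination, \
    illumination_sensor_view

__all__ = [
    "StatResult",
    "DensitySummary",
    "CalibrationCurve",
    "mann_whitney_u",
    "stars",
    "cov_percent",
    "density_summary",
    "pinhole_sweep",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of a two-sided Mann-Whitney U comparison."""

    u_statistic: float                  # min(U1, U2)
    p_value: float
    method: Literal["exact", "normal-approx"]
    n1: int
    n2: int
    stars: str
    flags: tuple[str, ...] = ()


@dataclass
class DensitySummary:
    """2D histogram plus concentration ellipse of a PPD x MMD-SD cloud."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    mean: np.ndarray | None             # (mean_x, mean_y)
    covariance: np.ndarray | None       # 2x2
    level: float                        # ellipse radius in sigma units
    ellipse_axes: tuple[float, float] | None = None   # semi-axes
    ellipse_angle: float | None = None                # rad, major axis
    flags: tuple[str, ...] = ()


@dataclass
class CalibrationCurve:
    """Mean-gray / uniformity response of the pinhole-diameter sweep."""

    diameters: list[float]              # um, strictly increasing
    mean_gray: list[float]              # gray levels, central sensor region
    gray_sd: list[float]
    uniformity: list[float]             # SD/mean of the central region

    def as_records(self) -> list[dict]:
        return [
            {"diameter_um": d, "mean_gray": m, "gray_sd": s, "uniformity": u}
            for d, m, s, u in zip(self.diameters, self.mean_gray,
                                  self.gray_sd, self.uniformity)
        ]


# ---------------------------------------------------------------------------
# hypothesis testing
# ---------------------------------------------------------------------------

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def stars(p_value: float) -> str:
    """Significance label with the strict (<) caption thresholds."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    for thr, label in _STAR_THRESHOLDS:
        if p_value < thr:
            return label
    return "ns"


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float],
                   mode: Literal["auto", "exact", "approx"] = "auto"
                   ) -> StatResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses the exact null distribution when min(n1, n2) <= 8 and
    the pooled data carry no ties, else the normal approximation with tie
    and continuity corrections.  The reported U is min(U1, U2).  Two
    identical constant samples are degenerate: U is n1*n2/2 and p = 1,
    flagged ``degenerate``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return StatResult(u_statistic=n1 * n2 / 2.0, p_value=1.0,
                          method="normal-approx", n1=n1, n2=n2,
                          stars=stars(1.0), flags=("degenerate",))
    if mode == "exact" or (mode == "auto" and min(n1, n2) <= 8 and not has_ties):
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        method, label = "exact", "exact"
    else:
        method, label = "asymptotic", "normal-approx"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    p = float(min(res.pvalue, 1.0))
    return StatResult(u_statistic=u, p_value=p, method=label,
                      n1=n1, n2=n2, stars=stars(p))


def cov_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 x sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mean = v.mean()
    if abs(mean) < 1e-12 * max(v.std(), 1.0) or mean == 0:
        raise ValueError("CoV undefined for near-zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# density summaries
# ---------------------------------------------------------------------------

def density_summary(ppd: Sequence[float], mmd_sd: Sequence[float],
                    bins: int | tuple[int, int] = 40,
                    level: float = 2.0,
                    ranges=None) -> DensitySummary:
    """2D histogram and concentration ellipse of paired per-cell values.

    The ellipse is centred on the sample mean with semi-axes ``level``
    (default 2 sigma) times the square roots of the covariance
    eigenvalues; a degenerate covariance omits the ellipse and flags the
    summary.
    """
    x = np.asarray(ppd, dtype=float)
    y = np.asarray(mmd_sd, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("density summary needs >= 10 paired values")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges)
    mean = np.array([x.mean(), y.mean()])
    cov = np.cov(np.vstack([x, y]), ddof=1)
    flags: tuple[str, ...] = ()
    axes = angle = None
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or not np.all(np.isfinite(evals)):
        flags = ("degenerate_covariance",)
    else:
        axes = (level * math.sqrt(evals[1]), level * math.sqrt(evals[0]))
        major = evecs[:, 1]
        angle = math.atan2(major[1], major[0])
    return DensitySummary(x_edges=xe, y_edges=ye, counts=counts,
                          mean=mean, covariance=cov, level=level,
                          ellipse_axes=axes, ellipse_angle=angle,
                          flags=flags)


# ---------------------------------------------------------------------------
# pinhole calibration sweep
# ---------------------------------------------------------------------------

def pinhole_sweep(diameters: Sequence[float], cfg: OpticsConfig | None = None,
                  seed: int = 0, n_source_points: int = 16,
                  target_gray: float | None = None,
                  edge_roughness: float = 0.0) -> CalibrationCurve:
    """Background-illumination response across pinhole diameters.

    For each diameter the sample-plane illumination is simulated and the
    sensor's central 50 % x 50 % crop summarised: mean gray value (the
    radiance-limited plateau maps to ``target_gray``, default 70 % of
    full scale), its SD, and the uniformity metric SD/mean.
    """
    cfg = OpticsConfig() if cfg is None else cfg
    diams = [float(d) for d in diameters]
    if any(d2 <= d1 for d1, d2 in zip(diams, diams[1:])):
        raise ValueError("diameters must be strictly increasing")
    grid_dx = 2.0
    if min(diams) < 2 * grid_dx:
        raise ValueError(
            f"smallest diameter {min(diams):.0f} um is below twice the "
            f"{grid_dx} um source sampling step")
    if target_gray is None:
        target_gray = 0.7 * ((1 << cfg.bit_depth) - 1)
    mean_gray, gray_sd, uniformity = [], [], []
    for k, d in enumerate(diams):
        ap = ApertureSpec(diameter=d, edge_roughness_amplitude=edge_roughness,
                          seed=seed + k)
        illum = simulate_illumination(cfg, ap, n_source_points=n_source_points,
                                      seed=seed, grid_dx=grid_dx)
        view = illumination_sensor_view(illum, cfg)
        rows, cols = view.shape
        crop = view[rows // 4:rows - rows // 4, cols // 4:cols - cols // 4]
        gray = np.clip(crop * target_gray, 0, (1 << cfg.bit_depth) - 1)
        mean_gray.append(float(gray.mean()))
        gray_sd.append(float(gray.std()))
        uniformity.append(float(gray.std() / gray.mean()))
    return CalibrationCurve(diameters=diams, mean_gray=mean_gray,
                            gray_sd=gray_sd, uniformity=uniformity)
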