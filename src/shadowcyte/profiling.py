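"""Radial profiling of shadow patterns and the per-cell shadow parameters.

The shadow pattern a cell casts on the sensor is sampled along equally
spaced rays from its sub-pixel centre.  Each ray's intensity profile is
smoothed with a local quadratic filter and its alternating maxima/minima
are located with sub-sample (parabolic) refinement.  From the per-ray
extrema the module computes the shadow parameters of lens-free imaging
cytometry:

PPD     peak-to-peak distance: the distance between the two dominant
        intensity peaks flanking the pattern centre, averaged over
        diameters (pairs of opposite rays).  PPD correlates linearly
        with object size.
MMD     maxima-to-minima distance: the radial distance from the principal
        peak to the adjacent minimum, per ray.  MMD tracks internal
        complexity.
MMD-SD  standard deviation of MMD across ray directions: low for circular
        patterns, high for elongated ones — a shape proxy.

A Tenengrad (mean squared gradient) sharpness score summarises ring
contrast, used for aperture-quality QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import savgol_filter

from .detection import PatternROI

__all__ = [
    "ProfilingConfig",
    "RadialProfileSet",
    "ShadowParams",
    "radial_profiles",
    "find_extrema",
    "compute_ppd",
    "compute_mmd",
    "compute_mmd_sd",
    "sharpness",
    "extract_params",
]

_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class ProfilingConfig:
    """Parameters of profile extraction and extremum search."""

    n_angles: int = 36                  # rays; must be even for diameters
    radial_step_px: float = 0.5
    r_min_px: float = 2.0               # exclude the centre lobe apex
    r_max_px: float | None = None       # default: ROI window radius
    smooth_window: int = 5              # samples, local quadratic
    smooth_poly: int = 2
    prominence_mad: float = 3.0         # extremum floor, noise-MAD units
    mmd_search_px: float = 4.0          # outward window for the MMD minimum
    quorum: int = 8                     # min valid rays for a valid cell
    peak_mode: Literal["principal", "first"] = "principal"
    mmd_reference: Literal["ring", "center"] = "ring"
    report_units: Literal["um", "px"] = "um"

    def __post_init__(self) -> None:
        if self.n_angles < 8 or self.n_angles % 2:
            raise ValueError("n_angles must be even and >= 8")
        if self.radial_step_px > 0.5:
            raise ValueError("radial step must be <= 0.5 px")
        if self.smooth_window % 2 == 0:
            raise ValueError("smoothing window must be odd")


@dataclass
class RadialProfileSet:
    """Intensity along rays from a common sub-pixel centre.

    All rays share one radial grid (``radii_px``); ``raw`` and ``smoothed``
    are (n_angles, n_radii) arrays; rays that exited the usable window are
    marked invalid.
    """

    angles: np.ndarray
    radii_px: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    center: tuple[float, float]
    pixel_pitch: float
    valid: np.ndarray                   # per-ray bool
    noise_scale: float                  # robust per-sample noise estimate


@dataclass
class ShadowParams:
    """The per-cell shadow feature vector."""

    ppd: float = math.nan               # um (or px per config)
    mmd_per_angle: list[float] = field(default_factory=list)
    mmd_mean: float = math.nan
    mmd_sd: float = math.nan
    lap: float = math.nan               # filled by activation metrics
    sharpness: float = math.nan
    n_valid_angles: int = 0
    valid: bool = False
    flags: list[str] = field(default_factory=list)


def radial_profiles(roi: PatternROI, n_angles: int = 36,
                    cfg: ProfilingConfig | None = None) -> RadialProfileSet:
    """Bilinear radial resampling of an ROI along ``n_angles`` rays."""
    cfg = cfg or ProfilingConfig(n_angles=n_angles)
    if n_angles != cfg.n_angles:
        cfg = ProfilingConfig(**{**cfg.__dict__, "n_angles": n_angles})
    img = roi.image.as_float()
    r_max = cfg.r_max_px if cfg.r_max_px is not None else float(roi.window_radius)
    radii = np.arange(0.0, r_max + 1e-9, cfg.radial_step_px)
    angles = np.arange(cfg.n_angles) * (2.0 * np.pi / cfg.n_angles)
    ci, cj = roi.center
    rows = ci + np.outer(np.sin(angles), radii)
    cols = cj + np.outer(np.cos(angles), radii)
    inside = ((rows >= 0) & (rows <= img.shape[0] - 1)
              & (cols >= 0) & (cols <= img.shape[1] - 1))
    raw = map_coordinates(img, [rows, cols], order=1, mode="nearest")
    valid = inside.all(axis=1)
    window = min(cfg.smooth_window, len(radii) // 2 * 2 - 1)
    smoothed = savgol_filter(raw, window, cfg.smooth_poly, axis=1)
    # robust noise estimate from the residual of smoothing
    resid = raw - smoothed
    noise = float(np.median(np.abs(resid - np.median(resid))) * _MAD_TO_SD)
    return RadialProfileSet(angles=angles, radii_px=radii, raw=raw,
                            smoothed=smoothed, center=(float(ci), float(cj)),
                            pixel_pitch=roi.image.pixel_pitch,
                            valid=valid, noise_scale=max(noise, 1e-12))


def find_extrema(radii: np.ndarray, values: np.ndarray,
                 noise_floor: float = 0.0) -> list[tuple[float, str, float]]:
    """Alternating extrema of one (smoothed) radial profile.

    Extrema are located by sign changes of the first differences; adjacent
    max/min pairs whose amplitude gap falls below ``noise_floor`` are
    cancelled (smallest gap first), which removes noise wiggles while
    preserving alternation.  Surviving extrema get parabolic sub-sample
    refinement.  Returns ``(radius, "max"|"min", intensity)`` ordered by
    radius; an empty list means the ray carries no usable structure.
    """
    v = np.asarray(values, dtype=float)
    d = np.diff(v)
    idx: list[int] = []
    kinds: list[str] = []
    prev = 0.0
    for i in range(len(d)):
        if d[i] == 0:
            continue
        if prev > 0 and d[i] < 0:
            idx.append(i)
            kinds.append("max")
        elif prev < 0 and d[i] > 0:
            idx.append(i)
            kinds.append("min")
        prev = d[i]
    # cancel low-contrast adjacent pairs
    while len(idx) > 1:
        gaps = [abs(v[idx[k + 1]] - v[idx[k]]) for k in range(len(idx) - 1)]
        k = int(np.argmin(gaps))
        if gaps[k] >= noise_floor:
            break
        del idx[k:k + 2]
        del kinds[k:k + 2]
    if idx and noise_floor > 0 and len(idx) == 1:
        # a lone extremum must still clear the floor against the endpoints
        k = idx[0]
        if max(abs(v[k] - v[0]), abs(v[k] - v[-1])) < noise_floor:
            return []
    out = []
    for k, kind in zip(idx, kinds):
        r, val = radii[k], v[k]
        if 0 < k < len(v) - 1:
            denom = v[k - 1] - 2 * v[k] + v[k + 1]
            if denom != 0:
                delta = 0.5 * (v[k - 1] - v[k + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                r = radii[k] + delta * (radii[min(k + 1, len(radii) - 1)] - radii[k])
                val = v[k] - 0.25 * (v[k - 1] - v[k + 1]) * delta
        out.append((float(r), kind, float(val)))
    return out


def _ray_peak(extrema: list[tuple[float, str, float]], r_min: float,
              mode: str) -> tuple[float, float] | None:
    """Radius and intensity of the ray's reference peak."""
    maxima = [(r, v) for r, kind, v in extrema if kind == "max" and r >= r_min]
    if not maxima:
        return None
    if mode == "first":
        return maxima[0]
    return max(maxima, key=lambda t: t[1])


def _ray_extrema(profiles: RadialProfileSet,
                 cfg: ProfilingConfig) -> list[list[tuple[float, str, float]]]:
    floor = cfg.prominence_mad * profiles.noise_scale
    return [find_extrema(profiles.radii_px, profiles.smoothed[k], floor)
            if profiles.valid[k] else []
            for k in range(len(profiles.angles))]


def compute_ppd(profiles: RadialProfileSet,
                cfg: ProfilingConfig | None = None) -> float:
    """Peak-to-peak distance: mean over diameters of the summed peak radii
    of opposite rays.  NaN when fewer than ``quorum`` rays carry a peak."""
    cfg = cfg or ProfilingConfig()
    extrema = _ray_extrema(profiles, cfg)
    n = len(profiles.angles)
    peaks = [(_ray_peak(e, cfg.r_min_px, cfg.peak_mode)) for e in extrema]
    n_valid = sum(p is not None for p in peaks)
    if n_valid < cfg.quorum:
        return math.nan
    pairs = []
    for k in range(n // 2):
        a, b = peaks[k], peaks[k + n // 2]
        if a is not None and b is not None:
            pairs.append(a[0] + b[0])
    if not pairs:
        return math.nan
    ppd_px = float(np.mean(pairs))
    scale = profiles.pixel_pitch if cfg.report_units == "um" else 1.0
    return ppd_px * scale


def compute_mmd(profiles: RadialProfileSet,
                cfg: ProfilingConfig | None = None
                ) -> tuple[list[float], float]:
    """Per-ray maxima-to-minima distances and their mean.

    With ``mmd_reference="ring"`` (default) the distance runs from the
    ray's reference peak to the adjacent outward minimum, sought within
    ``mmd_search_px`` of the peak; when no prominent local minimum
    survives the noise filter there, the lowest point of the smoothed
    segment is used so that a shallow adjacent dip still yields a bounded
    distance.  ``"center"`` measures from the pattern centre to the first
    minimum instead.
    """
    cfg = cfg or ProfilingConfig()
    extrema = _ray_extrema(profiles, cfg)
    radii = profiles.radii_px
    scale = profiles.pixel_pitch if cfg.report_units == "um" else 1.0
    mmd: list[float] = []
    for k, e in enumerate(extrema):
        if not e:
            mmd.append(math.nan)
            continue
        if cfg.mmd_reference == "center":
            minima = [r for r, kind, _ in e if kind == "min" and r >= cfg.r_min_px]
            mmd.append(minima[0] * scale if minima else math.nan)
            continue
        peak = _ray_peak(e, cfg.r_min_px, cfg.peak_mode)
        if peak is None:
            mmd.append(math.nan)
            continue
        r_hi = peak[0] + cfg.mmd_search_px
        if r_hi > radii[-1] + 1e-9:
            r_hi = float(radii[-1])
            if r_hi - peak[0] < cfg.mmd_search_px / 2:
                mmd.append(math.nan)
                continue
        outward = [r for r, kind, _ in e
                   if kind == "min" and peak[0] < r <= r_hi]
        if outward:
            mmd.append((outward[0] - peak[0]) * scale)
            continue
        # no prominent minimum: lowest point of the smoothed segment
        seg = (radii > peak[0]) & (radii <= r_hi)
        if not seg.any():
            mmd.append(math.nan)
            continue
        vals = profiles.smoothed[k][seg]
        rr = radii[seg]
        j = int(np.argmin(vals))
        r_min_loc = rr[j]
        if 0 < j < len(vals) - 1:
            denom = vals[j - 1] - 2 * vals[j] + vals[j + 1]
            if denom != 0:
                delta = float(np.clip(
                    0.5 * (vals[j - 1] - vals[j + 1]) / denom, -0.5, 0.5))
                r_min_loc = rr[j] + delta * (rr[1] - rr[0])
        mmd.append((r_min_loc - peak[0]) * scale)
    arr = np.array(mmd, dtype=float)
    good = arr[~np.isnan(arr)]
    mean = float(good.mean()) if len(good) >= cfg.quorum else math.nan
    return mmd, mean


def compute_mmd_sd(mmd_per_angle: list[float], quorum: int = 8) -> float:
    """Sample standard deviation of per-ray MMD; NaN below quorum."""
    arr = np.array(mmd_per_angle, dtype=float)
    good = arr[~np.isnan(arr)]
    if len(good) < max(quorum, 2):
        return math.nan
    return float(good.std(ddof=1))


def sharpness(roi: PatternROI) -> float:
    """Tenengrad sharpness: mean squared gradient magnitude of the ROI
    window normalized to [0, 1] by the sensor's full gray scale."""
    from scipy.ndimage import sobel

    win = roi.window().astype(float)
    if win.max() <= win.min():
        return 0.0
    win = win / float((1 << roi.image.bit_depth) - 1)
    gx = sobel(win, axis=1) / 8.0
    gy = sobel(win, axis=0) / 8.0
    return float(np.mean(gx ** 2 + gy ** 2))


def extract_params(roi: PatternROI,
                   cfg: ProfilingConfig | None = None) -> ShadowParams:
    """Full shadow-parameter vector of one detected pattern."""
    cfg = cfg or ProfilingConfig()
    profiles = radial_profiles(roi, cfg.n_angles, cfg)
    params = ShadowParams()
    params.ppd = compute_ppd(profiles, cfg)
    params.mmd_per_angle, params.mmd_mean = compute_mmd(profiles, cfg)
    good = [m for m in params.mmd_per_angle if not math.isnan(m)]
    params.n_valid_angles = len(good)
    params.mmd_sd = compute_mmd_sd(params.mmd_per_angle, cfg.quorum)
    params.sharpness = sharpness(roi)
    params.valid = (not math.isnan(params.ppd) and params.ppd > 0
                    and params.n_valid_angles >= cfg.quorum)
    if not params.valid:
        params.flags.append("quorum" if params.n_valid_angles < cfg.quorum
                            else "no_peak")
    if "degenerate" in roi.flags:
        params.flags.append("degenerate_center")
    return params
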