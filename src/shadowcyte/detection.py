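"""Detection of individual shadow (diffraction) patterns in a wide field.

A wide-field frame from a lens-free imager contains up to ~1000
non-overlapping ring patterns, one per cell.  Candidate centres are found
by a multi-scale Laplacian-of-Gaussian blob response tuned to the expected
central-lobe radius; the response polarity is rectified so both
bright-centre (phase-dominant) and dark-centre (absorbing) patterns are
found.  Scores are expressed in robust noise units (median absolute
deviation of the response) and candidates closer than a minimum separation
are suppressed, keeping the stronger one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import ShadowImage

logger = logging.getLogger(__name__)

__all__ = ["DetectionConfig", "PatternROI", "detect_patterns", "refine_center"]

_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the blob detector.

    ``expected_ppd_um`` is the anticipated peak-to-peak distance of the
    patterns; the LoG scales and the minimum separation are derived from
    it unless overridden.
    """

    expected_ppd_um: float = 24.0
    scale_factors: tuple[float, ...] = (0.7, 1.0, 1.4)
    threshold_mad: float = 8.0          # score floor, response-MAD units
    min_separation_px: float | None = None   # default 1.5 x expected PPD
    window_radius_px: int = 16
    refine_radius_px: float = 3.0       # bound on sub-pixel refinement

    def sigmas(self, pixel_pitch: float) -> tuple[float, ...]:
        # central lobe radius ~ half the PPD; LoG responds maximally when
        # sigma ~ radius / sqrt(2)
        r_px = self.expected_ppd_um / 2.0 / pixel_pitch
        return tuple(max(f * r_px / math.sqrt(2.0), 1.0)
                     for f in self.scale_factors)

    def min_sep(self, pixel_pitch: float) -> float:
        if self.min_separation_px is not None:
            return self.min_separation_px
        return 1.5 * self.expected_ppd_um / pixel_pitch


@dataclass
class PatternROI:
    """One detected pattern: sub-pixel centre plus its analysis window."""

    center: tuple[float, float]         # (row, col), sub-pixel
    window_radius: int                  # px
    score: float                        # detection score, MAD units
    image: ShadowImage
    flags: list[str] = field(default_factory=list)

    def window(self) -> np.ndarray:
        """The square pixel window around the (rounded) centre."""
        r = self.window_radius
        i = int(round(self.center[0]))
        j = int(round(self.center[1]))
        return self.image.as_float()[i - r:i + r + 1, j - r:j + r + 1]


def _log_response(img: np.ndarray, sigmas: tuple[float, ...]) -> np.ndarray:
    """Scale-normalized, polarity-rectified LoG response (max over scales)."""
    resp = None
    for s in sigmas:
        r = np.abs(ndimage.gaussian_laplace(img, s)) * s ** 2
        resp = r if resp is None else np.maximum(resp, r)
    return resp


def detect_patterns(image: ShadowImage,
                    params: DetectionConfig | None = None) -> list[PatternROI]:
    """Locate candidate shadow patterns in one frame.

    Returns ROIs sorted by descending score.  An empty list is a valid
    result for a blank or noise-only frame.
    """
    params = params or DetectionConfig()
    img = image.as_float()
    img = img / max(img.max(), 1.0)      # intensity-scale invariant
    resp = _log_response(img, params.sigmas(image.pixel_pitch))
    med = np.median(resp)
    mad = np.median(np.abs(resp - med)) * _MAD_TO_SD
    if mad <= 0:
        mad = resp.std() if resp.std() > 0 else 1.0
    score_map = (resp - med) / mad
    min_sep = params.min_sep(image.pixel_pitch)
    # local maxima of the response above the robust threshold
    footprint = ndimage.maximum_filter(resp, size=int(max(3, round(min_sep))))
    peaks = (resp == footprint) & (score_map > params.threshold_mad)
    coords = np.argwhere(peaks)
    scores = score_map[peaks]
    order = np.argsort(scores)[::-1]
    coords, scores = coords[order], scores[order]
    # greedy non-maximum suppression at min_sep (maximum_filter is square;
    # enforce the euclidean criterion too)
    kept: list[tuple[np.ndarray, float]] = []
    for c, s in zip(coords, scores):
        if all(np.hypot(*(c - k)) >= min_sep for k, _ in kept):
            kept.append((c, s))
    rois: list[PatternROI] = []
    r = params.window_radius_px
    n_border = 0
    for c, s in kept:
        if (c[0] < r or c[1] < r or c[0] >= img.shape[0] - r
                or c[1] >= img.shape[1] - r):
            n_border += 1
            continue
        roi = PatternROI(center=(float(c[0]), float(c[1])),
                         window_radius=r, score=float(s), image=image)
        refine_center(roi, params)
        rois.append(roi)
    if n_border:
        logger.info("dropped %d detections whose window exits the frame",
                    n_border)
    return rois


def _centroid_estimate(win: np.ndarray, sigma: float) -> tuple[float, float]:
    """Intensity-weighted centroid of the rectified deviation map."""
    dev = np.abs(ndimage.gaussian_filter(win - np.median(win), sigma))
    ny, nx = dev.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    tot = dev.sum()
    if tot <= 0:
        return ((ny - 1) / 2.0, (nx - 1) / 2.0)
    return (float((dev * yy).sum() / tot), float((dev * xx).sum() / tot))


def refine_center(roi: PatternROI,
                  params: DetectionConfig | None = None) -> tuple[float, float]:
    """Refine an ROI centre to sub-pixel precision, in place.

    Shadow patterns are centro-symmetric to good approximation, so the
    centre is located at half the lag of the peak of the window's
    autoconvolution (correlation with its own 180-degree rotation), with a
    parabolic sub-sample fit on the peak.  This uses every ring of the
    pattern and is insensitive to whether the pattern centre is bright or
    dark.  Refinement is bounded by ``refine_radius_px`` around the
    initial estimate; when the symmetry peak is not significant or not
    concave (e.g. a pure-noise window) the intensity-weighted centroid is
    kept and the ROI is flagged ``degenerate``.
    """
    from numpy.fft import fft2, fftshift, ifft2

    params = params or DetectionConfig()
    img = roi.image.as_float()
    r0 = roi.center
    rad = roi.window_radius
    i0, j0 = int(round(r0[0])), int(round(r0[1]))
    win = img[i0 - rad:i0 + rad + 1, j0 - rad:j0 + rad + 1]
    n = win.shape[0]
    w = win - np.median(win)
    yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2.0
    w = w * np.exp(-0.5 * (np.hypot(yy, xx) / (0.45 * n)) ** 6)
    conv = fftshift(ifft2(fft2(w) ** 2).real)
    med = np.median(conv)
    mad = np.median(np.abs(conv - med)) * _MAD_TO_SD
    peak = np.unravel_index(np.argmax(conv), conv.shape)
    significant = mad > 0 and (conv[peak] - med) / mad > 10.0
    sigma = params.sigmas(roi.image.pixel_pitch)[0] / 2.0
    if not significant:
        ci, cj = _centroid_estimate(win, sigma)
        roi.flags.append("degenerate")
    else:
        est = []
        concave = True
        for axis, k in enumerate(peak):
            sl = conv[:, peak[1]] if axis == 0 else conv[peak[0], :]
            delta = 0.0
            if 0 < k < n - 1:
                curv = sl[k + 1] + sl[k - 1] - 2 * sl[k]
                if curv < 0:
                    delta = float(np.clip(
                        0.5 * (sl[k - 1] - sl[k + 1]) / curv, -0.5, 0.5))
                else:
                    concave = False
            lag = (k + delta - n // 2) % n
            cands = (lag / 2.0, (lag + n) / 2.0, (lag - n) / 2.0)
            est.append(min(cands, key=lambda t: abs(t - (n - 1) / 2.0)))
        if concave:
            ci, cj = est
        else:
            ci, cj = _centroid_estimate(win, sigma)
            roi.flags.append("degenerate")
    new = (i0 - rad + ci, j0 - rad + cj)
    lim = params.refine_radius_px
    if abs(new[0] - r0[0]) > lim or abs(new[1] - r0[1]) > lim:
        roi.flags.append("refine_bound")
        new = (float(np.clip(new[0], r0[0] - lim, r0[0] + lim)),
               float(np.clip(new[1], r0[1] - lim, r0[1] + lim)))
    roi.center = (float(new[0]), float(new[1]))
    return roi.center
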