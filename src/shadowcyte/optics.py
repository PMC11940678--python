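"""Forward optical model for a lens-free shadow imaging channel.

A single channel consists of an LED die behind a circular pinhole aperture.
The pinhole turns the spatially incoherent LED emission into semi-coherent
illumination; micro-objects in the sample chamber sit close to a bare CMOS
sensor and project diffraction ("shadow") patterns onto it.  This module
simulates that chain: aperture masks (ideal wet-etched discs or rough
drilled openings), band-limited angular-spectrum free-space propagation,
partially coherent illumination, and full scene rendering with a shot /
read noise model, down to quantized 8- or 16-bit sensor frames.

All lengths are expressed in micrometres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2

logger = logging.getLogger(__name__)

__all__ = [
    "OpticsConfig",
    "ApertureSpec",
    "CellPhantom",
    "Scene",
    "ShadowImage",
    "IlluminationField",
    "make_aperture_mask",
    "propagate",
    "simulate_illumination",
    "render_shadow_image",
    "simulate_channel_run",
    "ChannelPerturbation",
    "bead_phantom",
    "leukocyte_phantom",
    "random_scene",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition geometry and sensor model of one imaging channel.

    Distances and pixel pitch of the physical device are not public; the
    defaults below are physically consistent placeholders chosen so that a
    300 um pinhole produces high-contrast shadow patterns (coherence width
    at the sample well above the pattern size, source-blur at the sensor
    below one pixel).  Every value is configurable.
    """

    wavelength: float = 0.470           # um (470 nm blue LED)
    pinhole_diameter: float = 300.0     # um
    source_diameter: float = 150.0      # um, LED die treated as incoherent disc
    source_to_pinhole: float = 10_000.0  # um
    pinhole_to_sample: float = 20_000.0  # um
    sample_to_sensor: float = 150.0     # um
    pixel_pitch: float = 2.2            # um
    sensor_shape: tuple[int, int] = (384, 384)
    bit_depth: int = 8
    photon_scale: float = 20_000.0      # photons per unit relative intensity
    read_noise_sd: float = 1.0          # gray levels
    illumination_gain: float = 1.0      # per-channel relative gain
    oversample: int = 2                 # simulation grid refinement vs pitch
    n_coherence_points: int = 16        # pinhole points for partial coherence

    def __post_init__(self) -> None:
        for name in ("wavelength", "pinhole_diameter", "source_diameter",
                     "source_to_pinhole", "pinhole_to_sample",
                     "sample_to_sensor", "pixel_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        rows, cols = self.sensor_shape
        if rows < 64 or cols < 64:
            raise ValueError("sensor_shape components must be >= 64")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.illumination_gain <= 0:
            raise ValueError("illumination_gain must be positive")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")

    # -- derived geometry ---------------------------------------------------
    @property
    def grid_dx(self) -> float:
        """Sample-plane simulation grid step (um)."""
        return self.pixel_pitch / self.oversample

    @property
    def field_extent(self) -> tuple[float, float]:
        """Physical size (height, width) of the sensor footprint (um)."""
        return (self.sensor_shape[0] * self.pixel_pitch,
                self.sensor_shape[1] * self.pixel_pitch)

    @property
    def max_gray(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def pattern_magnification(self) -> float:
        """Projective magnification of a sample point onto the sensor.

        Illumination diverges from an effective source one pinhole-to-sample
        distance (plus LED standoff) behind the sample.
        """
        src = self.source_to_pinhole + self.pinhole_to_sample
        return (src + self.sample_to_sensor) / src

    @property
    def coherence_blur_scale(self) -> float:
        """Shadow-pattern displacement per unit pinhole-point offset."""
        return self.sample_to_sensor / self.pinhole_to_sample


@dataclass(frozen=True)
class ApertureSpec:
    """Circular pinhole aperture with optional rough (drilled) edge.

    ``edge_roughness_amplitude`` is the maximum radial boundary excursion;
    zero models a wet-etched aperture with a clean circular rim.
    ``edge_roughness_correlation`` is the angular correlation scale of the
    boundary perturbation in radians.
    """

    diameter: float
    edge_roughness_amplitude: float = 0.0
    edge_roughness_correlation: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not (0 <= self.edge_roughness_amplitude < self.diameter / 2):
            raise ValueError("roughness amplitude must be in [0, diameter/2)")
        if self.edge_roughness_correlation <= 0:
            raise ValueError("roughness correlation scale must be positive")


@dataclass(frozen=True)
class CellPhantom:
    """Ground-truth description of one micro-object on the sample plane.

    The object is a thin transmission element: an elliptical footprint with
    smooth edges, uniform amplitude transmittance and phase retardation,
    plus a band-limited random phase texture ("granularity") standing in
    for internal structure.  Leukocyte activation is emulated by a larger
    ``equivalent_diameter``, lower ``granularity_amplitude`` and an aspect
    ratio closer to one.
    """

    center: tuple[float, float]         # (x, y) um on the sample plane
    equivalent_diameter: float          # um
    aspect_ratio: float = 1.0           # major/minor axis ratio, >= 1
    orientation: float = 0.0            # rad, major-axis angle
    phase_shift: float = 1.2            # rad at footprint centre
    amplitude_transmittance: float = 0.85
    granularity_amplitude: float = 0.0  # rad RMS of internal phase texture
    granularity_scale: float = 1.0      # um correlation length of texture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.equivalent_diameter <= 0:
            raise ValueError("equivalent_diameter must be positive")
        if not (0.0 <= self.amplitude_transmittance <= 1.0):
            raise ValueError("amplitude_transmittance must lie in [0, 1]")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio must be >= 1")
        if self.granularity_amplitude < 0 or self.granularity_scale <= 0:
            raise ValueError("invalid granularity parameters")


@dataclass(frozen=True)
class Scene:
    """A set of phantoms inside a physical field of view."""

    phantoms: tuple[CellPhantom, ...]
    field_extent: tuple[float, float]   # (height, width) um
    background_level: float = 0.55      # gray fraction of the empty field

    def __post_init__(self) -> None:
        h, w = self.field_extent
        for p in self.phantoms:
            x, y = p.center
            if abs(x) > w / 2 or abs(y) > h / 2:
                raise ValueError(
                    f"phantom at ({x:.1f}, {y:.1f}) um lies outside the "
                    f"{h:.0f} x {w:.0f} um field")
        if not (0 < self.background_level <= 1):
            raise ValueError("background_level must lie in (0, 1]")


@dataclass
class ShadowImage:
    """One quantized sensor frame plus its acquisition metadata."""

    pixels: np.ndarray                  # 2D uint8/uint16
    pixel_pitch: float                  # um
    bit_depth: int
    channel_id: int = 0
    meta: dict = field(default_factory=dict)

    def as_float(self) -> np.ndarray:
        """Pixels as float64 gray levels."""
        return self.pixels.astype(np.float64)


@dataclass
class IlluminationField:
    """Partially coherent illumination intensity at the sample plane."""

    intensity: np.ndarray               # 2D, relative units (1 = radiance limit)
    dx: float                           # grid step, um
    transmitted_power: float            # open aperture area, um^2
    n_source_points: int


# ---------------------------------------------------------------------------
# aperture masks
# ---------------------------------------------------------------------------

def _roughness_series(spec: ApertureSpec) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray, float]:
    """Fourier coefficients of the rim perturbation and the scale that
    normalizes its peak excursion to the roughness amplitude."""
    rng = np.random.default_rng(spec.seed)
    m_max = max(2, int(math.ceil(2.0 * math.pi / spec.edge_roughness_correlation)))
    m = np.arange(1, m_max + 1)
    damp = np.exp(-0.5 * (m * spec.edge_roughness_correlation) ** 2)
    a = rng.standard_normal(m_max) * damp
    b = rng.standard_normal(m_max) * damp
    dense = np.linspace(0.0, 2.0 * np.pi, 8192, endpoint=False)
    pert = a @ np.cos(np.outer(m, dense)) + b @ np.sin(np.outer(m, dense))
    peak = float(np.max(np.abs(pert)))
    scale = spec.edge_roughness_amplitude / peak if peak > 0 else 0.0
    return m, a, b, scale


def _boundary_radius(spec: ApertureSpec, theta: np.ndarray) -> np.ndarray:
    """Boundary radius r(theta) of the aperture, including edge roughness.

    The perturbation is a smooth random Fourier series whose harmonic
    content decays on the requested angular correlation scale; it is
    reproducible from the seed and independent of the evaluation grid.
    """
    r0 = spec.diameter / 2.0
    if spec.edge_roughness_amplitude == 0:
        return np.full_like(np.asarray(theta, dtype=float), r0)
    m, a, b, scale = _roughness_series(spec)
    theta = np.asarray(theta, dtype=float)
    pert = np.zeros_like(theta)
    for mk, ak, bk in zip(m, a, b):     # bounded memory on large 2D grids
        pert += ak * np.cos(mk * theta) + bk * np.sin(mk * theta)
    return r0 + scale * pert


def make_aperture_mask(spec: ApertureSpec, n: int, dx: float) -> np.ndarray:
    """Rasterize an aperture onto an ``n`` x ``n`` grid of step ``dx`` um.

    Returns a binary (0/1) float transmission mask centred on the grid.
    Raises ``ValueError`` when the grid resolves the diameter by fewer than
    32 samples.
    """
    if spec.diameter / dx < 32:
        raise ValueError(
            f"grid too coarse: {spec.diameter / dx:.1f} samples across the "
            f"{spec.diameter:.0f} um aperture (need >= 32); reduce dx")
    coords = (np.arange(n) - n / 2) * dx
    xx, yy = np.meshgrid(coords, coords)
    rr = np.hypot(xx, yy)
    if spec.edge_roughness_amplitude == 0:
        return (rr <= spec.diameter / 2.0).astype(np.float64)
    theta = np.arctan2(yy, xx)
    return (rr <= _boundary_radius(spec, theta)).astype(np.float64)


# ---------------------------------------------------------------------------
# free-space propagation
# ---------------------------------------------------------------------------

def propagate(field_in: np.ndarray, distance: float, cfg: OpticsConfig,
              dx: float | None = None) -> np.ndarray:
    """Band-limited angular-spectrum propagation of a complex field.

    The transfer function is evaluated on the exact non-paraxial dispersion
    relation; spatial frequencies whose transfer-function phase would alias
    on the finite grid are suppressed (band limiting), which keeps the
    periodic wrap-around of long propagations out of the observation
    window.  ``distance`` 0 returns the field unchanged.
    """
    if distance < 0:
        raise ValueError("propagation distance must be >= 0")
    if field_in.ndim != 2:
        raise ValueError("field must be 2D")
    if distance == 0:
        return field_in.copy()
    dx = cfg.grid_dx if dx is None else dx
    lam = cfg.wavelength
    ny, nx = field_in.shape
    fx = fftfreq(nx, dx)
    fy = fftfreq(ny, dx)
    fxx, fyy = np.meshgrid(fx, fy)
    arg = 1.0 / lam ** 2 - fxx ** 2 - fyy ** 2
    kz = 2.0 * np.pi * np.sqrt(np.maximum(arg, 0.0))
    h = np.where(arg > 0, np.exp(1j * kz * distance), 0.0)
    # band limit (Matsushima-style): local frequency of H must stay below
    # the Nyquist rate of the frequency grid in each axis
    fx_lim = 1.0 / (lam * math.sqrt((2.0 * distance / (nx * dx)) ** 2 + 1.0))
    fy_lim = 1.0 / (lam * math.sqrt((2.0 * distance / (ny * dx)) ** 2 + 1.0))
    h *= (np.abs(fxx) <= fx_lim) & (np.abs(fyy) <= fy_lim)
    # diagnostic: geometric spread of the pass band vs available guard band
    spread = distance * lam * min(fx_lim, fy_lim)
    if spread > min(nx, ny) * dx / 2.0:
        logger.warning(
            "propagation over %.3g um spreads light %.3g um, beyond half the "
            "grid extent; wrap-around may reach the observation window",
            distance, spread)
    return ifft2(fft2(field_in) * h)


# ---------------------------------------------------------------------------
# partially coherent illumination
# ---------------------------------------------------------------------------

def _disc_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points in a disc; the first point is always the centre."""
    pts = np.zeros((n, 2))
    if n > 1:
        u = rng.random(n - 1)
        phi = rng.random(n - 1) * 2.0 * np.pi
        r = radius * np.sqrt(u)
        pts[1:, 0] = r * np.cos(phi)
        pts[1:, 1] = r * np.sin(phi)
    return pts


def _shift_average(intensity: np.ndarray, shifts_px: np.ndarray) -> np.ndarray:
    """Incoherent average of ``intensity`` displaced by each row of
    ``shifts_px``, computed as one Fourier-domain kernel product."""
    ny, nx = intensity.shape
    fx = fftfreq(nx)[None, :]
    fy = fftfreq(ny)[:, None]
    kernel = np.zeros((ny, nx), dtype=complex)
    for dy, dxs in shifts_px:
        kernel += np.exp(-2j * np.pi * (fx * dxs + fy * dy))
    kernel /= len(shifts_px)
    out = ifft2(fft2(intensity) * kernel).real
    return np.maximum(out, 0.0)


def simulate_illumination(cfg: OpticsConfig, aperture: ApertureSpec,
                          n_source_points: int = 16, seed: int = 0,
                          grid_n: int = 1024,
                          grid_dx: float = 2.0) -> IlluminationField:
    """Sample-plane illumination produced by the LED die behind the pinhole.

    The LED die is modelled as a spatially incoherent disc; each sampled die
    point illuminates the aperture with a spherical wave that is fully
    coherent across the pinhole.  By the Fresnel scaling theorem each such
    wave is equivalent to a plane wave propagated over the reduced distance
    ``z1 * L0 / (L0 + z1)`` and observed on a grid magnified by
    ``(L0 + z1) / L0``; off-axis die points displace the same diffraction
    pattern laterally.  The returned intensity is the incoherent average
    over die points, normalized so the geometric (radiance-limited) level
    is 1.  ``n_source_points`` = 1 degenerates to fully coherent on-axis
    illumination.
    """
    if n_source_points < 1:
        raise ValueError("n_source_points must be >= 1")
    mask = make_aperture_mask(aperture, grid_n, grid_dx)
    l0, z1 = cfg.source_to_pinhole, cfg.pinhole_to_sample
    mag = (l0 + z1) / l0
    z_eff = z1 * l0 / (l0 + z1)
    field_out = propagate(mask.astype(complex), z_eff, cfg, dx=grid_dx)
    # magnified observation grid; 1/mag^2 keeps energy, so the geometric
    # image of the open aperture has unit relative intensity
    intensity = np.abs(field_out) ** 2
    dx_sample = grid_dx * mag
    rng = np.random.default_rng(seed)
    pts = _disc_points(n_source_points, cfg.source_diameter / 2.0, rng)
    if n_source_points > 1:
        shifts_px = pts * (z1 / l0) / dx_sample
        intensity = _shift_average(intensity, shifts_px[:, ::-1])
    power = float(mask.sum()) * grid_dx ** 2
    return IlluminationField(intensity=intensity, dx=dx_sample,
                             transmitted_power=power,
                             n_source_points=n_source_points)


def illumination_sensor_view(illum: IlluminationField,
                             cfg: OpticsConfig) -> np.ndarray:
    """Crop of the illumination field matching the sensor footprint,
    resampled to the sensor pixel grid by bilinear interpolation."""
    from scipy.ndimage import map_coordinates

    rows, cols = cfg.sensor_shape
    ny, nx = illum.intensity.shape
    yc = (np.arange(rows) - (rows - 1) / 2) * cfg.pixel_pitch / illum.dx + ny / 2
    xc = (np.arange(cols) - (cols - 1) / 2) * cfg.pixel_pitch / illum.dx + nx / 2
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    return map_coordinates(illum.intensity, [yy, xx], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _granularity_phase(shape: tuple[int, int], dx: float, scale: float,
                       amplitude: float, seed: int) -> np.ndarray:
    """Band-limited Gaussian random phase field, RMS = amplitude (rad)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma = max(scale / dx, 0.5)
    textured = gaussian_filter(noise, sigma, mode="wrap")
    sd = textured.std()
    if sd > 0:
        textured *= amplitude / sd
    return textured


def _transmission(scene: Scene, cfg: OpticsConfig, n: tuple[int, int],
                  dx: float) -> np.ndarray:
    """Thin-object complex transmission of the whole scene."""
    ny, nx = n
    t = np.ones((ny, nx), dtype=complex)
    edge_sigma = max(0.7, 0.6 * dx)     # um, smooth membrane edge
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dx
    for p in scene.phantoms:
        a = p.equivalent_diameter / 2.0 * math.sqrt(p.aspect_ratio)
        b = p.equivalent_diameter / 2.0 / math.sqrt(p.aspect_ratio)
        pad = 4.0 * edge_sigma
        j0 = np.searchsorted(x, p.center[0] - a - pad)
        j1 = np.searchsorted(x, p.center[0] + a + pad)
        i0 = np.searchsorted(y, p.center[1] - a - pad)
        i1 = np.searchsorted(y, p.center[1] + a + pad)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = x[j0:j1] - p.center[0]
        ys = y[i0:i1] - p.center[1]
        xx, yy = np.meshgrid(xs, ys)
        c, s = math.cos(p.orientation), math.sin(p.orientation)
        u = c * xx + s * yy
        v = -s * xx + c * yy
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        signed = (rho - 1.0) * math.sqrt(a * b)
        w = 1.0 / (1.0 + np.exp(np.clip(signed / edge_sigma, -60, 60)))
        phase = np.full_like(w, p.phase_shift)
        if p.granularity_amplitude > 0:
            phase = phase + _granularity_phase(
                w.shape, dx, p.granularity_scale,
                p.granularity_amplitude, p.seed)
        cell = p.amplitude_transmittance * np.exp(1j * phase)
        t[i0:i1, j0:j1] *= 1.0 + (cell - 1.0) * w
    return t


def _coherence_shifts(cfg: OpticsConfig, aperture: ApertureSpec,
                      rng: np.random.Generator, dx: float) -> np.ndarray:
    """Pattern displacements (rows, cols, px) of the coherence modes.

    Semi-coherence is modelled as an incoherent sum over point sources
    spread across the pinhole; each pinhole point displaces the sensor
    pattern by its offset scaled by sample-to-sensor over pinhole-to-sample.
    """
    n = cfg.n_coherence_points
    pts = _disc_points(n, aperture.diameter / 2.0, rng)
    shifts = pts * cfg.coherence_blur_scale
    return shifts[:, ::-1] / dx          # (row, col) order, px


def _roughness_halo(intensity: np.ndarray, cfg: OpticsConfig,
                    aperture: ApertureSpec, dx: float) -> np.ndarray:
    """Diffuse scattering halo of a rough (drilled) aperture rim.

    Boundary irregularities scatter a fraction of the illumination into
    angles set by the rim correlation length; at the sensor this adds a
    smooth halo that dilutes ring contrast.  The scattered energy fraction
    scales with the perturbed rim area relative to the aperture area
    (2a/R); the halo width is the scatter angle (wavelength over one
    boundary correlation cell): a ray tilted by that angle at the rim
    shifts the shadow pattern by angle times sample-to-sensor distance.
    """
    from scipy.ndimage import gaussian_filter

    amp = aperture.edge_roughness_amplitude
    if amp <= 0:
        return intensity
    radius = aperture.diameter / 2.0
    corr_len = aperture.edge_roughness_correlation * radius
    scatter_angle = cfg.wavelength / max(corr_len, cfg.wavelength)
    sigma_px = max(scatter_angle * cfg.sample_to_sensor / dx, 0.5)
    frac = min(1.0, 2.0 * amp / radius)
    halo = gaussian_filter(intensity, sigma_px, mode="nearest")
    return (1.0 - frac) * intensity + frac * halo


def render_shadow_image(scene: Scene, cfg: OpticsConfig,
                        aperture: ApertureSpec | None = None,
                        seed: int = 0,
                        illumination: IlluminationField | None = None,
                        channel_id: int = 0) -> tuple[ShadowImage, list[dict]]:
    """Render one sensor frame of a scene and return its ground truth.

    The scene transmission is applied to the (optionally structured)
    illumination, propagated from the sample plane to the sensor, blurred
    by the partial-coherence kernel of the pinhole, box-integrated to the
    pixel pitch, and degraded by shot noise, read noise and quantization.

    Returns ``(image, truth)`` where ``truth`` lists, per phantom, the
    sensor-plane centre in pixel coordinates plus the phantom parameters.
    """
    if aperture is None:
        aperture = ApertureSpec(diameter=cfg.pinhole_diameter)
    rows, cols = cfg.sensor_shape
    q = cfg.oversample
    ny, nx = rows * q, cols * q
    dx = cfg.grid_dx
    h_ext, w_ext = cfg.field_extent
    if scene.field_extent[0] > h_ext + 1e-9 or scene.field_extent[1] > w_ext + 1e-9:
        raise ValueError("scene field exceeds the sensor footprint")

    rng = np.random.default_rng(seed)
    t = _transmission(scene, cfg, (ny, nx), dx)
    if illumination is not None:
        from scipy.ndimage import map_coordinates
        iy, ix = illumination.intensity.shape
        ycoord = (np.arange(ny) - (ny - 1) / 2) * dx / illumination.dx + iy / 2
        xcoord = (np.arange(nx) - (nx - 1) / 2) * dx / illumination.dx + ix / 2
        yy, xx = np.meshgrid(ycoord, xcoord, indexing="ij")
        envelope = map_coordinates(illumination.intensity, [yy, xx],
                                   order=1, mode="nearest")
        field_in = np.sqrt(np.maximum(envelope, 0.0)) * t
    else:
        field_in = t
    field_out = propagate(field_in, cfg.sample_to_sensor, cfg, dx=dx)
    intensity = np.abs(field_out) ** 2
    if cfg.n_coherence_points > 1:
        shifts = _coherence_shifts(cfg, aperture, rng, dx)
        intensity = _shift_average(intensity, shifts)
    intensity = _roughness_halo(intensity, cfg, aperture, dx)
    # box-integrate the oversampled grid down to sensor pixels
    pix = intensity.reshape(rows, q, cols, q).mean(axis=(1, 3))
    expected = pix * scene.background_level * cfg.illumination_gain
    # shot noise at photon_scale photons per unit relative intensity,
    # then additive Gaussian read noise in gray levels, then quantization
    photons = rng.poisson(np.maximum(expected, 0.0) * cfg.photon_scale)
    gray_frac = photons / cfg.photon_scale
    gray = gray_frac * cfg.max_gray
    gray += rng.normal(0.0, cfg.read_noise_sd, size=gray.shape)
    gray = np.clip(np.rint(gray), 0, cfg.max_gray)
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    image = ShadowImage(
        pixels=gray.astype(dtype), pixel_pitch=cfg.pixel_pitch,
        bit_depth=cfg.bit_depth, channel_id=channel_id,
        meta={"seed": seed, "n_phantoms": len(scene.phantoms),
              "aperture_diameter": aperture.diameter,
              "aperture_roughness": aperture.edge_roughness_amplitude})
    mag = cfg.pattern_magnification
    truth = []
    for k, p in enumerate(scene.phantoms):
        x, y = p.center
        truth.append({
            "cell_id": k,
            "row": y * mag / cfg.pixel_pitch + (rows - 1) / 2,
            "col": x * mag / cfg.pixel_pitch + (cols - 1) / 2,
            "equivalent_diameter_um": p.equivalent_diameter,
            "aspect_ratio": p.aspect_ratio,
            "orientation": p.orientation,
            "granularity_amplitude": p.granularity_amplitude,
        })
    return image, truth


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------

def bead_phantom(center: tuple[float, float], diameter: float,
                 seed: int = 0) -> CellPhantom:
    """Polystyrene microsphere surrogate (thin-object equivalent)."""
    return CellPhantom(center=center, equivalent_diameter=diameter,
                       aspect_ratio=1.0, phase_shift=1.8,
                       amplitude_transmittance=0.55,
                       granularity_amplitude=0.0, seed=seed)


def leukocyte_phantom(center: tuple[float, float], seed: int = 0,
                      activated: bool = False,
                      rng: np.random.Generator | None = None) -> CellPhantom:
    """Leukocyte surrogate; activation enlarges the cell, reduces the
    internal phase texture and rounds the outline."""
    rng = np.random.default_rng(seed) if rng is None else rng
    if activated:
        diameter = 10.8 * (1.0 + 0.06 * rng.standard_normal())
        aspect = 1.0 + abs(rng.normal(0.0, 0.05))
        gran = 0.25
    else:
        diameter = 9.0 * (1.0 + 0.06 * rng.standard_normal())
        aspect = 1.0 + abs(rng.normal(0.15, 0.10))
        gran = 0.50
    return CellPhantom(center=center, equivalent_diameter=max(diameter, 4.0),
                       aspect_ratio=min(aspect, 1.6),
                       orientation=rng.uniform(0, math.pi),
                       phase_shift=1.2, amplitude_transmittance=0.85,
                       granularity_amplitude=gran, granularity_scale=1.2,
                       seed=int(rng.integers(0, 2 ** 31)))


def random_scene(n: int, cfg: OpticsConfig, seed: int = 0,
                 min_separation: float = 70.0, margin: float = 45.0,
                 phantom_factory=None, background_level: float = 0.55) -> Scene:
    """Place ``n`` phantoms on a jittered grid with a minimum separation.

    ``phantom_factory(center, index, rng)`` builds each phantom; the default
    produces 10 um beads.  Raises if ``n`` exceeds the available sites.
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.field_extent
    if phantom_factory is None:
        def phantom_factory(center, index, rng):
            return bead_phantom(center, 10.0, seed=int(rng.integers(2 ** 31)))
    usable_w, usable_h = w - 2 * margin, h - 2 * margin
    nx = int(usable_w // min_separation) + 1
    nyy = int(usable_h // min_separation) + 1
    if nx * nyy < n:
        raise ValueError(f"cannot place {n} phantoms with separation "
                         f"{min_separation} um in a {w:.0f} x {h:.0f} um field")
    sites = [( -usable_w / 2 + i * min_separation,
               -usable_h / 2 + j * min_separation)
             for i in range(nx) for j in range(nyy)]
    picks = rng.choice(len(sites), size=n, replace=False)
    jit = min_separation * 0.12
    phantoms = []
    for k, idx in enumerate(picks):
        x0, y0 = sites[idx]
        center = (float(np.clip(x0 + rng.uniform(-jit, jit),
                                -usable_w / 2, usable_w / 2)),
                  float(np.clip(y0 + rng.uniform(-jit, jit),
                                -usable_h / 2, usable_h / 2)))
        phantoms.append(phantom_factory(center, k, rng))
    return Scene(phantoms=tuple(phantoms),
                 field_extent=cfg.field_extent,
                 background_level=background_level)


# ---------------------------------------------------------------------------
# multi-channel runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelPerturbation:
    """Channel-to-channel manufacturing tolerances.

    Defaults: illumination gain within +/-2 %, sample-to-sensor distance
    within +/-5 %, drawn uniformly once per channel.
    """

    gain_tolerance: float = 0.02
    distance_tolerance: float = 0.05


def simulate_channel_run(bead_diameter: float, n_beads: int,
                         n_replicates: int, cfg: OpticsConfig | None = None,
                         perturbation: ChannelPerturbation | None = None,
                         seed: int = 0, n_channels: int = 4
                         ) -> list[tuple[int, ShadowImage, list[dict]]]:
    """Replicate bead acquisitions across perturbed optical channels.

    Each channel receives its own gain and sample-to-sensor perturbation;
    each replicate is an independently placed bead scene.  Returns a list
    of ``(channel_id, image, truth)`` records.
    """
    cfg = OpticsConfig() if cfg is None else cfg
    perturbation = ChannelPerturbation() if perturbation is None else perturbation
    master = np.random.default_rng(seed)
    records = []
    for ch in range(n_channels):
        gain = 1.0 + master.uniform(-1, 1) * perturbation.gain_tolerance
        dist = cfg.sample_to_sensor * (
            1.0 + master.uniform(-1, 1) * perturbation.distance_tolerance)
        ch_cfg = replace(cfg, illumination_gain=gain, sample_to_sensor=dist)
        for rep in range(n_replicates):
            scene_seed = int(master.integers(0, 2 ** 31))
            render_seed = int(master.integers(0, 2 ** 31))
            scene = random_scene(
                n_beads, ch_cfg, seed=scene_seed,
                phantom_factory=lambda c, i, r, d=bead_diameter: bead_phantom(
                    c, d, seed=int(r.integers(2 ** 31))))
            img, truth = render_shadow_image(scene, ch_cfg, seed=render_seed,
                                             channel_id=ch)
            img.meta.update({"replicate": rep, "gain": gain,
                             "sample_to_sensor": dist})
            records.append((ch, img, truth))
    return records
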