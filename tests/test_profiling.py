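"""Radial profiling and shadow parameters: closed forms, symmetry, oracle."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from shadowcyte.detection import PatternROI, detect_patterns
from shadowcyte.optics import OpticsConfig, Scene, ShadowImage, bead_phantom, \
    render_shadow_image
from shadowcyte.profiling import (ProfilingConfig, RadialProfileSet,
                                  compute_mmd, compute_mmd_sd, compute_ppd,
                                  extract_params, find_extrema,
                                  radial_profiles, sharpness)


def _profile_set(values: np.ndarray, radii: np.ndarray, n_angles: int = 8,
                 pitch: float = 1.0) -> RadialProfileSet:
    """RadialProfileSet with every ray carrying the same profile."""
    tiled = np.tile(values, (n_angles, 1))
    return RadialProfileSet(
        angles=np.arange(n_angles) * 2 * np.pi / n_angles,
        radii_px=radii, raw=tiled, smoothed=tiled, center=(0.0, 0.0),
        pixel_pitch=pitch, valid=np.ones(n_angles, dtype=bool),
        noise_scale=1e-9)


def _ring_image(radius_px: float, center=(96.0, 96.0), shape=(192, 192),
                pitch: float = 2.2) -> ShadowImage:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    img = 120.0 + 100.0 * np.exp(-0.5 * ((r - radius_px) / 2.0) ** 2)
    return ShadowImage(pixels=img, pixel_pitch=pitch, bit_depth=8)


class TestFindExtrema:
    def test_cosine_extrema_at_multiples_of_pi_over_k(self):
        k = 0.9
        radii = np.arange(0, 20, 0.25)
        ext = find_extrema(radii, np.cos(k * radii))
        assert len(ext) >= 4
        kinds = [kind for _, kind, _ in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternating
        for r, kind, _ in ext:
            n = round(r / (math.pi / k))
            assert abs(r - n * math.pi / k) <= 0.005 * (n * math.pi / k)
            assert kind == ("max" if n % 2 == 0 else "min")

    def test_monotone_profile_has_no_extrema(self):
        radii = np.arange(0, 10, 0.25)
        assert find_extrema(radii, np.exp(-radii)) == []

    def test_noisy_cosine_matches_noiseless_after_prominence_filter(self):
        from scipy.signal import savgol_filter

        k = 0.8
        radii = np.arange(0, 15, 0.25)
        clean = np.cos(k * radii)
        rng = np.random.default_rng(17)
        noisy = clean + rng.normal(0, 0.1, clean.shape)   # SNR 10
        smoothed = savgol_filter(noisy, 5, 2)
        resid = noisy - smoothed
        floor = 3.0 * np.median(np.abs(resid - np.median(resid))) * 1.4826
        ext_clean = find_extrema(radii, clean)
        ext_noisy = find_extrema(radii, smoothed, noise_floor=floor)
        assert len(ext_noisy) == len(ext_clean)
        for (rc, kc, _), (rn, kn, _) in zip(ext_clean, ext_noisy):
            assert kc == kn
            assert abs(rn - rc) <= 0.02 * max(rc, 1.0)

    def test_matches_exhaustive_neighbor_scan(self):
        """Oracle equivalence: sign-change extrema equal brute-force
        local-neighbour comparison on dense tie-free profiles."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            v = gaussian_filter1d(rng.standard_normal(300), 4.0)
            radii = np.arange(len(v), dtype=float)
            got = find_extrema(radii, v)
            oracle = []
            for i in range(1, len(v) - 1):
                if v[i] > v[i - 1] and v[i] > v[i + 1]:
                    oracle.append((i, "max"))
                elif v[i] < v[i - 1] and v[i] < v[i + 1]:
                    oracle.append((i, "min"))
            assert len(got) == len(oracle)
            for (r, kind, _), (i, okind) in zip(got, oracle):
                assert kind == okind
                assert abs(r - i) <= 0.5   # pre-refinement grid position


class TestRadialProfiles:
    def test_circular_pattern_rays_agree(self, bead_frame):
        img, _ = bead_frame
        roi = detect_patterns(img)[0]
        cfg = ProfilingConfig()
        profiles = radial_profiles(roi, 36, cfg)
        peaks = []
        for k in range(36):
            ext = find_extrema(profiles.radii_px, profiles.smoothed[k])
            maxima = [(r, v) for r, kind, v in ext if kind == "max" and r >= 2.0]
            peaks.append(max(maxima, key=lambda t: t[1])[0])
        peaks = np.array(peaks)
        assert np.max(np.abs(peaks - peaks.mean())) <= 0.02 * peaks.mean()

    def test_n_angles_8_vs_36_agree_within_one_percent(self, bead_frame):
        img, _ = bead_frame
        roi = detect_patterns(img)[0]
        ppds = [compute_ppd(radial_profiles(roi, n, ProfilingConfig(n_angles=n)),
                            ProfilingConfig(n_angles=n))
                for n in (8, 36)]
        assert abs(ppds[0] / ppds[1] - 1.0) < 0.01

    def test_offset_center_gives_sinusoidal_peak_radii(self):
        img = _ring_image(15.0)
        roi = PatternROI(center=(97.0, 96.0), window_radius=24, score=10.0,
                         image=img)   # centre deliberately 1 px off
        cfg = ProfilingConfig()
        profiles = radial_profiles(roi, 36, cfg)
        peaks = []
        for k in range(36):
            ext = find_extrema(profiles.radii_px, profiles.smoothed[k])
            maxima = [(r, v) for r, kind, v in ext if kind == "max" and r >= 2.0]
            peaks.append(max(maxima, key=lambda t: t[1])[0])
        peaks = np.array(peaks)
        th = profiles.angles
        design = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
        coef, *_ = np.linalg.lstsq(design, peaks, rcond=None)
        amplitude = math.hypot(coef[1], coef[2])
        assert amplitude == pytest.approx(1.0, abs=0.25)
        residual = peaks - design @ coef
        assert np.abs(residual).max() < 0.3

    def test_ray_exiting_window_marked_invalid(self):
        img = _ring_image(10.0, center=(20.0, 96.0))
        roi = PatternROI(center=(20.0, 96.0), window_radius=24, score=10.0,
                         image=img)
        profiles = radial_profiles(roi, 36, ProfilingConfig())
        assert not profiles.valid.all()
        assert profiles.valid.any()


class TestShadowParams:
    def test_ppd_from_known_ring_radius(self):
        """Ring at 15 px with 2.2 um pitch -> PPD = 66 um."""
        img = _ring_image(15.0)
        roi = PatternROI(center=(96.0, 96.0), window_radius=24, score=10.0,
                         image=img)
        ppd = compute_ppd(radial_profiles(roi, 36, ProfilingConfig()),
                          ProfilingConfig())
        assert ppd == pytest.approx(66.0, rel=0.01)

    def test_mmd_closed_form_on_cosine(self):
        k = 1.0
        radii = np.arange(0, 16, 0.25)
        profiles = _profile_set(np.cos(k * radii), radii)
        cfg = ProfilingConfig(n_angles=8)
        per_angle, mean = compute_mmd(profiles, cfg)
        assert mean == pytest.approx(math.pi / k, rel=0.005)
        assert compute_mmd_sd(per_angle, quorum=8) == pytest.approx(0.0, abs=1e-6)

    def test_mmd_sd_closed_form(self):
        assert compute_mmd_sd([10.0, 12.0], quorum=2) == pytest.approx(
            math.sqrt(2.0))

    def test_all_angles_equal_gives_zero_sd(self):
        assert compute_mmd_sd([4.0] * 12) == 0.0

    def test_quorum_not_met_gives_nan(self):
        assert math.isnan(compute_mmd_sd([1.0, 2.0, math.nan], quorum=8))

    def test_bead_size_orders_ppd(self, cfg_small):
        """20 um bead PPD exceeds 10 um bead PPD (size proxy)."""
        ppds = {}
        for d in (10.0, 20.0):
            scene = Scene(phantoms=(bead_phantom((0, 0), d),),
                          field_extent=cfg_small.field_extent)
            img, _ = render_shadow_image(scene, cfg_small, seed=3)
            params = extract_params(detect_patterns(img)[0], ProfilingConfig())
            ppds[d] = params.ppd
        assert ppds[20.0] > ppds[10.0]

    def test_rotation_by_90_degrees_is_exact(self, bead_frame):
        img, _ = bead_frame
        rot = ShadowImage(pixels=np.rot90(img.pixels).copy(),
                          pixel_pitch=img.pixel_pitch, bit_depth=img.bit_depth)
        p0 = extract_params(detect_patterns(img)[0], ProfilingConfig())
        p1 = extract_params(detect_patterns(rot)[0], ProfilingConfig())
        assert p1.ppd == pytest.approx(p0.ppd, rel=1e-6)
        assert p1.mmd_mean == pytest.approx(p0.mmd_mean, rel=1e-6)
        assert p1.mmd_sd == pytest.approx(p0.mmd_sd, abs=1e-6)

    def test_rotation_by_30_degrees_stable(self, bead_frame):
        """PPD and mean MMD within 3 % under an interpolating rotation;
        MMD-SD (a near-zero dispersion for circular patterns) stays small
        in absolute terms."""
        from skimage.transform import rotate

        img, _ = bead_frame
        rot = ShadowImage(
            pixels=rotate(img.as_float(), 30.0, preserve_range=True, order=3),
            pixel_pitch=img.pixel_pitch, bit_depth=img.bit_depth)
        p0 = extract_params(detect_patterns(img)[0], ProfilingConfig())
        p1 = extract_params(detect_patterns(rot)[0], ProfilingConfig())
        assert abs(p1.ppd / p0.ppd - 1.0) < 0.03
        assert abs(p1.mmd_mean / p0.mmd_mean - 1.0) < 0.03
        assert max(p0.mmd_sd, p1.mmd_sd) < 0.25 * p0.mmd_mean


class TestSharpness:
    def test_constant_roi_scores_zero(self):
        img = ShadowImage(pixels=np.full((64, 64), 120.0), pixel_pitch=2.2,
                          bit_depth=8)
        roi = PatternROI(center=(32.0, 32.0), window_radius=16, score=0.0,
                         image=img)
        assert sharpness(roi) == 0.0

    def test_blur_reduces_sharpness(self, bead_frame):
        img, _ = bead_frame
        roi = detect_patterns(img)[0]
        blurred = ShadowImage(pixels=gaussian_filter(img.as_float(), 2.0),
                              pixel_pitch=img.pixel_pitch,
                              bit_depth=img.bit_depth)
        roi_b = PatternROI(center=roi.center, window_radius=roi.window_radius,
                           score=roi.score, image=blurred)
        assert sharpness(roi_b) < sharpness(roi)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_angles": 7}, {"n_angles": 6}, {"radial_step_px": 0.7},
        {"smooth_window": 4},
    ])
    def test_invalid_profiling_config(self, kwargs):
        with pytest.raises(ValueError):
            ProfilingConfig(**kwargs)
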