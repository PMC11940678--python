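"""Forward-model unit tests: apertures, propagation, illumination, rendering."""

import math

import numpy as np
import pytest

from shadowcyte.optics import (ApertureSpec, CellPhantom, ChannelPerturbation,
                               OpticsConfig, Scene, _boundary_radius,
                               bead_phantom, make_aperture_mask, propagate,
                               random_scene, render_shadow_image,
                               simulate_channel_run, simulate_illumination)


class TestApertureMask:
    def test_ideal_disk_area_within_one_percent(self):
        spec = ApertureSpec(diameter=300.0)
        mask = make_aperture_mask(spec, 512, 2.0)
        area = mask.sum() * 4.0
        expected = math.pi * 150.0 ** 2
        assert abs(area / expected - 1.0) < 0.01
        assert set(np.unique(mask)) <= {0.0, 1.0}

    def test_same_seed_is_bit_identical(self):
        spec = ApertureSpec(diameter=300.0, edge_roughness_amplitude=10.0,
                            seed=42)
        a = make_aperture_mask(spec, 256, 2.0)
        b = make_aperture_mask(spec, 256, 2.0)
        assert np.array_equal(a, b)

    def test_roughness_bounds_boundary_radius(self):
        spec = ApertureSpec(diameter=300.0, edge_roughness_amplitude=12.0,
                            seed=3)
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        r = _boundary_radius(spec, theta)
        assert r.min() >= 150.0 - 12.0 - 1e-9
        assert r.max() <= 150.0 + 12.0 + 1e-9
        # the perturbation actually reaches its nominal amplitude
        assert np.max(np.abs(r - 150.0)) == pytest.approx(12.0, rel=0.01)

    def test_zero_roughness_recovers_ideal_disk(self):
        ideal = make_aperture_mask(ApertureSpec(diameter=200.0), 256, 2.0)
        rough = make_aperture_mask(
            ApertureSpec(diameter=200.0, edge_roughness_amplitude=0.0, seed=9),
            256, 2.0)
        assert np.array_equal(ideal, rough)

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="grid too coarse"):
            make_aperture_mask(ApertureSpec(diameter=100.0), 128, 4.0)

    @pytest.mark.parametrize("kwargs", [
        {"diameter": -1.0},
        {"diameter": 100.0, "edge_roughness_amplitude": 60.0},
        {"diameter": 100.0, "edge_roughness_correlation": 0.0},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ApertureSpec(**kwargs)


class TestPropagate:
    def test_zero_distance_is_identity(self, cfg_small):
        rng = np.random.default_rng(0)
        field = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        out = propagate(field, 0.0, cfg_small, dx=1.0)
        assert np.array_equal(out, field)
        assert out is not field

    def test_interior_energy_conserved(self, cfg_small):
        # compact Gaussian beam, guard band excluded
        n, dx = 256, 1.1
        x = (np.arange(n) - n / 2) * dx
        xx, yy = np.meshgrid(x, x)
        field = np.exp(-(xx ** 2 + yy ** 2) / (2 * 25.0 ** 2)).astype(complex)
        out = propagate(field, 150.0, cfg_small, dx=dx)
        g = n // 8
        e_in = np.sum(np.abs(field[g:-g, g:-g]) ** 2)
        e_out = np.sum(np.abs(out[g:-g, g:-g]) ** 2)
        assert abs(e_out / e_in - 1.0) < 0.005

    def test_plane_wave_stays_flat(self, cfg_small):
        field = np.ones((128, 128), dtype=complex)
        out = propagate(field, 200.0, cfg_small, dx=1.1)
        intensity = np.abs(out) ** 2
        assert np.allclose(intensity, 1.0, atol=1e-9)

    def test_negative_distance_rejected(self, cfg_small):
        with pytest.raises(ValueError):
            propagate(np.ones((64, 64), dtype=complex), -1.0, cfg_small, dx=1.0)


class TestIllumination:
    def test_single_point_is_coherent_propagation(self, cfg_default):
        ap = ApertureSpec(diameter=300.0)
        il = simulate_illumination(cfg_default, ap, n_source_points=1, seed=0,
                                   grid_n=512, grid_dx=2.0)
        mask = make_aperture_mask(ap, 512, 2.0)
        l0 = cfg_default.source_to_pinhole
        z1 = cfg_default.pinhole_to_sample
        z_eff = z1 * l0 / (l0 + z1)
        ref = np.abs(propagate(mask.astype(complex), z_eff, cfg_default,
                               dx=2.0)) ** 2
        assert np.allclose(il.intensity, ref, atol=1e-12)

    def test_transmitted_power_monotone_in_diameter(self, cfg_default):
        powers = []
        for d in range(100, 401, 50):
            il = simulate_illumination(cfg_default, ApertureSpec(diameter=d),
                                       n_source_points=4, seed=1,
                                       grid_n=512, grid_dx=2.0)
            powers.append(il.transmitted_power)
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_uniformity_improves_100_to_300(self, cfg_default):
        from shadowcyte.optics import illumination_sensor_view
        unif = {}
        for d in (100.0, 300.0):
            il = simulate_illumination(cfg_default, ApertureSpec(diameter=d),
                                       n_source_points=16, seed=1)
            view = illumination_sensor_view(il, cfg_default)
            r, c = view.shape
            crop = view[r // 4:-(r // 4), c // 4:-(c // 4)]
            unif[d] = crop.std() / crop.mean()
        assert unif[300.0] < unif[100.0]


class TestRenderShadowImage:
    def test_empty_scene_flat_background(self, cfg_small):
        scene = Scene(phantoms=(), field_extent=cfg_small.field_extent,
                      background_level=0.55)
        img, truth = render_shadow_image(scene, cfg_small, seed=1)
        assert truth == []
        gray = img.as_float()
        expected = 0.55 * cfg_small.max_gray
        assert abs(gray.mean() - expected) < 2.0
        # SD consistent with the shot + read noise model
        shot_sd = cfg_small.max_gray * math.sqrt(
            0.55 / cfg_small.photon_scale)
        model_sd = math.hypot(shot_sd, cfg_small.read_noise_sd)
        assert 0.6 * model_sd < gray.std() < 1.6 * model_sd

    def test_same_seed_bit_identical(self, cfg_small):
        scene = Scene(phantoms=(bead_phantom((0, 0), 10.0),),
                      field_extent=cfg_small.field_extent)
        a, _ = render_shadow_image(scene, cfg_small, seed=7)
        b, _ = render_shadow_image(scene, cfg_small, seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_phantom_outside_field_rejected(self, cfg_small):
        h, w = cfg_small.field_extent
        with pytest.raises(ValueError, match="outside"):
            Scene(phantoms=(bead_phantom((w, 0.0), 10.0),),
                  field_extent=cfg_small.field_extent)

    def test_ring_radius_grows_with_sensor_distance(self):
        """First-ring (principal peak) radius of a 20 um bead pattern is
        monotone increasing in the sample-to-sensor distance."""
        from shadowcyte.detection import detect_patterns
        from shadowcyte.profiling import ProfilingConfig, extract_params

        ppds = []
        for z2 in (100.0, 150.0, 200.0):
            cfg = OpticsConfig(sample_to_sensor=z2, sensor_shape=(192, 192))
            scene = Scene(phantoms=(bead_phantom((0, 0), 20.0),),
                          field_extent=cfg.field_extent)
            img, _ = render_shadow_image(scene, cfg, seed=2)
            params = extract_params(detect_patterns(img)[0], ProfilingConfig())
            ppds.append(params.ppd)
        assert ppds[0] < ppds[1] < ppds[2]


class TestChannelRun:
    def test_zero_perturbation_channels_agree(self, cfg_default):
        from shadowcyte.pipeline import process_image

        records = simulate_channel_run(
            20.0, 20, 1, cfg=cfg_default,
            perturbation=ChannelPerturbation(gain_tolerance=0.0,
                                             distance_tolerance=0.0),
            seed=3)
        means = []
        for ch, image, _ in records:
            tab = process_image(image, image_id=f"ch{ch}")
            means.append(tab["ppd_um"].dropna().mean())
        cov = 100.0 * np.std(means, ddof=1) / np.mean(means)
        assert cov < 1.0     # only detection/noise variance remains

    def test_record_structure(self, cfg_default):
        records = simulate_channel_run(20.0, 5, 2, cfg=cfg_default, seed=1)
        assert len(records) == 4 * 2
        channels = sorted({ch for ch, _, _ in records})
        assert channels == [0, 1, 2, 3]
        for _, image, truth in records:
            assert image.pixels.shape == cfg_default.sensor_shape
            assert len(truth) == 5
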