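"""Synthetic fringe-image rendering: signal model, noise, determinism."""

import numpy as np
import pytest

from swfringe.geometry import UM, DiscocyteSpecimen, HeightMap, discocyte_surfaces
from swfringe.imaging import (
    FringeImage,
    NoiseModel,
    foreshortening_factor,
    render_membrane_image,
    render_monolayer_image,
    simulate_subtraction_pair,
    subtract_images,
)
from swfringe.optics import DetectionMode, OpticsConfig, antinode_spacing
from swfringe.presets import cap_optics, cap_specimen, cap_surface


def flat_surface(z, shape=(64, 64), pixel_size=100.0):
    return HeightMap(np.full(shape, float(z)), pixel_size)


class TestMonolayerRender:
    def test_flat_surface_at_antinode_is_uniform(self):
        cfg = OpticsConfig(514.0)
        surface = flat_surface(514.0 / 4.0)
        img = render_monolayer_image(surface, cfg, NoiseModel.noiseless(200.0))
        assert np.allclose(img.data, 200.0)

    def test_contact_point_dark(self, cap_noiseless):
        img, _, spec, _ = cap_noiseless
        # expected value at the contact pixel is the background alone
        # (noiseless fixture renders without background: exactly 0)
        i = img.shape[0] // 2
        centre_patch = img.data[i - 1 : i + 1, i - 1 : i + 1]
        assert centre_patch.max() < 1e-3 * img.data.max()

    def test_same_seed_bit_identical(self):
        cfg = cap_optics()
        spec, px = cap_specimen(cfg, size=128)
        surface = cap_surface(spec, px, 128)
        noise = NoiseModel(photon_scale=300.0, background=5.0, seed=42)
        a = render_monolayer_image(surface, cfg, noise)
        b = render_monolayer_image(surface, cfg, noise)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        cfg = cap_optics()
        spec, px = cap_specimen(cfg, size=128)
        surface = cap_surface(spec, px, 128)
        a = render_monolayer_image(surface, cfg, NoiseModel(300.0, seed=1))
        b = render_monolayer_image(surface, cfg, NoiseModel(300.0, seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_negative_blur_rejected(self):
        cfg = cap_optics()
        surface = flat_surface(100.0)
        with pytest.raises(ValueError):
            render_monolayer_image(surface, cfg, NoiseModel.noiseless(), blur_sigma=-1)

    def test_noisy_mean_converges_to_noiseless(self):
        # mean of N noisy renders approaches the expected image on
        # bright pixels, with relative error < 3 / sqrt(N * photon_scale)
        cfg = cap_optics()
        spec, px = cap_specimen(cfg, size=128)
        surface = cap_surface(spec, px, 128)
        scale = 200.0
        noiseless = render_monolayer_image(surface, cfg, NoiseModel.noiseless(scale))
        n_renders = 50
        acc = np.zeros(noiseless.shape)
        for s in range(n_renders):
            acc += render_monolayer_image(
                surface, cfg, NoiseModel(photon_scale=scale, seed=s)
            ).data
        mean = acc / n_renders
        bright = noiseless.data > 0.5 * scale
        rel = np.abs(mean[bright] - noiseless.data[bright]) / noiseless.data[bright]
        assert rel.mean() < 3.0 / np.sqrt(n_renders * scale)

    def test_azimuthal_symmetry_of_noiseless_cap(self, cap_noiseless):
        # noiseless pixel value is a function of radius alone: the image
        # is exactly invariant under the dihedral symmetries of the grid
        # (centre sits on the grid symmetry point)
        img, _, _, _ = cap_noiseless
        scale = img.data.max()
        for sym in (np.rot90(img.data), np.rot90(img.data, 2), img.data.T):
            assert np.max(np.abs(sym - img.data)) < 1e-9 * scale


class TestMembraneRender:
    def test_degenerate_shell_doubles_signal(self):
        cfg = OpticsConfig(488.0, refractive_index=1.34)
        surface = flat_surface(300.0)
        noise = NoiseModel.noiseless(100.0)
        single = render_monolayer_image(surface, cfg, noise)
        double = render_membrane_image(surface, surface, cfg, noise)
        assert np.allclose(double.data, 2.0 * single.data)

    def test_control_without_mirror_shows_rim_only(self, discocyte_noiseless):
        from swfringe.presets import discocyte_fixture

        img, *_ = discocyte_fixture(noisy=False, mirror_present=False)
        n = img.shape[0] // 2
        centre = img.data[n - 2 : n + 2, n - 2 : n + 2].mean()
        assert img.data.max() / centre > 3.0

    def test_ring_count_matches_antinode_count(self):
        # for a monotone membrane sheet the number of distinct bright
        # rings equals the number of antinodes crossing its height range
        from swfringe.analysis import detect_peaks, radial_profile
        from swfringe.presets import cap_optics, cap_specimen, cap_surface

        cfg = OpticsConfig(488.0, refractive_index=1.34)
        n_antinodes = 12
        spec, px = cap_specimen(cfg, n_antinodes=n_antinodes, size=256)
        sheet = cap_surface(spec, px, 256)
        img = render_membrane_image(
            sheet, sheet, cfg, NoiseModel.noiseless(100.0)
        )
        spacing = antinode_spacing(cfg)
        zk = (2 * np.arange(200) + 1) * spacing / 2.0
        in_range = (zk >= np.nanmin(sheet.data)) & (
            zk <= sheet.data[128, :].max()  # profiled field: inscribed circle
        )
        profile = radial_profile(img, (127.5, 127.5))
        peaks = detect_peaks(profile)
        assert len(peaks) == int(in_range.sum()) == n_antinodes

    def test_mask_mismatch_rejected(self):
        cfg = OpticsConfig(488.0, refractive_index=1.34)
        a = flat_surface(300.0)
        b = HeightMap(np.where(np.eye(64) > 0, np.nan, 200.0), 100.0)
        with pytest.raises(ValueError):
            render_membrane_image(a, b, cfg, NoiseModel.noiseless())

    def test_upper_below_lower_rejected(self):
        cfg = OpticsConfig(488.0, refractive_index=1.34)
        with pytest.raises(ValueError):
            render_membrane_image(
                flat_surface(100.0), flat_surface(200.0), cfg, NoiseModel.noiseless()
            )


class TestForeshortening:
    def test_flat_surface_unity(self):
        assert np.allclose(foreshortening_factor(flat_surface(500.0)), 1.0)

    def test_known_slope(self):
        # plane z = x: |grad| = 1, factor sqrt(2)
        x = (np.arange(64) + 0.5) * 10.0
        hm = HeightMap(np.tile(x, (64, 1)), 10.0)
        f = foreshortening_factor(hm)
        assert np.allclose(f[:, 1:-1], np.sqrt(2.0), rtol=1e-6)


class TestSubtraction:
    def test_self_subtraction_zero(self, cap_noiseless):
        img, *_ = cap_noiseless
        assert np.all(subtract_images(img, img).data == 0)

    def test_shape_mismatch_rejected(self, cap_noiseless):
        img, *_ = cap_noiseless
        other = FringeImage(np.zeros((64, 64)), img.pixel_size)
        with pytest.raises(ValueError):
            subtract_images(img, other)

    def test_clipping_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = FringeImage(rng.random((64, 64)), 10.0)
        b = FringeImage(rng.random((64, 64)), 10.0)
        ab = subtract_images(a, b).data
        ba = subtract_images(b, a).data
        # at every pixel at most one of the clipped differences is nonzero
        assert np.all((ab > 0) & (ba > 0)) == False  # noqa: E712
        assert np.allclose(ab - ba, a.data - b.data)

    def test_near_equal_wavelengths_cancel(self):
        cfg = cap_optics()
        spec, px = cap_specimen(cfg, size=128)
        surface = cap_surface(spec, px, 128)
        ex, em, diff = simulate_subtraction_pair(
            surface, 514.0, 514.0 + 1e-6, 1.0,
            NoiseModel.noiseless(100.0), detection_bandwidth=0.0,
        )
        assert np.max(diff.data) < 1e-3 * np.max(ex.data)

    def test_difference_zero_at_contact(self, cap_noiseless):
        _, surface, spec, cfg = cap_noiseless
        ex, em, diff = simulate_subtraction_pair(
            surface, 514.0, 580.0, 1.0, NoiseModel.noiseless(100.0)
        )
        i = diff.shape[0] // 2
        assert diff.data[i - 1 : i + 1, i - 1 : i + 1].max() < 1e-3 * diff.data.max()

    def test_wavelength_order_enforced(self, cap_noiseless):
        _, surface, _, _ = cap_noiseless
        with pytest.raises(ValueError):
            simulate_subtraction_pair(
                surface, 580.0, 514.0, 1.0, NoiseModel.noiseless()
            )


class TestNoiseModel:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(photon_scale=0.0)
        with pytest.raises(ValueError):
            NoiseModel(photon_scale=10.0, read_noise_sd=-1.0)

    def test_read_noise_widens_distribution(self):
        cfg = OpticsConfig(514.0)
        surface = flat_surface(514.0 / 4.0)
        a = render_monolayer_image(surface, cfg, NoiseModel(1000.0, seed=0))
        b = render_monolayer_image(
            surface, cfg, NoiseModel(1000.0, read_noise_sd=50.0, seed=0)
        )
        assert b.data.std() > a.data.std()
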