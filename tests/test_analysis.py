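"""Measurement chain: centre, radial profile, peaks, spacing, envelope."""

import numpy as np
import pytest

from swfringe.analysis import (
    FringePeakSet,
    RadialProfile,
    analyze_cap_image,
    detect_peaks,
    estimate_envelope_period,
    estimate_spacing,
    estimate_spacing_differences,
    find_fringe_center,
    radial_profile,
    radii_to_heights,
)
from swfringe.errors import (
    CenterNotFoundError,
    EnvelopeNotFoundError,
    NoPeaksFoundError,
)
from swfringe.geometry import SphericalCapSpecimen, spherical_cap_radius
from swfringe.imaging import FringeImage
from swfringe.optics import antinode_spacing
from swfringe.presets import cap_fixture


class TestFindFringeCenter:
    def test_noiseless_cap_center(self, cap_noiseless):
        img, _, _, _ = cap_noiseless
        cx, cy = find_fringe_center(img)
        assert abs(cx - 255.5) <= 0.5 and abs(cy - 255.5) <= 0.5

    def test_translation_equivariance(self, cap_noiseless):
        img, _, _, _ = cap_noiseless
        shifted = FringeImage(
            np.roll(np.roll(img.data, 10, axis=1), -7, axis=0), img.pixel_size
        )
        cx, cy = find_fringe_center(shifted)
        assert abs(cx - (255.5 + 10)) <= 0.5
        assert abs(cy - (255.5 - 7)) <= 0.5

    def test_uniform_image_rejected(self):
        img = FringeImage(np.full((128, 128), 7.0), 100.0)
        with pytest.raises(CenterNotFoundError):
            find_fringe_center(img)

    def test_noise_only_image_rejected(self):
        rng = np.random.default_rng(3)
        img = FringeImage(rng.poisson(50.0, (128, 128)).astype(float), 100.0)
        with pytest.raises(CenterNotFoundError):
            find_fringe_center(img)


class TestRadialProfile:
    def test_uniform_image_constant_profile(self):
        img = FringeImage(np.full((128, 128), 3.5), 50.0)
        p = radial_profile(img, (63.5, 63.5))
        assert np.allclose(p.intensities, 3.5)

    def test_bin_width_doubling_halves_bins(self, cap_noiseless):
        img, _, _, _ = cap_noiseless
        p1 = radial_profile(img, (255.5, 255.5))
        p2 = radial_profile(img, (255.5, 255.5), bin_width=2 * img.pixel_size)
        assert abs(len(p1.radii) - 2 * len(p2.radii)) <= 2

    def test_bin_width_below_pixel_rejected(self, cap_noiseless):
        img, _, _, _ = cap_noiseless
        with pytest.raises(ValueError):
            radial_profile(img, (255.5, 255.5), bin_width=0.5 * img.pixel_size)

    def test_profile_peaks_at_analytic_antinode_radii(self, cap_noiseless):
        img, _, spec, cfg = cap_noiseless
        p = radial_profile(img, (255.5, 255.5))
        peaks = detect_peaks(p)
        spacing = antinode_spacing(cfg)
        zk = (2 * np.arange(len(peaks)) + 1) * spacing / 2.0
        rk = spherical_cap_radius(zk, spec)
        assert np.allclose(peaks.peak_radii, rk, atol=img.pixel_size)


class TestDetectPeaks:
    def test_sine_squared_profile_analytic_maxima(self):
        r = np.arange(0.5, 1000.0, 1.0)
        p = RadialProfile(r, np.sin(np.pi * r / 100.0) ** 2, 1.0, (0.0, 0.0))
        peaks = detect_peaks(p, min_separation=10.0)
        expected = np.arange(50.0, 1000.0, 100.0)
        assert len(peaks) == len(expected)
        assert np.allclose(peaks.peak_radii, expected, atol=0.5)

    def test_flat_profile_rejected(self):
        p = RadialProfile(np.arange(0.5, 100.0), np.ones(100), 1.0, (0, 0))
        with pytest.raises(NoPeaksFoundError):
            detect_peaks(p)

    def test_default_cap_fixture_has_37_peaks(self, cap_noiseless):
        img, _, _, _ = cap_noiseless
        p = radial_profile(img, (255.5, 255.5))
        assert len(detect_peaks(p)) == 37

    def test_refinement_matches_oversampled_argmax_oracle(self):
        # brute-force argmax over a 100x oversampled cubic interpolation
        # agrees with the bounded-minimisation refinement within 0.1 bin
        from scipy.interpolate import CubicSpline

        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(50):
            # random smooth profile: a few random broad Gaussian bumps
            r = np.arange(0.5, 200.0, 1.0)
            v = np.zeros_like(r)
            for _ in range(rng.integers(2, 6)):
                c = rng.uniform(20, 180)
                w = rng.uniform(6, 25)
                v += rng.uniform(0.3, 1.0) * np.exp(-((r - c) ** 2) / (2 * w**2))
            try:
                peaks = detect_peaks(
                    RadialProfile(r, v, 1.0, (0, 0)), min_separation=5.0
                )
            except NoPeaksFoundError:
                continue
            for pr in peaks.peak_radii:
                i = np.argmin(np.abs(r - pr))
                lo, hi = max(0, i - 4), min(len(r), i + 5)
                spline = CubicSpline(r[lo:hi], v[lo:hi])
                dense = np.linspace(max(r[lo], pr - 1.5), min(r[hi - 1], pr + 1.5),
                                    300)
                oracle = dense[np.argmax(spline(dense))]
                worst = max(worst, abs(oracle - pr))
        assert worst <= 0.1


class TestHeightsAndSpacing:
    def test_exact_antinode_ladder(self):
        spec = SphericalCapSpecimen(30.0e6)
        z = (2 * np.arange(10) + 1) * 128.5
        r = spherical_cap_radius(z, spec)
        peaks = radii_to_heights(
            FringePeakSet(r, np.ones(len(r))), spec
        )
        assert np.allclose(peaks.peak_heights_z, z, rtol=1e-12)
        assert np.array_equal(peaks.antinode_index, np.arange(10))
        s, sd = estimate_spacing(peaks)
        assert s == pytest.approx(257.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_radius_exceeding_sphere_rejected(self):
        spec = SphericalCapSpecimen(1.0e6)
        peaks = FringePeakSet(np.array([0.5e6, 2.0e6]), np.ones(2))
        with pytest.raises(ValueError):
            radii_to_heights(peaks, spec)

    def test_too_few_peaks_rejected(self):
        spec = SphericalCapSpecimen(30.0e6)
        peaks = radii_to_heights(
            FringePeakSet(np.array([1e4, 2e4]), np.ones(2)), spec
        )
        with pytest.raises(ValueError):
            estimate_spacing(peaks)

    def test_regression_and_differences_agree_on_clean_data(self):
        spec = SphericalCapSpecimen(30.0e6)
        z = (2 * np.arange(15) + 1) * 128.5
        r = spherical_cap_radius(z, spec)
        peaks = radii_to_heights(FringePeakSet(r, np.ones(len(r))), spec)
        s1, _ = estimate_spacing(peaks)
        s2, _ = estimate_spacing_differences(peaks)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_spacing_invariant_to_intensity_scaling(self, cap_noisy):
        img, _, spec, cfg = cap_noisy
        rep1 = analyze_cap_image(img, cfg, spec)
        scaled = FringeImage(img.data * 7.5, img.pixel_size)
        rep2 = analyze_cap_image(scaled, cfg, spec)
        assert rep2.spacing_nm == pytest.approx(rep1.spacing_nm, rel=1e-6)


class TestEnvelopePeriod:
    def test_constructed_envelope(self):
        # amplitudes modulated as sin^2(pi z / 2258.5 nm) -> L = 4517 nm
        period = 2258.4848484848485
        z = (2 * np.arange(40) + 1) * 128.5
        amps = np.sin(np.pi * z / period) ** 2
        peaks = FringePeakSet(
            np.sqrt(z) * 1000.0, amps,
            peak_heights_z=z, antinode_index=np.arange(40),
        )
        est = estimate_envelope_period(peaks)
        assert 2.0 * est == pytest.approx(4517.0, rel=0.01)

    def test_unmodulated_amplitudes_rejected(self):
        z = (2 * np.arange(40) + 1) * 128.5
        amps = np.full(40, 0.8) - 1e-5 * z / z.max()  # flat, slight decay
        peaks = FringePeakSet(
            np.sqrt(z) * 1000.0, amps,
            peak_heights_z=z, antinode_index=np.arange(40),
        )
        with pytest.raises(EnvelopeNotFoundError):
            estimate_envelope_period(peaks)

    def test_moire_fixture_recovers_L(self, cap_moire_noisy):
        img, _, spec, cfg = cap_moire_noisy
        rep = analyze_cap_image(img, cfg, spec, estimate_envelope=True)
        assert rep.envelope_L_nm == pytest.approx(4520.0, rel=0.05)


class TestEndToEndRecovery:
    def test_mean_recovery_over_seeds(self):
        # 20 seeded noisy cap fixtures: mean recovered spacing within 1% of
        # lambda/2n and mean envelope period within 5% of L/2n
        spacings = []
        for seed in range(20):
            img, _, spec, cfg = cap_fixture(seed=seed, photon_scale=500.0,
                                            background=5.0)
            rep = analyze_cap_image(img, cfg, spec)
            spacings.append(rep.spacing_nm)
        assert np.mean(spacings) == pytest.approx(257.0, rel=0.01)

        envelopes = []
        for seed in range(20):
            img, _, spec, cfg = cap_fixture(
                mode="narrowband_moire", seed=seed,
                photon_scale=500.0, background=5.0,
            )
            rep = analyze_cap_image(img, cfg, spec, estimate_envelope=True)
            envelopes.append(rep.envelope_L_nm)
        assert np.mean(envelopes) == pytest.approx(4516.97, rel=0.05)
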