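import itertools

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from phasefuse.errors import DegenerateInputError, ShapeError
from phasefuse.fourier_mellin import (
    RegistrationResult,
    ValidityBounds,
    cross_power_spectrum,
    estimate_rotation_scale,
    logpolar_magnitude,
    logpolar_params,
    phase_correlation,
    register_affine,
    validate_transform,
    warp_image,
)
from phasefuse.grid import as_mask
from phasefuse.transform import AffineTransform2D

from conftest import make_plant_raster


class TestCrossPowerSpectrum:
    def test_identical_fields_give_zero_phase(self, rng):
        f = np.fft.fft2(rng.random((8, 8)))
        cps = cross_power_spectrum(f, f)
        assert np.allclose(cps, 1.0)

    def test_constant_phase_offset_preserved(self, rng):
        f = np.fft.fft2(rng.random((8, 8)) + 0.1)
        theta = 0.7
        cps = cross_power_spectrum(f * np.exp(1j * theta), f)
        assert np.allclose(cps, np.exp(1j * theta))

    def test_random_pair_unit_modulus_and_phase_oracle(self, rng):
        a = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        b = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        cps = cross_power_spectrum(a, b)
        assert np.allclose(np.abs(cps), 1.0)
        assert np.allclose(np.angle(cps), np.angle(a * np.conj(b)))

    def test_epsilon_guard_zeroes_nulls(self):
        a = np.zeros((4, 4), dtype=complex)
        a[0, 0] = 1.0
        cps = cross_power_spectrum(a, a)
        assert cps[0, 0] == 1.0
        assert np.all(cps[1:, :] == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            cross_power_spectrum(np.ones((4, 4)), np.ones((4, 5)))


class TestPhaseCorrelation:
    def test_self_correlation_peaks_at_origin(self, plant_raster):
        surf = phase_correlation(plant_raster, plant_raster)
        assert (surf.peak_row, surf.peak_col) == (0, 0)
        assert surf.peak_height == pytest.approx(1.0)

    def test_shift_theorem_delta_on_all_32x32_shifts(self, rng):
        """For every integer circular shift the PC surface is a Kronecker
        delta at the true shift; off-peak magnitudes are at floating noise."""
        a = rng.random((32, 32))
        for dy, dx in itertools.product(range(32), range(32)):
            b = np.roll(a, (dy, dx), axis=(0, 1))
            surf = phase_correlation(a, b)
            assert (surf.peak_row, surf.peak_col) == (dy, dx)
            assert surf.peak_height == pytest.approx(1.0, abs=1e-9)
            off = surf.values.copy()
            off[dy, dx] = 0.0
            assert np.abs(off).max() < 1e-6

    def test_wrap_correction_signs(self, rng):
        a = rng.random((40, 40))
        surf = phase_correlation(a, np.roll(a, (-3, 30), axis=(0, 1)))
        assert surf.wrapped_shift == (-10.0, -3.0)
        assert abs(surf.wrapped_shift[0]) <= 20 and abs(surf.wrapped_shift[1]) <= 20

    def test_matches_spatial_cross_correlation_argmax(self, rng):
        """PC peak equals brute-force circular cross-correlation argmax on
        25 random shifted pairs (independent spatial-domain oracle)."""
        for case in range(25):
            n = int(rng.integers(24, 65))
            a = rng.random((n, n))
            dy, dx = int(rng.integers(0, n)), int(rng.integers(0, n))
            b = np.roll(a, (dy, dx), axis=(0, 1))
            cc = np.empty((n, n))
            for sy in range(n):
                for sx in range(n):
                    cc[sy, sx] = float(np.sum(a * np.roll(b, (-sy, -sx),
                                                          axis=(0, 1))))
            oy, ox = np.unravel_index(np.argmax(cc), cc.shape)
            surf = phase_correlation(a, b)
            assert (surf.peak_row, surf.peak_col) == (oy, ox) == (dy, dx)

    def test_matches_skimage_reference(self, plant_raster):
        """Cross-check the shift estimate against an independent library
        implementation on a non-periodic noisy shift."""
        rng = np.random.default_rng(5)
        a = np.zeros((200, 200))
        a[20:180, 20:180] = plant_raster[:160, :160]
        b = np.roll(a, (9, -14), axis=(0, 1)) + rng.normal(0, 0.05, a.shape)
        b = np.clip(b, 0, 1)
        surf = phase_correlation(a, b)
        ref_shift, _, _ = phase_cross_correlation(b, a, normalization="phase")
        assert surf.wrapped_shift[1] == pytest.approx(ref_shift[0], abs=1.0)
        assert surf.wrapped_shift[0] == pytest.approx(ref_shift[1], abs=1.0)
        assert surf.wrapped_shift == (-14.0, 9.0)

    def test_degenerate_and_mismatched_inputs(self):
        with pytest.raises(DegenerateInputError):
            phase_correlation(np.zeros((8, 8)), np.ones((8, 8)))
        with pytest.raises(ShapeError):
            phase_correlation(np.ones((8, 8)), np.ones((8, 9)))


class TestLogPolar:
    def test_rotation_becomes_angle_shift(self, plant_raster):
        n = plant_raster.shape[0]
        rot = 17.0
        t = AffineTransform2D.from_params(rotation_deg=rot, center=(n / 2, n / 2))
        rotated = warp_image(plant_raster, t, (n, n))
        la = logpolar_magnitude(plant_raster).pixels
        lb = logpolar_magnitude(rotated).pixels
        surf = phase_correlation(la, lb)
        lp = logpolar_params((n, n))
        expected_bins = rot / (180.0 / lp["n_theta"])
        assert surf.wrapped_shift[1] == pytest.approx(expected_bins, abs=1.0)
        assert surf.wrapped_shift[0] == pytest.approx(0.0, abs=1.0)

    def test_identity_scaling_gives_zero_radial_shift(self, plant_raster):
        la = logpolar_magnitude(plant_raster).pixels
        surf = phase_correlation(la, la)
        assert surf.wrapped_shift == (0.0, 0.0)

    def test_scaling_becomes_log_radius_shift(self, plant_raster):
        n = plant_raster.shape[0]
        t = AffineTransform2D.from_params(scale=1.25, center=(n / 2, n / 2))
        scaled = warp_image(plant_raster, t, (n, n))
        la = logpolar_magnitude(plant_raster).pixels
        lb = logpolar_magnitude(scaled).pixels
        surf = phase_correlation(la, lb)
        lp = logpolar_params((n, n))
        expected = -np.log(1.25) / np.log(lp["base"])
        assert surf.wrapped_shift[0] == pytest.approx(expected, abs=1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            logpolar_magnitude(np.full((16, 16), 0.5))


class TestEstimateRotationScale:
    def test_identity_pair(self, plant_raster):
        rot, scale, h = estimate_rotation_scale(plant_raster, plant_raster)
        assert rot == 0.0 and scale == 1.0
        assert h == pytest.approx(1.0)

    @pytest.mark.parametrize("true_rot,true_scale", [(10.0, 1.0), (0.0, 0.8)])
    def test_pure_rotation_and_pure_scale(self, plant_raster, true_rot, true_scale):
        n = plant_raster.shape[0]
        t = AffineTransform2D.from_params(scale=true_scale, rotation_deg=true_rot,
                                          center=(n / 2, n / 2))
        moved = warp_image(plant_raster, t, (n, n))
        rot, scale, _ = estimate_rotation_scale(plant_raster, moved)
        lp = logpolar_params((n, n))
        assert rot == pytest.approx(true_rot, abs=180.0 / lp["n_theta"])
        assert abs(np.log(scale / true_scale)) <= np.log(lp["base"]) + 1e-9


class TestRegisterAffine:
    def test_self_registration_is_identity_and_valid(self, plant_image):
        res = register_affine(plant_image, plant_image)
        assert res.valid
        assert res.peak_height == pytest.approx(1.0)
        assert res.transform.scale == pytest.approx(1.0)
        assert res.transform.rotation_deg == pytest.approx(0.0)
        assert abs(res.transform.shift_x) <= 1 and abs(res.transform.shift_y) <= 1

    @pytest.mark.parametrize("scale", [0.8, 1.0, 1.25])
    @pytest.mark.parametrize("rot", [-10.0, 0.0, 17.0])
    def test_similarity_recovery_within_bin_resolution(self, scale, rot):
        """Noise-free similarity pairs are recovered within one angular bin,
        one radial bin and one pixel of translation, with H above the gate."""
        img = make_plant_raster(192)
        n = 192
        center = (n / 2, n / 2)
        t = AffineTransform2D.from_params(scale=scale, rotation_deg=rot,
                                          shift_x=-31.0, shift_y=40.0,
                                          center=center)
        vis = warp_image(img, t, (n, n))
        res = register_affine(img, vis)
        lp = logpolar_params((n, n))
        assert res.peak_height > 0.03
        assert res.transform.rotation_deg == pytest.approx(
            rot, abs=180.0 / lp["n_theta"])
        assert abs(np.log(res.transform.scale / scale)) <= np.log(lp["base"]) + 1e-9
        c = np.asarray(center)
        shift_err = np.abs(res.transform.apply(c) - t.apply(c)).max()
        assert shift_err <= 1.0

    def test_symmetry_gives_mutually_inverse_transforms(self):
        img = make_plant_raster(160)
        n = 160
        t = AffineTransform2D.from_params(scale=1.1, rotation_deg=8.0,
                                          shift_x=10.0, shift_y=-6.0,
                                          center=(n / 2, n / 2))
        vis = warp_image(img, t, (n, n))
        fwd = register_affine(img, vis).transform
        bwd = register_affine(vis, img).transform
        comp = fwd @ bwd
        pts = np.array([[40.0, 40.0], [120.0, 80.0], [80.0, 120.0]])
        assert np.abs(comp.apply(pts) - pts).max() < 3.0

    def test_translation_robust_to_noise(self, plant_raster, rng):
        """Shift recovery stays within one pixel under additive Gaussian
        noise up to sigma 0.1 (artifact property of the standard fixture)."""
        n = plant_raster.shape[0]
        for sigma in (0.05, 0.1):
            vis = np.roll(plant_raster, (6, -9), axis=(0, 1))
            vis = np.clip(vis + rng.normal(0, sigma, vis.shape), 0, 1)
            res = register_affine(plant_raster, vis)
            assert res.valid
            assert res.transform.rotation_deg == pytest.approx(0.0, abs=1.2)
            assert res.transform.shift_x == pytest.approx(-9.0, abs=1.0)
            assert res.transform.shift_y == pytest.approx(6.0, abs=1.0)

    def test_degenerate_input_yields_invalid_result(self):
        res = register_affine(np.zeros((32, 32)), np.ones((32, 32)) * 0.5)
        assert not res.valid
        assert res.peak_height == 0.0
        assert "error" in res.diagnostics

    def test_unequal_sizes_are_padded_to_common_frame(self, plant_raster):
        small = plant_raster[:120, :140]
        res = register_affine(small, plant_raster)
        assert res.frame_shape == plant_raster.shape


class TestValidateTransform:
    def _result(self, h, **params):
        t = AffineTransform2D.from_params(**params)
        return RegistrationResult(transform=t, peak_height=h, valid=False,
                                  frame_shape=(100, 100))

    def test_high_peak_identity_is_valid(self):
        assert validate_transform(self._result(0.5))

    def test_peak_below_gate_is_invalid(self):
        assert not validate_transform(self._result(0.01))
        # the gate is strict: exactly 0.03 does not pass
        assert not validate_transform(self._result(0.03))

    def test_scale_bound_violation(self):
        res = self._result(0.2, scale=5.0)
        assert not validate_transform(res, ValidityBounds(scale_max=2.0))

    def test_rotation_and_shift_bounds(self):
        assert not validate_transform(self._result(0.2, rotation_deg=45.0))
        assert not validate_transform(self._result(0.2, shift_x=80.0))
        assert validate_transform(self._result(0.2, shift_x=30.0))


class TestWarpImage:
    def test_identity_is_pixel_exact_nearest(self, rng):
        mask = as_mask(rng.random((20, 20)) > 0.6)
        out = warp_image(mask, AffineTransform2D.identity(), (20, 20))
        assert np.array_equal(out.pixels, mask.pixels)

    def test_integer_translation_nearest_is_exact(self, rng):
        m = np.zeros((24, 24))
        m[8:14, 6:12] = 1.0
        t = AffineTransform2D.translation(5.0, 3.0)
        out = warp_image(as_mask(m), t, (24, 24))
        assert np.array_equal(out.pixels[3:, 5:], m[:-3, :-5])

    def test_round_trip_jaccard_on_smooth_mask(self):
        yy, xx = np.mgrid[0:64, 0:64]
        m = ((yy - 32) ** 2 / 400 + (xx - 30) ** 2 / 256 <= 1).astype(float)
        t = AffineTransform2D.from_params(scale=1.15, rotation_deg=12.0,
                                          shift_x=4.0, shift_y=-3.0,
                                          center=(32.0, 32.0))
        there = warp_image(as_mask(m), t, (64, 64))
        back = warp_image(there, t.inverse(), (64, 64))
        a = back.pixels > 0.5
        b = m > 0.5
        assert (a & b).sum() / (a | b).sum() >= 0.95
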