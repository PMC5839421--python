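"""Velocity-field exponentials, demons forces, and pairwise registration."""

import numpy as np
import pytest

import odatlas as od
from odatlas.registration import _identity_grid, compose_displacements

from conftest import rk4_flow, rms


def smooth_field(seed, shape=(64, 64), amplitude=3.0, sigma=8.0):
    rng = np.random.default_rng(seed)
    return od.synthetic.random_smooth_field(shape, amplitude, sigma, rng)


class TestFieldExponential:
    def test_zero_field_is_identity(self):
        d = od.field_exponential(np.zeros((2, 32, 32)))
        assert np.all(d == 0)

    def test_constant_field_translates_interior(self):
        v = np.zeros((2, 48, 48))
        v[1] = 1.3
        d = od.field_exponential(v)
        interior = d[:, 10:-10, 10:-10]
        assert np.allclose(interior[1], 1.3, atol=1e-9)
        assert np.allclose(interior[0], 0.0, atol=1e-9)

    def test_nonfinite_rejected(self):
        v = np.zeros((2, 8, 8))
        v[0, 3, 3] = np.nan
        with pytest.raises(ValueError):
            od.field_exponential(v)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_rk4_integration(self, seed):
        v = smooth_field(seed)
        d = od.field_exponential(v)
        d_ref = rk4_flow(v)
        assert rms(d - d_ref) < 0.05

    def test_inverse_composition_is_identity(self):
        v = smooth_field(3, amplitude=5.0)
        fwd = od.field_exponential(v)
        bwd = od.field_exponential(-v)
        comp = compose_displacements(bwd, fwd)
        assert rms(comp[:, 8:-8, 8:-8]) < 0.05

    def test_one_parameter_subgroup(self):
        v = smooth_field(7, amplitude=4.0)
        whole = od.field_exponential(v)
        half = od.field_exponential(0.5 * v)
        comp = compose_displacements(half, half)
        assert rms((whole - comp)[:, 8:-8, 8:-8]) < 0.05


class TestDemonsUpdate:
    def test_zero_difference_gives_zero(self):
        img = np.random.default_rng(0).random((32, 32))
        u = od.demons_update(img, img)
        assert np.all(u == 0)

    def test_unit_gradient_unit_difference(self):
        # moving has gradient (1, 0) in x; fixed is one level higher
        xx = np.tile(np.arange(32, dtype=float), (32, 1))
        u = od.demons_update(xx + 1.0, xx)
        interior = u[:, 8:-8, 8:-8]
        assert np.allclose(interior[1], 0.5, atol=1e-12)
        assert np.allclose(interior[0], 0.0, atol=1e-12)

    def test_zero_gradient_guarded(self):
        flat = np.zeros((16, 16))
        u = od.demons_update(flat + 1.0, flat)
        assert np.all(u == 0)

    def test_step_cap(self):
        rng = np.random.default_rng(1)
        fixed = rng.random((32, 32)) * 100
        u = od.demons_update(fixed, np.zeros((32, 32)), step_cap=2.0)
        assert np.sqrt((u**2).sum(axis=0)).max() <= 2.0 + 1e-12


class TestRegularize:
    def test_zero_update_small_sigma_keeps_field(self):
        cfg = od.DemonsConfig(sigma_fluid=1.0, sigma_diff=1e-6)
        v = smooth_field(0, shape=(32, 32))
        out = od.regularize(v, np.zeros_like(v), cfg)
        assert np.allclose(out, v, atol=1e-6)

    def test_impulse_becomes_cascaded_gaussian(self):
        cfg = od.DemonsConfig(sigma_fluid=2.0, sigma_diff=1.5)
        u = np.zeros((2, 65, 65))
        u[1, 32, 32] = 1.0
        out = od.regularize(np.zeros_like(u), u, cfg)
        # cascade of two Gaussians = Gaussian with combined variance
        from scipy.ndimage import gaussian_filter
        expected = gaussian_filter(u[1], np.hypot(2.0, 1.5), mode="reflect",
                                   truncate=4.0)
        assert np.allclose(out[1], expected, atol=2e-4)

    def test_mean_preserved(self):
        cfg = od.DemonsConfig()
        v = smooth_field(2, shape=(40, 40))
        u = smooth_field(3, shape=(40, 40))
        out = od.regularize(v, u, cfg)
        assert np.allclose(out.mean(axis=(1, 2)),
                           (v + u).mean(axis=(1, 2)), atol=1e-3)


class TestJacobian:
    def test_identity_is_one(self):
        det = od.jacobian_determinant(np.zeros((2, 24, 24)))
        assert np.allclose(det, 1.0)

    def test_linear_expansion_closed_form(self):
        # v = 0.1 (x - xc, y - yc) integrates to a uniform scaling by e^0.1,
        # so the Jacobian determinant is e^0.2 in the interior
        m = 64
        grid = _identity_grid((m, m))
        v = 0.1 * (grid - (m - 1) / 2.0)
        det = od.jacobian_determinant(od.field_exponential(v))
        interior = det[16:-16, 16:-16]
        assert np.allclose(interior, np.exp(0.2), rtol=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_smooth_fields_never_fold(self, seed):
        v = smooth_field(seed, amplitude=5.0, sigma=6.0)
        det = od.jacobian_determinant(od.field_exponential(v))
        assert det.min() > 0


class TestWarp:
    def test_identity_field(self):
        img = np.random.default_rng(0).random((32, 32))
        assert np.allclose(od.warp(img, np.zeros((2, 32, 32))), img)

    def test_constant_shift(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 1.0
        phi = np.zeros((2, 32, 32))
        phi[1] = 3.0     # sample 3 px to the right -> content moves left
        out = od.warp(img, phi)
        assert np.allclose(out[10:20, 7:17], 1.0)

    def test_rgb_channels_independent(self):
        rng = np.random.default_rng(5)
        img = rng.random((24, 24, 3))
        phi = smooth_field(1, shape=(24, 24), amplitude=2.0)
        out = od.warp(img, phi)
        for c in range(3):
            assert np.allclose(out[..., c], od.warp(img[..., c], phi))

    def test_inverse_warp_round_trip(self):
        rng = np.random.default_rng(4)
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.random((64, 64)), 2.0)
        v = smooth_field(9, amplitude=3.0)
        fwd = od.warp(img, od.field_exponential(v))
        back = od.warp(fwd, od.field_exponential(-v))
        assert rms((back - img)[8:-8, 8:-8]) < 0.02

    def test_matches_simpleitk_resampling(self):
        SimpleITK = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(11)
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.random((48, 48)), 2.0)
        phi = smooth_field(13, shape=(48, 48), amplitude=2.0)
        ours = od.warp(img, phi)
        disp = np.stack([phi[1], phi[0]], axis=-1)  # sitk wants (x, y) vectors
        tx = SimpleITK.DisplacementFieldTransform(
            SimpleITK.GetImageFromArray(disp, isVector=True))
        ref = SimpleITK.GetArrayFromImage(SimpleITK.Resample(
            SimpleITK.GetImageFromArray(img), tx, SimpleITK.sitkLinear, 0.0))
        assert rms((ours - ref)[4:-4, 4:-4]) < 1e-6


class TestLogDemonsRegister:
    def test_already_aligned(self, rep96):
        v = od.log_demons_register(rep96, rep96)
        assert np.abs(v).max() < 0.05

    def test_recovers_translation(self, rep96):
        shift = np.zeros((2, 96, 96))
        shift[0], shift[1] = 2.0, 4.0
        moving = od.warp(rep96, shift)
        v = od.log_demons_register(rep96, moving)
        warped = od.warp(moving, od.field_exponential(v))
        ssd0 = ((rep96 - moving) ** 2).sum()
        ssd1 = ((rep96 - warped) ** 2).sum()
        assert ssd1 < 0.02 * ssd0

    def test_residual_reduction_on_diffeomorphic_pair(self, rep96):
        rng = np.random.default_rng(6)
        v_true = od.synthetic.random_smooth_field((96, 96), 6.0, 10.0, rng)
        moving = od.warp(rep96, od.field_exponential(v_true))
        v = od.log_demons_register(rep96, moving)
        res0, _ = od.registration_residual(rep96, moving, np.zeros_like(v))
        res1, _ = od.registration_residual(rep96, moving, v)
        assert res1 < 0.2 * res0
        det = od.jacobian_determinant(od.field_exponential(v))
        assert det.min() > 0

    def test_energy_trend_decreases(self, rep96):
        shift = np.zeros((2, 96, 96))
        shift[1] = 3.0
        moving = od.warp(rep96, shift)
        v, trace = od.log_demons_register(rep96, moving, return_trace=True)
        trace = np.asarray(trace)
        # transient increases allowed but rare (trace spans pyramid levels)
        increases = np.diff(trace) > 0.05 * trace[:-1]
        assert increases.mean() < 0.2
        warped = od.warp(moving, od.field_exponential(v))
        assert ((rep96 - warped) ** 2).sum() < 0.1 * ((rep96 - moving) ** 2).sum()

    def test_approximate_symmetry(self, rep96):
        # log-demons is not exactly symmetric; on smooth small deformations
        # the forward and backward fields should still nearly cancel
        rng = np.random.default_rng(8)
        v1 = od.synthetic.random_smooth_field((96, 96), 4.0, 16.0, rng)
        v2 = od.synthetic.random_smooth_field((96, 96), 4.0, 16.0, rng)
        a = od.warp(rep96, od.field_exponential(v1))
        b = od.warp(rep96, od.field_exponential(v2))
        v_ab = od.log_demons_register(a, b)
        v_ba = od.log_demons_register(b, a)
        asym = np.linalg.norm(v_ab + v_ba)
        assert asym < 0.3 * np.linalg.norm(v_ab)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            od.log_demons_register(np.zeros((32, 32)), np.zeros((16, 16)))
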