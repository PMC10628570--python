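"""CC objective, affine resampling/recovery, and nonlinear field recovery."""

import numpy as np
import pytest
from scipy import ndimage

from restbrain.registration import (AffineParams, DisplacementField,
                                    RegistrationConfig, affine_register,
                                    apply_affine, apply_field, compose_affine,
                                    correlation_coefficient, nonlinear_register)
from restbrain.volgrid import MaskVolume, Volume, gaussian_smooth


def smooth_phantom(shape=(48, 48, 32), spacing=(3.0, 3.0, 3.0)):
    x, y, z = np.indices(shape).astype(float)
    img = (np.exp(-(((x - 24) / 10.0) ** 2 + ((y - 24) / 12.0) ** 2 + ((z - 16) / 8.0) ** 2))
           + 0.3 * np.exp(-(((x - 30) / 4.0) ** 2 + ((y - 18) / 5.0) ** 2 + ((z - 20) / 4.0) ** 2)))
    return Volume(img, spacing)


class TestCC:
    def test_self_correlation_one(self, rng):
        x = rng.standard_normal((6, 6, 6))
        assert correlation_coefficient(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_antisymmetry(self, rng):
        x = rng.standard_normal((6, 6, 6))
        assert correlation_coefficient(x, -x + 5.0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_pearson(self, rng):
        a = rng.standard_normal((6, 6, 6))
        b = rng.standard_normal((6, 6, 6))
        am, bm = a.mean(), b.mean()
        direct = (((a - am) * (b - bm)).sum()
                  / np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum()))
        assert correlation_coefficient(a, b) == pytest.approx(direct, abs=1e-12)

    def test_intensity_rescale_invariance(self, rng):
        a = rng.standard_normal((8, 8, 8))
        b = rng.standard_normal((8, 8, 8))
        base = correlation_coefficient(a, b)
        assert abs(correlation_coefficient(3.2 * a + 7.0, b) - base) < 1e-10
        assert abs(correlation_coefficient(a, 0.5 * b - 2.0) - base) < 1e-10

    def test_constant_image_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlation_coefficient(np.ones((4, 4, 4)), rng.standard_normal((4, 4, 4)))


class TestApplyAffine:
    def test_identity(self):
        vol = smooth_phantom()
        out = apply_affine(vol, AffineParams.identity())
        np.testing.assert_allclose(out.data, vol.data, atol=1e-10)

    def test_one_voxel_translation_nearest_is_shift(self):
        vol = smooth_phantom((16, 16, 12))
        p = AffineParams(np.eye(3), np.array([3.0, 0.0, 0.0]))  # +1 voxel in x
        out = apply_affine(vol, p, interp="nearest")
        np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-12)

    def test_composition_matches_composed_matrix(self):
        # trilinear interpolation is exact on an affine-in-space image, so
        # sequential resampling must equal the composed-matrix resampling
        # to numerical precision away from the out-of-field boundary
        x, y, z = np.indices((24, 24, 16)).astype(float)
        vol = Volume(0.3 * x - 0.7 * y + 1.1 * z + 5.0, (3.0, 3.0, 3.0))
        p1 = AffineParams(np.diag([1.05, 0.95, 1.0]), np.array([2.0, -1.0, 0.5]))
        th = np.radians(4.0)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        p2 = AffineParams(R, np.array([-1.0, 0.5, 1.0]))
        seq = apply_affine(apply_affine(vol, p1), p2)
        combined = apply_affine(vol, compose_affine(p1, p2))
        inner = (slice(4, -4),) * 3
        assert np.abs(seq.data[inner] - combined.data[inner]).max() < 1e-6

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineParams(np.zeros((3, 3)), np.zeros(3))


class TestAffineRegister:
    def test_self_registration_recovers_identity(self):
        vol = smooth_phantom()
        p = affine_register(vol, vol, RegistrationConfig(dof="rigid", pyramid=(2, 1)))
        assert np.abs(p.translation).max() < 0.1 * 3.0  # 0.1 voxel
        assert np.abs(p.rotation_angles_deg()).max() < 0.2

    def test_known_shift_and_rotation_recovered(self):
        fixed = smooth_phantom()
        shape = fixed.data.shape
        th = np.radians(5.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        center_mm = (np.array(shape) - 1) / 2.0 * 3.0
        t_mm = np.array([3.0, -2.0, 1.0]) * 3.0
        p_true = AffineParams(R, t_mm + center_mm - R @ center_mm)
        moving = apply_affine(fixed, p_true)
        p = affine_register(moving, fixed, RegistrationConfig(dof="rigid"))
        # composing true and recovered transforms should give the identity
        resid = compose_affine(p_true, p)
        rot_err = np.degrees(np.arccos(np.clip((np.trace(resid.matrix) - 1) / 2, -1, 1)))
        assert rot_err < 1.0
        assert np.linalg.norm(resid.translation) / 3.0 < 0.5  # voxels

    def test_cc_never_below_identity(self, rng):
        fixed = smooth_phantom((24, 24, 16))
        moving = Volume(fixed.data + 0.3 * rng.standard_normal(fixed.data.shape),
                        fixed.spacing)
        p = affine_register(moving, fixed,
                            RegistrationConfig(dof="rigid", pyramid=(2, 1), maxiter=40))
        cc_id = correlation_coefficient(moving, fixed)
        cc_fit = correlation_coefficient(apply_affine(moving, p, out_grid=fixed), fixed)
        assert cc_fit >= cc_id - 1e-12


class TestField:
    def _bump_setup(self):
        shape, spacing = (32, 32, 24), (3.0, 3.0, 3.0)
        x, y, z = np.indices(shape).astype(float)
        r = np.sqrt((x - 16) ** 2 + (y - 16) ** 2 + (z - 12) ** 2)
        rng = np.random.default_rng(5)
        # concentric-shell phantom: the radial deformation is visible to
        # the intensity metric everywhere
        img = np.cos(r / 1.8) * np.exp(-r / 14.0) + 0.05 * rng.standard_normal(shape)
        fixed = gaussian_smooth(Volume(img, spacing), 4.0)
        bump = 4.0 * np.exp(-r ** 2 / 50.0)
        dirs = np.stack([x - 16, y - 16, z - 12], axis=-1)
        nrm = np.linalg.norm(dirs, axis=-1, keepdims=True)
        nrm[nrm == 0] = 1.0
        u_true = bump[..., None] * dirs / nrm
        fld_true = DisplacementField(u_true, spacing, fixed.affine.copy())
        return fixed, apply_field(fixed, fld_true), u_true

    def test_zero_field_identity(self):
        vol = smooth_phantom((16, 16, 12))
        fld = DisplacementField(np.zeros(vol.data.shape + (3,)), vol.spacing,
                                vol.affine.copy())
        np.testing.assert_allclose(apply_field(vol, fld).data, vol.data, atol=1e-12)

    def test_constant_field_matches_affine_translation(self):
        vol = smooth_phantom((16, 16, 12))
        u = np.zeros(vol.data.shape + (3,))
        u[..., 1] = 3.0
        fld = DisplacementField(u, vol.spacing, vol.affine.copy())
        via_field = apply_field(vol, fld)
        via_affine = apply_affine(vol, AffineParams(np.eye(3), np.array([0.0, 3.0, 0.0])))
        np.testing.assert_allclose(via_field.data, via_affine.data, atol=1e-6)

    def test_warp_unwarp_approximate_inverse(self):
        shape = (32, 32, 24)
        x, y, z = np.indices(shape).astype(float)
        img = np.exp(-(((x - 16) / 8.0) ** 2 + ((y - 16) / 8.0) ** 2 + ((z - 12) / 6.0) ** 2))
        fixed = Volume(img, (3.0, 3.0, 3.0))
        r = np.sqrt((x - 16) ** 2 + (y - 16) ** 2 + (z - 12) ** 2)
        bump = 4.0 * np.exp(-r ** 2 / 50.0)
        dirs = np.stack([x - 16, y - 16, z - 12], -1)
        nrm = np.linalg.norm(dirs, axis=-1, keepdims=True)
        nrm[nrm == 0] = 1.0
        u_true = bump[..., None] * dirs / nrm
        fld = DisplacementField(u_true, fixed.spacing, fixed.affine.copy())
        neg = DisplacementField(-u_true, fixed.spacing, fixed.affine.copy())
        back = apply_field(apply_field(fixed, fld), neg)
        rng_int = fixed.data.max() - fixed.data.min()
        inner = (slice(3, -3),) * 3
        assert np.abs(back.data[inner] - fixed.data[inner]).max() < 0.1 * rng_int

    def test_self_registration_near_zero_field(self):
        vol = smooth_phantom((24, 24, 16))
        fld = nonlinear_register(vol, vol, RegistrationConfig(nl_iterations=30))
        assert np.abs(fld.data).max() < 0.05 * 3.0  # 0.05 voxel

    def test_bump_field_recovery(self):
        fixed, moving, u_true = self._bump_setup()
        cfg = RegistrationConfig(nl_iterations=300, nl_force_fwhm_mm=6.0,
                                 nl_field_fwhm_mm=1.0)
        fld = nonlinear_register(moving, fixed, cfg)
        shape = fixed.data.shape

        def residual(u_arr):
            coords = (np.stack(np.indices(shape).astype(float), -1)
                      + u_arr / np.array(fixed.spacing))
            ut = np.stack([ndimage.map_coordinates(u_true[..., i],
                                                   coords.reshape(-1, 3).T,
                                                   order=1, mode="nearest").reshape(shape)
                           for i in range(3)], -1)
            return np.linalg.norm(u_arr + ut, axis=-1)

        region = np.linalg.norm(u_true, axis=-1) > 0.5
        before = residual(np.zeros_like(fld.data))[region].mean()
        after = residual(fld.data)[region].mean()
        assert 1.0 - after / before >= 0.60

    def test_cc_contract(self):
        fixed, moving, _ = self._bump_setup()
        fld = nonlinear_register(moving, fixed, RegistrationConfig(nl_iterations=60))
        cc0 = correlation_coefficient(moving, fixed)
        cc1 = correlation_coefficient(apply_field(moving, fld), fixed)
        assert cc1 >= cc0

    def test_grid_mismatch_rejected(self):
        vol = smooth_phantom((16, 16, 12))
        fld = DisplacementField(np.zeros((8, 8, 8, 3)), vol.spacing, vol.affine.copy())
        with pytest.raises(ValueError, match="grids"):
            apply_field(vol, fld)
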