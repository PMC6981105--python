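import numpy as np
import pytest

from cermorph.registration import (
    AffineTransform,
    RegistrationError,
    affine_register,
    apply_deformation,
    dct_basis,
    default_mask,
    invert_deformation,
    load_field,
    membrane_matrix,
    nonrigid_register,
    save_field,
    threshold_probability,
    warp_scan,
    _synthesize,
)


class TestThresholdProbability:
    def test_strict_inequality_at_threshold(self):
        assert not threshold_probability(np.full((4, 4, 4), 0.5)).any()

    def test_indicator_map_recovers_support(self, rng):
        ind = (rng.random((6, 6, 6)) > 0.7).astype(float)
        np.testing.assert_array_equal(threshold_probability(ind), ind.astype(bool))

    def test_cardinality_matches_bruteforce_count(self, rng):
        pmap = rng.random((8, 8, 8))
        mask = threshold_probability(pmap, 0.4)
        brute = sum(
            1
            for i in range(8)
            for j in range(8)
            for k in range(8)
            if pmap[i, j, k] > 0.4
        )
        assert mask.sum() == brute

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_probability(np.full((2, 2, 2), 1.5))


class TestAffineTransform:
    def test_params_matrix_round_trip(self, rng):
        m = np.eye(4)
        m[:3, :3] += rng.normal(0, 0.05, (3, 3))
        m[:3, 3] = rng.normal(0, 2, 3)
        t = AffineTransform(m)
        t2 = AffineTransform.from_params(t.params)
        np.testing.assert_allclose(t2.matrix, t.matrix, atol=1e-12)

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        m[0, 1] = 0.0
        m[0, 2] = 0.0
        with pytest.raises(ValueError):
            AffineTransform(m)

    def test_json_round_trip(self, tmp_path):
        t = AffineTransform.from_params(np.r_[1.0, -2.0, 0.5, np.eye(3).ravel()])
        p = t.to_json(tmp_path / "a.json")
        np.testing.assert_allclose(AffineTransform.from_json(p).matrix, t.matrix)


def _shift_transform(shift):
    m = np.eye(4)
    m[:3, 3] = shift
    return AffineTransform(m)


def _scale_transform(s, shape):
    c = (np.asarray(shape, dtype=float) - 1) / 2
    m = np.eye(4)
    m[:3, :3] = np.eye(3) * s
    m[:3, 3] = c - s * c
    return AffineTransform(m)


class TestAffineRegister:
    def test_self_registration_is_identity(self, reg_atlas):
        tpl = reg_atlas.template
        t = affine_register(tpl, tpl)
        assert np.abs(_net_translation(t, tpl.shape)).max() < 1e-3
        np.testing.assert_allclose(t.matrix[:3, :3], np.eye(3), atol=1e-3)

    def test_translation_recovered_within_half_voxel(self, reg_atlas):
        tpl = reg_atlas.template
        shift = np.array([3.0, -2.0, 1.0])
        moving = apply_deformation(
            tpl, np.broadcast_to(shift, tpl.shape + (3,)).copy()
        )
        # moving(y) = tpl(y + shift): registration must sample moving at
        # x - shift, i.e. recover translation = -shift
        t = affine_register(moving, tpl)
        np.testing.assert_allclose(t.translation, -shift, atol=0.5)

    def test_isotropic_scale_recovered_within_two_percent(self, reg_atlas):
        tpl = reg_atlas.template
        s = 1.1
        moving = _resample_affine(tpl, _scale_transform(s, tpl.shape))
        t = affine_register(moving, tpl)
        recovered = np.diag(t.matrix)[:3]
        np.testing.assert_allclose(recovered, 1 / s, rtol=0.02)

    def test_inverse_consistency_on_synthetic_transform(self, reg_atlas):
        tpl = reg_atlas.template
        fwd = _shift_transform([2.0, -1.0, 1.5])
        moving = _resample_affine(tpl, fwd)
        ab = affine_register(moving, tpl)
        ba = affine_register(tpl, moving)
        comp = ab.matrix @ ba.matrix
        assert np.abs(comp[:3, 3]).max() < 1.0

    def test_empty_mask_raises(self, reg_atlas):
        with pytest.raises(RegistrationError):
            affine_register(
                reg_atlas.template,
                reg_atlas.template,
                mask=np.zeros(reg_atlas.shape, dtype=bool),
            )


def _resample_affine(vol, transform):
    from cermorph.registration import apply_affine

    return apply_affine(vol, transform)


def _net_translation(t, shape):
    c = (np.asarray(shape, dtype=float) - 1) / 2
    return t.matrix[:3, :3] @ c + t.matrix[:3, 3] - c



class TestNonrigidRegister:
    def test_self_registration_gives_near_zero_field(self, reg_atlas):
        tpl = reg_atlas.template
        _, disp = nonrigid_register(tpl, tpl)
        assert np.abs(disp).max() < 0.1

    def test_huge_regularization_pins_field_to_zero(self, reg_atlas, rng):
        tpl = reg_atlas.template
        moving = tpl + rng.normal(0, 3, tpl.shape) * (tpl > 0)
        _, disp = nonrigid_register(moving, tpl, lam=1e9)
        assert np.abs(disp).max() < 1e-3

    def test_known_dct_field_recovered(self, reg_atlas, rng):
        tpl = reg_atlas.template
        K = 4
        bases = [dct_basis(n, K)[0] for n in tpl.shape]
        coeffs = rng.standard_normal((3, K, K, K)) / (
            1 + np.add.outer(np.add.outer(np.arange(K), np.arange(K)), np.arange(K))
        )
        d_true = _synthesize(coeffs, *bases)
        d_true *= 1.5 / np.abs(d_true).max()
        moving = apply_deformation(tpl, invert_deformation(d_true))
        _, disp = nonrigid_register(moving, tpl, max_iter=20)
        mask = default_mask(tpl, dilate=0)
        rms = np.sqrt(((disp - d_true)[mask] ** 2).sum(axis=-1).mean())
        assert rms < 0.5

    def test_cost_monotone_nonincreasing(self, reg_atlas, rng):
        tpl = reg_atlas.template
        moving = np.roll(tpl, 1, axis=0)
        deform, _ = nonrigid_register(moving, tpl)
        assert all(b <= a for a, b in zip(deform.costs, deform.costs[1:]))

    def test_order_one_with_huge_lambda_is_near_identity(self, reg_atlas, rng):
        tpl = reg_atlas.template
        moving = np.roll(tpl, 2, axis=1)
        _, disp = nonrigid_register(moving, tpl, K=1, lam=1e10)
        assert np.abs(disp).max() < 0.05


class TestMembraneMatrix:
    def test_energy_matches_direct_sum(self, rng):
        shape, K = (10, 9, 8), 3
        R = membrane_matrix(shape, K)
        c = rng.standard_normal((3, K, K, K))
        bases = [dct_basis(n, K) for n in shape]
        d = _synthesize(c, *[b for b, _ in bases])
        # direct: sum over voxels of squared analytic first derivatives
        direct = 0.0
        for a in range(3):
            for ax in range(3):
                Bs = [bases[i][1] if i == ax else bases[i][0] for i in range(3)]
                dd = _synthesize(c, *Bs)
                direct += (dd[..., a] ** 2).sum()
        quad = sum(c[a].ravel() @ R @ c[a].ravel() for a in range(3))
        assert quad == pytest.approx(direct, rel=1e-9)


class TestApplyDeformation:
    def test_zero_field_is_identity(self, reg_atlas):
        tpl = reg_atlas.template
        out = apply_deformation(tpl, np.zeros(tpl.shape + (3,)))
        np.testing.assert_allclose(out, tpl, atol=1e-12)

    def test_integer_shift_matches_index_shift(self, reg_atlas):
        tpl = reg_atlas.template
        disp = np.zeros(tpl.shape + (3,))
        disp[..., 0] = 2.0
        out = apply_deformation(tpl, disp)
        np.testing.assert_allclose(out[:-2], tpl[2:], atol=1e-12)

    def test_grid_mismatch_rejected(self, reg_atlas):
        with pytest.raises(ValueError):
            apply_deformation(reg_atlas.template, np.zeros((4, 4, 4, 3)))

    def test_forward_then_inverse_round_trip(self, reg_atlas, rng):
        tpl = reg_atlas.template
        K = 3
        bases = [dct_basis(n, K)[0] for n in tpl.shape]
        d = _synthesize(rng.standard_normal((3, K, K, K)), *bases)
        d *= 1.2 / np.abs(d).max()
        warped = apply_deformation(tpl, d)
        back = apply_deformation(warped, invert_deformation(d))
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(default_mask(tpl, dilate=0), iterations=2)
        rms = np.sqrt(((back - tpl)[interior] ** 2).mean())
        assert rms < 0.02 * (tpl.max() - tpl.min())

    def test_warp_scan_single_interpolation_matches_two_step(self, reg_atlas):
        tpl = reg_atlas.template
        t = _shift_transform([1.0, 0.0, -1.0])
        disp = np.zeros(tpl.shape + (3,))
        disp[..., 2] = 0.5
        one_step = warp_scan(tpl, t, disp)
        manual = apply_deformation(_resample_affine(tpl, t), disp)
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(default_mask(tpl, dilate=0), iterations=3)
        np.testing.assert_allclose(
            one_step[interior], manual[interior], atol=2.0
        )


class TestInvertDeformation:
    def test_zero_field_inverts_to_zero(self):
        disp = np.zeros((8, 8, 8, 3))
        np.testing.assert_array_equal(invert_deformation(disp), disp)

    def test_constant_field_inverts_to_negation(self):
        disp = np.zeros((12, 12, 12, 3))
        disp[...] = [1.5, -0.5, 1.0]
        inv = invert_deformation(disp)
        np.testing.assert_allclose(inv, -disp, atol=0.01)

    def test_smooth_field_composition_residual_small(self, rng):
        shape = (16, 16, 16)
        K = 3
        bases = [dct_basis(n, K)[0] for n in shape]
        d = _synthesize(rng.standard_normal((3, K, K, K)), *bases)
        d *= 1.0 / np.abs(d).max()
        inv = invert_deformation(d)
        from cermorph.registration import _grid_points, _sample

        grid = _grid_points(shape)
        pts = (grid + inv).reshape(-1, 3)
        d_at = np.stack(
            [_sample(d[..., a], pts, mode="nearest") for a in range(3)], axis=-1
        ).reshape(d.shape)
        resid = np.abs(inv + d_at)[2:-2, 2:-2, 2:-2]
        assert resid.max() < 0.05

    def test_oversized_field_rejected(self):
        disp = np.zeros((8, 8, 8, 3))
        disp[..., 0] = 5.0
        with pytest.raises(RegistrationError):
            invert_deformation(disp)


class TestFieldPersistence:
    def test_round_trip(self, tmp_path, rng):
        disp = rng.normal(0, 1, (6, 5, 4, 3))
        p = save_field(disp, np.eye(4), tmp_path / "d.nii.gz")
        np.testing.assert_allclose(load_field(p), disp, atol=1e-6)

    def test_non_field_rejected(self, tmp_path):
        import nibabel as nib

        p = tmp_path / "x.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4)), np.eye(4)), p)
        with pytest.raises(ValueError):
            load_field(p)
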