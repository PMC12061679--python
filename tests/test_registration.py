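import numpy as np
import pytest

import ventiqct as vq
from ventiqct.images import DisplacementField, ImageVolume


def _field_from_fn(shape, spacing, fn):
    grid = ImageVolume(np.zeros(shape), spacing)
    xs, ys, zs = grid.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)
    return DisplacementField(fn(pts), spacing)


class TestDeformationMetrics:
    def test_zero_field(self):
        f = DisplacementField(np.zeros((10, 10, 10, 3)), (1, 1, 1))
        m = vq.deformation_metrics(f)
        assert np.allclose(m.jacobian, 1.0)
        assert np.allclose(m.adi, 0.0)

    def test_uniform_isotropic_expansion(self):
        # u = (s - 1) x with s = 1.2: J = s^3 = 1.728, isotropic so ADI = 0
        f = _field_from_fn((12, 12, 12), (2, 2, 2), lambda p: 0.2 * p)
        m = vq.deformation_metrics(f)
        assert np.allclose(m.jacobian, 1.728, atol=1e-6)
        assert np.allclose(m.adi, 0.0, atol=1e-9)

    def test_uniaxial_stretch(self):
        # stretches (2, 1, 1): ADI = sqrt(((2-1)/1)^2 + 0) = 1
        def fn(p):
            u = np.zeros_like(p)
            u[..., 0] = p[..., 0]
            return u

        m = vq.deformation_metrics(_field_from_fn((10, 10, 10), (1.5, 1.5, 1.5), fn))
        assert np.allclose(m.jacobian, 2.0, atol=1e-9)
        assert np.allclose(m.adi, 1.0, atol=1e-9)

    def test_composition_multiplies_jacobians_in_small_deformation_limit(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        shape, sp = (24, 24, 24), (1.0, 1.0, 1.0)

        def smooth(seed, amp):
            g = np.stack(
                [ndimage.gaussian_filter(np.random.default_rng(seed + a).normal(size=shape), 4)
                 for a in range(3)], axis=-1)
            return amp * g / np.abs(g).max()

        u1, u2 = smooth(1, 0.8), smooth(7, 0.8)  # |u| <= 1 voxel
        f1 = DisplacementField(u1, sp)
        grid = ImageVolume(np.zeros(shape), sp)
        xs, ys, zs = grid.world_coordinates()
        pts = np.stack([xs, ys, zs], axis=-1) + u1
        u2_at = np.stack(
            [ndimage.map_coordinates(u2[..., a], np.moveaxis(pts, -1, 0), order=1, mode="nearest")
             for a in range(3)], axis=-1)
        comp = DisplacementField(u1 + u2_at, sp)
        J1 = vq.deformation_metrics(f1).jacobian
        J2_at = ndimage.map_coordinates(
            vq.deformation_metrics(DisplacementField(u2, sp)).jacobian,
            np.moveaxis(pts, -1, 0), order=1, mode="nearest")
        Jc = vq.deformation_metrics(comp).jacobian
        inner = (slice(3, -3),) * 3
        assert np.allclose(Jc[inner], (J1 * J2_at)[inner], rtol=0.05)

    def test_nonfinite_field_rejected(self):
        with pytest.raises(ValueError):
            DisplacementField(np.full((5, 5, 5, 3), np.inf), (1, 1, 1))


class TestApplyDisplacement:
    def test_zero_field_is_identity(self):
        img = ImageVolume(np.random.default_rng(0).normal(size=(12, 12, 12)), (1, 1, 1))
        out = vq.apply_displacement(img, DisplacementField(np.zeros((12, 12, 12, 3)), (1, 1, 1)))
        assert np.allclose(out.data, img.data, atol=1e-12)

    def test_constant_shift_moves_spike(self):
        img = ImageVolume(np.zeros((16, 16, 16)), (1, 1, 1))
        img.data[10, 8, 8] = 1.0
        shift = np.zeros((16, 16, 16, 3))
        shift[..., 0] = 2.0  # pull-back: out(x) = img(x + 2) => spike moves to x=8
        out = vq.apply_displacement(img, DisplacementField(shift, (1, 1, 1)))
        assert out.data[8, 8, 8] == pytest.approx(1.0)
        assert out.data[10, 8, 8] == pytest.approx(0.0)

    def test_counts_approximately_conserved_for_small_smooth_fields(self):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        data = np.zeros((24, 24, 24))
        data[6:18, 6:18, 6:18] = rng.uniform(0.5, 1.5, (12, 12, 12))
        data = ndimage.gaussian_filter(data, 2)
        img = ImageVolume(data, (1, 1, 1))
        u = np.stack(
            [ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 5) for _ in range(3)],
            axis=-1)
        u *= 1.0 / np.abs(u).max()
        out = vq.apply_displacement(img, DisplacementField(u, (1, 1, 1)))
        assert out.data.sum() == pytest.approx(img.data.sum(), rel=0.02)

    def test_unknown_interpolation_rejected(self):
        img = ImageVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError):
            vq.apply_displacement(img, DisplacementField(np.zeros((8, 8, 8, 3)), (1, 1, 1)),
                                  interpolation="cubic")


class TestAffineMI:
    def test_recovers_rigid_spect_offset_within_one_voxel(self, default_phantom, default_spect):
        spec, insp, exp, lobes, truth = default_phantom
        spect, _ = default_spect
        aff = vq.affine_register_mi(spect, exp, truth.exp_lobes)
        cen = np.argwhere(truth.exp_lobes.lung_mask).mean(axis=0) * np.asarray(exp.spacing)
        est_offset = aff.apply(cen) - cen
        err = np.linalg.norm(est_offset - truth.spect_offset_mm)
        assert err < np.mean(spec.spect_spacing_mm)  # one SPECT voxel

    def test_identity_case(self, default_phantom):
        spec, insp, exp, lobes, truth = default_phantom
        aff = vq.affine_register_mi(exp, exp, truth.exp_lobes)
        cen = np.argwhere(truth.exp_lobes.lung_mask).mean(axis=0) * np.asarray(exp.spacing)
        # within 0.1 voxel of identity at the lung centroid
        assert np.linalg.norm(aff.apply(cen) - cen) < 0.1 * np.mean(exp.spacing)

    def test_constant_moving_image_rejected(self, default_phantom):
        spec, insp, exp, lobes, truth = default_phantom
        flat = exp.with_data(np.zeros_like(exp.data))
        with pytest.raises(ValueError, match="degenerate histogram"):
            vq.affine_register_mi(flat, exp, truth.exp_lobes)

    def test_empty_mask_rejected(self, default_phantom, default_spect):
        spec, insp, exp, lobes, truth = default_phantom
        spect, _ = default_spect
        from ventiqct.images import LabelMap

        empty = LabelMap(np.zeros(exp.shape, dtype=int), exp.spacing)
        with pytest.raises(ValueError, match="empty mask"):
            vq.affine_register_mi(spect, exp, empty)

    def test_invariant_to_intensity_rescaling(self, default_phantom, default_spect):
        """Mutual information only sees the joint histogram, so scaling the
        moving intensities by 10 must not move the transform."""
        spec, insp, exp, lobes, truth = default_phantom
        spect, _ = default_spect
        a1 = vq.affine_register_mi(spect, exp, truth.exp_lobes)
        a2 = vq.affine_register_mi(spect.with_data(spect.data * 10.0), exp, truth.exp_lobes)
        cen = np.argwhere(truth.exp_lobes.lung_mask).mean(axis=0) * np.asarray(exp.spacing)
        assert np.linalg.norm(a1.apply(cen) - a2.apply(cen)) < 0.1


class TestDeformableSSTVD:
    def test_recovers_known_deformation(self, default_phantom, registered_field):
        spec, insp, exp, lobes, truth = default_phantom
        err = np.linalg.norm(
            registered_field.vectors - truth.true_displacement.vectors, axis=-1
        )
        assert err[lobes.lung_mask].mean() < 2.0

    def test_identity_pair_gives_near_zero_field(self, default_phantom):
        spec, insp, exp, lobes, truth = default_phantom
        f = vq.deformable_register_sstvd(insp, insp, lobes)
        assert f.magnitude()[lobes.lung_mask].mean() < 0.5

    def test_tissue_volume_conserved(self, default_phantom, registered_field):
        """The SSTVD objective drives the Jacobian-weighted warped tissue
        volume to match inspiration, evaluated away from the pleural
        partial-volume shell."""
        from scipy import ndimage

        spec, insp, exp, lobes, truth = default_phantom
        exp_w = vq.apply_displacement(exp, registered_field, fill_value=-1000.0)
        J = vq.deformation_metrics(registered_field).jacobian
        core = ndimage.binary_erosion(lobes.lung_mask, iterations=2)
        beta_i = np.clip((insp.data + 1000) / 1000, 0, 1)
        beta_w = np.clip((exp_w.data + 1000) / 1000, 0, 1)
        ratio = (beta_w * J)[core].sum() / beta_i[core].sum()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_error_shrinks_with_deformation_magnitude(self):
        errs = {}
        for mag in (6.0, 2.0):
            spec = vq.PhantomSpec(deformation_magnitude=mag, seed=13,
                                  grid_shape=(64, 64, 56))
            insp, exp, lobes, truth = vq.make_ct_pair(spec)
            f = vq.deformable_register_sstvd(exp, insp, lobes)
            errs[mag] = np.linalg.norm(
                f.vectors - truth.true_displacement.vectors, axis=-1
            )[lobes.lung_mask].mean()
        assert errs[2.0] < errs[6.0]

    def test_non_overlapping_volumes_rejected(self, default_phantom):
        spec, insp, exp, lobes, truth = default_phantom
        import dataclasses

        far = dataclasses.replace(exp, origin=(1e5, 1e5, 1e5))
        with pytest.raises(ValueError, match="overlap"):
            vq.deformable_register_sstvd(far, insp, lobes)
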