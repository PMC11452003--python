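"""Rigid ICP and nodal-grid deformable registration."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.transform import Rotation

from shapepost.metrics import dsc
from shapepost.registration import (DisplacementField, RigidTransform,
                                    apply_displacement, apply_rigid,
                                    auto_lambda, deformable_register,
                                    icp_rigid, jacobian_determinant)
from shapepost.volumes import BinaryMask, GeometryError, PointCloud, surface_voxels
from .conftest import ball_mask


def _rotate_cloud(points, angle_deg, axis, translation):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    r = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    c = points.mean(axis=0)
    return (points - c) @ r.T + c + np.asarray(translation), r


class TestICP:
    def test_identity_for_identical_clouds(self, bent_tube):
        cloud = surface_voxels(bent_tube)
        t = icp_rigid(cloud, cloud)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-6)

    def test_known_transform_recovered(self, bent_tube):
        fixed = surface_voxels(bent_tube)
        moved, r = _rotate_cloud(fixed.points, 10.0, (0, 0, 1), (4.0, 2.0, 0))
        t = icp_rigid(PointCloud(moved), fixed)
        residual = t.rotation @ r
        angle = np.degrees(np.arccos(np.clip((np.trace(residual) - 1) / 2,
                                             -1, 1)))
        assert angle < 0.1
        assert np.linalg.norm(t.apply(moved) - fixed.points, axis=1).max() < 0.1

    def test_jittered_cloud_rms_decreases(self, bent_tube, rng):
        fixed = surface_voxels(bent_tube)
        moved, _ = _rotate_cloud(fixed.points, 8.0, (1, 1, 0), (3.0, 0, 1.0))
        moved = moved + rng.uniform(-0.5, 0.5, moved.shape)
        from scipy.spatial import cKDTree
        tree = cKDTree(fixed.points)
        rms0 = np.sqrt(np.mean(tree.query(moved)[0] ** 2))
        t = icp_rigid(PointCloud(moved), fixed)
        rms1 = np.sqrt(np.mean(tree.query(t.apply(moved))[0] ** 2))
        assert rms1 < rms0

    def test_collinear_cloud_rejected(self):
        line = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        with pytest.raises(GeometryError):
            icp_rigid(PointCloud(line), PointCloud(line))


class TestApplyRigid:
    def test_identity_preserves_mask(self, bent_tube):
        out = apply_rigid(bent_tube, RigidTransform())
        np.testing.assert_array_equal(out.grid, bent_tube.grid)

    def test_integer_translation_exact(self, sphere8):
        t = RigidTransform(translation=(3.0, 0.0, -2.0))
        out = apply_rigid(sphere8, t)
        expected = np.roll(np.roll(sphere8.grid, 3, axis=0), -2, axis=2)
        np.testing.assert_array_equal(out.grid, expected)

    def test_rotation_roughly_volume_preserving(self, bent_tube):
        r = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        c = np.argwhere(bent_tube.grid).mean(axis=0)
        t = RigidTransform(rotation=r, translation=c - r @ c)
        out = apply_rigid(bent_tube, t)
        assert out.grid.sum() == pytest.approx(bent_tube.grid.sum(), rel=0.05)


class TestDeformable:
    def test_identical_masks_zero_field(self, bent_tube):
        res = deformable_register(bent_tube, bent_tube, ns=5.0, lam=1.0)
        assert np.abs(res.field.dense_index_displacement()).max() <= 0.1

    def test_three_voxel_shift_recovered(self, bent_tube):
        moving = BinaryMask(np.roll(bent_tube.grid, 3, axis=0),
                            bent_tube.spacing)
        assert dsc(bent_tube, moving) <= 0.80
        res = deformable_register(bent_tube, moving, ns=5.0, lam=0.1)
        warped = apply_displacement(moving, res.field)
        assert dsc(bent_tube, warped) >= 0.95

    def test_cost_trace_non_increasing(self, bent_tube):
        moving = BinaryMask(np.roll(bent_tube.grid, 2, axis=1),
                            bent_tube.spacing)
        res = deformable_register(bent_tube, moving, ns=5.0, lam=1.0)
        trace = np.asarray(res.cost_trace)
        assert (np.diff(trace) <= 0).all()
        assert res.final_cost <= trace[0]

    def test_smooth_synthetic_field_recovered(self, bent_tube):
        gs = bent_tube.shape
        base = np.stack(np.meshgrid(*[np.arange(s) for s in gs],
                                    indexing="ij")).astype(float)
        u_true = np.zeros((3,) + gs)
        u_true[0] = 2.0 * np.sin(2 * np.pi * base[2] / gs[2])
        smooth = ndimage.gaussian_filter(bent_tube.grid.astype(float), 1.0)
        warped = ndimage.map_coordinates(smooth, base + u_true, order=1)
        moving = BinaryMask(warped > 0.5, bent_tube.spacing)
        res = deformable_register(bent_tube, moving, ns=5.0, lam=1.0)
        u_est = res.field.dense_index_displacement()
        err = np.linalg.norm(u_est + u_true, axis=0)[bent_tube.grid]
        assert err.mean() <= 1.0

    def test_registration_improves_dice(self, bent_tube, rng):
        # composition consistency on a randomly perturbed pair
        noisy = bent_tube.grid.copy()
        noisy ^= (rng.random(noisy.shape) < 0.01) & \
            ndimage.binary_dilation(noisy, iterations=2)
        moving = BinaryMask(np.roll(noisy, 2, axis=0), bent_tube.spacing)
        before = dsc(bent_tube, moving)
        res = deformable_register(bent_tube, moving, ns=5.0, lam=1.0)
        after = dsc(bent_tube, apply_displacement(moving, res.field))
        assert after >= before


class TestAutoLambda:
    def test_identical_masks_smallest_candidate(self, sphere8):
        lam = auto_lambda(sphere8, sphere8, ns=5.0, lam_grid=(0.5, 5.0, 50.0))
        assert lam == 0.5

    def test_selected_lambda_fold_free(self, bent_tube):
        moving = BinaryMask(np.roll(bent_tube.grid, 3, axis=0),
                            bent_tube.spacing)
        res = deformable_register(bent_tube, moving, ns=5.0, lam="auto",
                                  lam_grid=(0.01, 0.1, 1.0, 10.0, 100.0))
        assert res.min_jacobian > 0

    def test_larger_lambda_smaller_displacement(self, bent_tube):
        moving = BinaryMask(np.roll(bent_tube.grid, 3, axis=0),
                            bent_tube.spacing)
        mags = []
        for lam in (0.1, 10.0):
            res = deformable_register(bent_tube, moving, ns=5.0, lam=lam,
                                      max_iter=10)
            mags.append(np.abs(res.field.node_disp).mean())
        assert mags[1] < mags[0]


class TestApplyDisplacement:
    def _zero_field(self, mask, ns=5.0):
        from shapepost.registration import _NodeGrid
        geom = _NodeGrid(mask.shape, ns)
        return DisplacementField(ns=ns, node_origin=geom.node_origin,
                                 node_disp=np.zeros((3,) + geom.node_shape),
                                 spacing=mask.spacing, grid_shape=mask.shape)

    def test_zero_field_identity(self, bent_tube):
        out = apply_displacement(bent_tube, self._zero_field(bent_tube))
        np.testing.assert_array_equal(out.grid, bent_tube.grid)

    def test_uniform_integer_field_exact_shift(self, sphere8):
        fld = self._zero_field(sphere8)
        fld.node_disp[0] = -2.0       # backward map: sample at x-(-2)=x+2
        out = apply_displacement(sphere8, fld)
        np.testing.assert_array_equal(out.grid, np.roll(sphere8.grid, 2,
                                                        axis=0))

    def test_volume_change_bounded_by_jacobian(self, sphere8, rng):
        fld = self._zero_field(sphere8)
        fld.node_disp[:] = rng.normal(scale=1.0,
                                      size=fld.node_disp.shape)
        det = jacobian_determinant(fld.dense_index_displacement())
        out = apply_displacement(sphere8, fld)
        ratio = out.grid.sum() / sphere8.grid.sum()
        assert det.min() - 0.35 <= ratio <= det.max() + 0.35
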