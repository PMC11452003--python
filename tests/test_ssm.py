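"""Shape-model construction: alignment, particles, PCA, mean mask."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from shapepost.ssm import (EnsembleError, build_shape_model,
                           initialize_particles, optimize_correspondences,
                           procrustes_align, reconstruct_mean_mask)
from shapepost.volumes import BinaryMask, signed_distance
from .conftest import ball_mask


class TestProcrustes:
    def test_identical_masks_identity_transforms(self, sphere8):
        aligned = procrustes_align([sphere8, sphere8, sphere8])
        for t, _ in aligned:
            np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)
            np.testing.assert_allclose(t.translation, 0.0, atol=1e-6)

    def test_translation_recovered(self, bent_tube):
        moved = BinaryMask(np.roll(bent_tube.grid, 5, axis=0),
                           bent_tube.spacing)
        aligned = procrustes_align([bent_tube, moved])
        t0, t1 = aligned[0][0], aligned[1][0]
        # relative transform between the two must undo the +5 voxel shift
        rel = t1.translation - t0.translation
        np.testing.assert_allclose(rel, (-5.0, 0.0, 0.0), atol=0.5)

    def test_rotation_about_long_axis_recovered(self):
        # needs distinct principal moments: an anisotropic ellipsoid (a
        # circular tube's cross-section moments are degenerate, leaving
        # rotation about its axis unidentifiable by construction)
        from shapepost.registration import RigidTransform, apply_rigid
        shape = (56, 40, 64)
        coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        c0 = [(s - 1) / 2 for s in shape]
        ellipsoid = BinaryMask(
            sum(((c - cc) / a) ** 2
                for c, cc, a in zip(coords, c0, (14, 8, 22))) <= 1.0)
        theta = np.radians(15)
        r = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        c = np.argwhere(ellipsoid.grid).mean(axis=0)
        t = RigidTransform(rotation=r, translation=c - r @ c)
        rotated = apply_rigid(ellipsoid, t)
        aligned = procrustes_align([ellipsoid, rotated])
        # both land in one frame: R1 r must equal R0, i.e. R0^T R1 r = I
        rel = aligned[0][0].rotation.T @ aligned[1][0].rotation @ r
        angle = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        assert angle < 1.0

    def test_single_shape_rejected(self, sphere8):
        with pytest.raises(EnsembleError):
            procrustes_align([sphere8])


class TestInitializeParticles:
    def test_particles_on_surface_and_deterministic(self, sphere8):
        sdf = signed_distance(sphere8)
        pts = initialize_particles(sdf, m_target=16, seed=0)
        assert pts.shape == (16, 3)
        from shapepost.ssm import _SurfaceInterp
        assert np.abs(_SurfaceInterp(sdf).value(pts)).max() <= 0.5
        np.testing.assert_array_equal(
            pts, initialize_particles(sdf, m_target=16, seed=0))

    def test_sphere_centroid_near_center(self, sphere8):
        sdf = signed_distance(sphere8)
        pts = initialize_particles(sdf, m_target=64, seed=1)
        center = (np.asarray(sphere8.shape) - 1) / 2.0
        assert np.linalg.norm(pts.mean(axis=0) - center) < 1.0

    @pytest.mark.parametrize("bad_m", [15, 48])
    def test_non_power_of_two_rejected(self, sphere8, bad_m):
        with pytest.raises(ValueError):
            initialize_particles(signed_distance(sphere8), m_target=bad_m)


class TestOptimizeCorrespondences:
    def test_identical_shapes_zero_shape_variance(self, sphere8):
        ps, trace = optimize_correspondences([sphere8] * 4, m=32,
                                             iterations=20, seed=0)
        x = ps.as_vectors()
        cov_trace = np.sum((x - x.mean(axis=0)) ** 2) / 3
        assert cov_trace <= 1e-6
        h = trace[-1].sampling
        assert max(h) - min(h) < 1e-3

    def test_single_shape_uniform_spread(self, sphere8):
        ps, _ = optimize_correspondences([sphere8], m=64, iterations=50,
                                         seed=0)
        pts = ps.positions[0]
        nn = cKDTree(pts).query(pts, k=2)[0][:, 1]
        assert nn.std() / nn.mean() < 0.5

    def test_energy_decreases_monotonically(self, radius_family_model):
        _, trace, _ = radius_family_model
        qs = [e.q for e in trace]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_energy_identity_holds(self, radius_family_model):
        _, trace, _ = radius_family_model
        for e in trace:
            assert abs(e.q - (e.ensemble - sum(e.sampling))) < 1e-10

    def test_particles_stay_on_surface(self, radius_family_model):
        ps, _, _ = radius_family_model
        from shapepost.ssm import _SurfaceInterp
        for k in range(ps.n_shapes):
            v = _SurfaceInterp(ps.sdfs[k]).value(ps.positions[k])
            assert np.abs(v).max() <= 0.5


class TestShapeModel:
    def test_rank_bound_n_minus_one(self, sphere8):
        masks = [sphere8, ball_mask(9.0), ball_mask(10.0)]
        ps, _ = optimize_correspondences(masks, m=32, iterations=30, seed=0)
        model = build_shape_model(ps)
        assert (model.eigenvalues > 1e-8 * model.eigenvalues.sum()).sum() <= 2

    def test_modes_orthonormal(self, radius_family_model):
        _, _, model = radius_family_model
        gram = model.modes @ model.modes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_eigenvalues_non_increasing(self, radius_family_model):
        _, _, model = radius_family_model
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_one_parameter_family_mode1_dominates(self, radius_family_model):
        ps, _, model = radius_family_model
        assert model.explained_variance_ratio()[0] >= 0.90

    def test_mode1_scores_track_generative_parameter(
            self, radius_family, radius_family_model):
        _, params = radius_family
        ps, _, model = radius_family_model
        corr = np.corrcoef(model.scores(ps)[:, 0], params)[0, 1]
        assert abs(corr) >= 0.95

    def test_permutation_invariance(self, radius_family):
        masks, _ = radius_family
        ps_a, _ = optimize_correspondences(masks[:5], m=32, iterations=30,
                                           seed=0)
        perm = [masks[i] for i in (3, 1, 4, 0, 2)]
        ps_b, _ = optimize_correspondences(perm, m=32, iterations=30, seed=0)
        ma = build_shape_model(ps_a)
        mb = build_shape_model(ps_b)
        np.testing.assert_allclose(ma.mean, mb.mean, atol=1e-6)
        np.testing.assert_allclose(ma.eigenvalues, mb.eigenvalues,
                                   rtol=1e-6, atol=1e-9)

    def test_identical_shapes_flat_spectrum(self, sphere8):
        ps, _ = optimize_correspondences([sphere8] * 3, m=32, iterations=10,
                                         seed=0)
        model = build_shape_model(ps)
        assert model.eigenvalues.max() <= 1e-8 * max(
            np.sum(ps.as_vectors() ** 2), 1.0)

    def test_two_shapes_required(self, sphere8):
        ps, _ = optimize_correspondences([sphere8], m=32, iterations=5, seed=0)
        with pytest.raises(EnsembleError):
            build_shape_model(ps)


class TestMeanMask:
    def test_identical_inputs_reproduce_shape(self, sphere8):
        from shapepost.metrics import dsc
        ps, _ = optimize_correspondences([sphere8] * 3, m=32, iterations=10,
                                         seed=0)
        model = build_shape_model(ps)
        mean = reconstruct_mean_mask(model, ps, [sphere8] * 3)
        assert dsc(mean, sphere8) >= 0.99

    def test_concentric_balls_mean_radius(self):
        masks = [ball_mask(8.0), ball_mask(12.0)]
        ps, _ = optimize_correspondences(masks, m=64, iterations=60, seed=0)
        model = build_shape_model(ps)
        mean = reconstruct_mean_mask(model, ps, masks)
        r_eq = (3 * mean.grid.sum() / (4 * np.pi)) ** (1 / 3)
        assert r_eq == pytest.approx(10.0, abs=1.0)

    def test_mean_volume_within_ensemble_range(self, radius_family,
                                               radius_family_model):
        masks, _ = radius_family
        ps, _, model = radius_family_model
        mean = reconstruct_mean_mask(model, ps, masks)
        vols = [m.grid.sum() for m in masks]
        assert min(vols) <= mean.grid.sum() <= max(vols)

    def test_mean_mask_single_component(self, radius_family,
                                        radius_family_model):
        masks, _ = radius_family
        ps, _, model = radius_family_model
        mean = reconstruct_mean_mask(model, ps, masks)
        struct = ndimage.generate_binary_structure(3, 1)
        assert ndimage.label(mean.grid, structure=struct)[1] == 1
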