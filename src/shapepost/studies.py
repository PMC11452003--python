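"""Seeded evaluation studies of the post-processing pipeline.

Self-contained, deterministic experiments used to characterize the
package's behaviour on phantoms: rigid-registration recovery, deformable
registration accuracy, shape-model parameter recovery, and the paired
mean-shape-vs-raw improvement study.  Problem sizes are desk-scale
(volumes around 48^3-64^3 voxels, 64 particles) so each study runs in
seconds to minutes on one core.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .meanshape import ms_postprocess_label
from .metrics import assd, dsc, hausdorff
from .phantoms import (CorruptionSpec, PhantomSpec, corrupt_prediction,
                       generate_shape_family)
from .registration import PointCloud, apply_displacement, deformable_register, icp_rigid
from .ssm import build_shape_model, optimize_correspondences, reconstruct_mean_mask
from .volumes import BinaryMask, LabelVolume, extract_label_mask, surface_voxels


def _study_tube(seed: int = 7, variability: float = 1.0) -> BinaryMask:
    spec = PhantomSpec(n_subjects=1, volume_shape=(48, 48, 64), base_radius=7,
                       variability=variability, bend_amplitude=2.0, seed=seed)
    return generate_shape_family(spec)[0]


def icp_recovery_study(n_trials: int = 20, seed: int = 1,
                       max_angle: float = 30.0, max_shift: float = 10.0):
    """Recover known rigid perturbations of a phantom surface cloud.

    Returns (rotation errors in degrees, translation errors in mm), one
    entry per trial.
    """
    cloud = surface_voxels(_study_tube(seed=7))
    rng = np.random.default_rng(seed)
    rot_errs, trans_errs = [], []
    c = cloud.points.mean(axis=0)
    for _ in range(n_trials):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_angle)
        r = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        shift = rng.uniform(-max_shift, max_shift, 3)
        moved = (cloud.points - c) @ r.T + c + shift
        t = icp_rigid(PointCloud(moved), cloud)
        composed_r = t.rotation @ r
        rot_errs.append(np.degrees(np.arccos(
            np.clip((np.trace(composed_r) - 1) / 2, -1.0, 1.0))))
        # composing recovered with true perturbation must be the identity
        residual = t.apply((cloud.points - c) @ r.T + c + shift) - cloud.points
        trans_errs.append(float(np.linalg.norm(residual, axis=1).mean()))
    return np.asarray(rot_errs), np.asarray(trans_errs)


def shift_recovery_study(ns: float = 5.0, lam: float = 0.1,
                         shift: int = 3, seed: int = 7):
    """Register a shifted copy of a tube back onto itself.

    Returns (initial DSC, recovered DSC).
    """
    fixed = _study_tube(seed=seed)
    moving = BinaryMask(np.roll(fixed.grid, shift, axis=0), fixed.spacing)
    initial = dsc(fixed, moving)
    res = deformable_register(fixed, moving, ns=ns, lam=lam)
    final = dsc(fixed, apply_displacement(moving, res.field))
    return initial, final


def field_recovery_study(ns: float = 5.0, lam: float = 1.0,
                         amplitude: float = 2.0, seed: int = 7) -> float:
    """Recover a smooth sinusoidal synthetic field; mean in-mask error (voxels)."""
    fixed = _study_tube(seed=seed)
    gs = fixed.shape
    base = np.stack(np.meshgrid(*[np.arange(s) for s in gs],
                                indexing="ij")).astype(float)
    u_true = np.zeros((3,) + gs)
    u_true[0] = amplitude * np.sin(2 * np.pi * base[2] / gs[2])
    smooth = ndimage.gaussian_filter(fixed.grid.astype(float), 1.0)
    warped = ndimage.map_coordinates(smooth, base + u_true, order=1)
    moving = BinaryMask(warped > 0.5, fixed.spacing)
    res = deformable_register(fixed, moving, ns=ns, lam=lam)
    u_est = res.field.dense_index_displacement()
    err = np.linalg.norm(u_est + u_true, axis=0)[fixed.grid]
    return float(err.mean())


def ssm_recovery_study(n_subjects: int = 10, m: int = 64, seed: int = 3):
    """One-parameter family: how much of the variance does mode 1 recover?

    Returns (explained variance ratio of mode 1, |correlation| between
    mode-1 scores and the generative radius parameter).
    """
    spec = PhantomSpec(n_subjects=n_subjects, volume_shape=(48, 48, 64),
                       base_radius=7, variability=2.0, bend_amplitude=0.0,
                       harmonics=(0,), seed=seed)
    masks, params = generate_shape_family(spec, return_params=True)
    ps, _ = optimize_correspondences(masks, m=m, iterations=80, seed=seed)
    model = build_shape_model(ps)
    evr = float(model.explained_variance_ratio()[0])
    corr = float(abs(np.corrcoef(model.scores(ps)[:, 0], params[:, 0])[0, 1]))
    return evr, corr


def two_ball_mean_study(r_small: float = 8.0, r_big: float = 12.0,
                        seed: int = 0) -> float:
    """Equivalent radius of the mean mask of two concentric balls."""
    shape = (40, 40, 40)
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((c - (s - 1) / 2.0) ** 2 for c, s in zip(coords, shape))
    masks = [BinaryMask(d2 <= r_small ** 2), BinaryMask(d2 <= r_big ** 2)]
    ps, _ = optimize_correspondences(masks, m=64, iterations=60, seed=seed)
    model = build_shape_model(ps)
    mean = reconstruct_mean_mask(model, ps, masks)
    return float((3.0 * mean.grid.sum() / (4.0 * np.pi)) ** (1.0 / 3.0))


def ms_improvement_study(n_cases: int = 50, seed: int = 0,
                         n_train: int = 10, m: int = 64,
                         ns: float = 5.0, lam: float = 10.0,
                         corruption: CorruptionSpec | None = None):
    """Paired mean-shape-vs-raw study over seeded corrupted predictions.

    Builds one mean shape from a training family, then for each case
    corrupts a freshly drawn subject and post-processes it.  Returns a
    dict with the fraction of cases improving HD and ASSD and the mean
    DSC change (positive = degradation).
    """
    spec = PhantomSpec(n_subjects=n_train, volume_shape=(48, 48, 64),
                       base_radius=7, variability=1.2, bend_amplitude=1.0,
                       seed=seed + 500)
    train = generate_shape_family(spec)
    ps, _ = optimize_correspondences(train, m=m, iterations=60, seed=seed)
    model = build_shape_model(ps)
    mean_mask = reconstruct_mean_mask(model, ps, train)
    if corruption is None:
        corruption = CorruptionSpec()
    hd_improved = assd_improved = 0
    dsc_deltas = []
    for case in range(n_cases):
        case_seed = seed + 1000 + case
        gt = generate_shape_family(
            replace(spec, n_subjects=1, seed=case_seed))[0]
        gtv = LabelVolume(gt.grid.astype(np.int16))
        pred = corrupt_prediction(gtv, replace(corruption, seed=case_seed))
        pred_mask = extract_label_mask(pred, 1)
        out = ms_postprocess_label(pred_mask, mean_mask, ns=ns, lam=lam,
                                   max_iter=25)
        hd_improved += hausdorff(gt, out) < hausdorff(gt, pred_mask)
        assd_improved += assd(gt, out) < assd(gt, pred_mask)
        dsc_deltas.append(dsc(gt, pred_mask) - dsc(gt, out))
    return {
        "hd_improved_fraction": hd_improved / n_cases,
        "assd_improved_fraction": assd_improved / n_cases,
        "mean_dsc_degradation": float(np.mean(dsc_deltas)),
        "n_cases": n_cases,
    }


def crf_denoising_study(size: int = 32, flip: float = 0.05, seed: int = 1,
                        conf: float = 0.8):
    """Two-region slice with flipped unaries, default CRF weights.

    Returns (input pixel error, CRF output pixel error).
    """
    from .crf import CRFParams, UnaryField, mean_field_infer
    rng = np.random.default_rng(seed)
    gt = np.zeros((size, size), int)
    gt[:, size // 2:] = 1
    img = np.where(gt == 1, 100.0, 40.0) + rng.normal(0, 5, gt.shape)
    noisy = np.where(rng.random(gt.shape) < flip, 1 - gt, gt)
    probs = np.stack([np.where(noisy == 0, conf, 1 - conf),
                      np.where(noisy == 1, conf, 1 - conf)])
    _, labels = mean_field_infer(UnaryField(probs, img), CRFParams())
    return float((noisy != gt).mean()), float((labels != gt).mean())
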