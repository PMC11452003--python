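"""Statistical shape modelling with entropy-based particle correspondences.

An ensemble of N aligned shapes is described by m index-matched particles
constrained to each shape's surface: shape k becomes a vector
``x_k in R^{3m}``.  Correspondence quality is driven by the energy

    Q = H(Z) - sum_k H(x_k)

where ``Z = {x_1..x_N}`` is the shape-space ensemble and H denotes
differential entropy.  Minimizing Q compacts the ensemble distribution
(good correspondence) while spreading particles uniformly on each surface
(good sampling).  H(Z) is estimated under a Gaussian model,
``H ∝ 0.5 * sum log(eigenvalue + alpha)``, with a small regularizer alpha
keeping the estimate finite at rank deficiency; per-shape entropies use an
isotropic Gaussian Parzen window with a per-particle adaptive bandwidth
(distance to the ~6th nearest neighbour).  Optimization is gradient
descent with tangent-plane projection and Newton re-projection onto each
shape's zero level set after every step, with step halving whenever a step
fails to decrease Q.

The mean correspondence vector and its PCA modes (at most N-1 of them
carry variance) form the shape model; the mean *mask* is reconstructed by
warping the ensemble member nearest the mean through a thin-plate-spline
interpolant from its correspondences to the mean correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .registration import RigidTransform, apply_rigid
from .volumes import (BinaryMask, DegenerateMaskError, SignedDistanceField,
                      signed_distance)


class EnsembleError(ValueError):
    """Raised when the shape ensemble is too small for the operation."""


class OptimizationError(RuntimeError):
    """Raised when particles leave the surface beyond recoverable tolerance."""


class ReconstructionError(RuntimeError):
    """Raised when the mean-mask warp cannot be built."""


@dataclass
class ParticleSystem:
    """Index-matched surface particles across an aligned shape ensemble."""

    positions: np.ndarray                  # (N, m, 3) world mm, common frame
    sdfs: list[SignedDistanceField]        # aligned per-shape SDFs
    transforms: list[RigidTransform]       # original -> common frame
    spacing: tuple[float, float, float]

    @property
    def n_shapes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def as_vectors(self) -> np.ndarray:
        """Shape-space matrix X with rows x_k in R^{3m}."""
        return self.positions.reshape(self.n_shapes, -1)


@dataclass
class ShapeModel:
    """Mean correspondence vector plus PCA modes of the aligned ensemble."""

    mean: np.ndarray                       # (3m,) mm
    modes: np.ndarray                      # (n_modes, 3m) orthonormal rows
    eigenvalues: np.ndarray                # (n_modes,) mm^2, non-increasing
    transforms: list[RigidTransform] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def scores(self, ps: ParticleSystem) -> np.ndarray:
        """Per-shape mode scores (projections onto the modes)."""
        return (ps.as_vectors() - self.mean) @ self.modes.T

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


@dataclass
class EnergyBreakdown:
    """One iteration's correspondence-energy decomposition."""

    q: float
    ensemble: float
    sampling: list[float]

    def __post_init__(self) -> None:
        assert abs(self.q - (self.ensemble - sum(self.sampling))) < 1e-10


class _SurfaceInterp:
    """Linear interpolation of an SDF and its gradient at world points."""

    def __init__(self, sdf: SignedDistanceField):
        self.sdf = sdf
        self.spacing = np.asarray(sdf.spacing)
        self.origin = np.asarray(sdf.origin)
        self._grads = np.gradient(sdf.grid, *sdf.spacing)

    def _idx(self, points: np.ndarray) -> np.ndarray:
        return ((points - self.origin) / self.spacing).T

    def value(self, points: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(self.sdf.grid, self._idx(points),
                                       order=1, mode="nearest")

    def gradient(self, points: np.ndarray) -> np.ndarray:
        idx = self._idx(points)
        return np.stack([ndimage.map_coordinates(g, idx, order=1,
                                                 mode="nearest")
                         for g in self._grads], axis=1)

    def project(self, points: np.ndarray, max_newton: int = 10,
                tol_factor: float = 0.05) -> np.ndarray:
        """Newton projection along the SDF gradient onto the zero level set."""
        pts = np.array(points, dtype=float)
        tol = tol_factor * self.spacing.min()
        for _ in range(max_newton):
            v = self.value(pts)
            if np.abs(v).max() < tol:
                break
            g = self.gradient(pts)
            gn2 = np.maximum(np.sum(g * g, axis=1), 1e-12)
            pts -= (v / gn2)[:, None] * g
        return pts

    def tangent(self, points: np.ndarray, vectors: np.ndarray) -> np.ndarray:
        """Remove the surface-normal component of per-particle vectors."""
        g = self.gradient(points)
        gn2 = np.maximum(np.sum(g * g, axis=1), 1e-12)
        return vectors - (np.sum(vectors * g, axis=1) / gn2)[:, None] * g


def _principal_frame(mask: BinaryMask, reference: np.ndarray | None = None):
    """Centroid (mm) and proper-orthonormal principal-axis matrix of a mask.

    Axis signs (and, if needed, the last axis) are flipped to best agree
    with a reference frame, resolving the eigenvector sign ambiguity.
    """
    pts = np.argwhere(mask.grid) * np.asarray(mask.spacing) + np.asarray(
        mask.origin)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    if reference is not None:
        for col in range(3):
            if np.dot(axes[:, col], reference[:, col]) < 0:
                axes[:, col] = -axes[:, col]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return c, axes


def _canonical_order(masks: list[BinaryMask]) -> list[int]:
    """Order-invariant ranking of shapes (volume, then centroid).

    Anchoring reference choices (Procrustes frame, particle seeding) to the
    canonical first shape makes the whole model permutation-invariant.
    """
    keys = []
    for m in masks:
        c = np.argwhere(m.grid).mean(axis=0) if m.grid.any() else np.zeros(3)
        keys.append((int(m.grid.sum()), *np.round(c, 6)))
    return sorted(range(len(masks)), key=lambda i: keys[i])


def procrustes_align(masks: list[BinaryMask], max_iter: int = 10,
                     tol: float = 1e-4):
    """Generalized Procrustes alignment over centroids and principal axes.

    Rigid only (no scaling: size differences are real shape signal).
    Returns per-shape (RigidTransform, aligned SignedDistanceField); the
    transforms map each original shape into the common frame.
    """
    if len(masks) < 2:
        raise EnsembleError("alignment needs at least 2 shapes")
    if any(m.is_empty() for m in masks):
        raise DegenerateMaskError("cannot align empty masks")
    order = _canonical_order(masks)
    anchor = order[0]
    ref_axes = _principal_frame(masks[anchor])[1]
    frames = [_principal_frame(m, reference=ref_axes) for m in masks]
    c_ref = np.mean([c for c, _ in frames], axis=0)
    r_ref = frames[anchor][1]
    transforms = None
    for _ in range(max_iter):
        new = [RigidTransform(rotation=r_ref @ axes.T,
                              translation=c_ref - (r_ref @ axes.T) @ c)
               for c, axes in frames]
        if transforms is not None:
            delta = max(np.abs(a.rotation - b.rotation).max()
                        + np.abs(a.translation - b.translation).max()
                        for a, b in zip(new, transforms))
            transforms = new
            if delta < tol:
                break
        transforms = new
        # reference update: mean rotation (polar factor) and mean centroid
        mean_r = np.mean([t.rotation @ f[1] for t, f in zip(transforms, frames)],
                         axis=0)
        u, _, vt = np.linalg.svd(r_ref.T @ mean_r)
        r_ref = r_ref @ (u @ vt) if np.linalg.det(u @ vt) > 0 else r_ref
    aligned = []
    for m, t in zip(masks, transforms):
        moved = apply_rigid(m, t, target=m)
        aligned.append((t, signed_distance(moved)))
    return aligned


def _bandwidth(pts: np.ndarray, k: int = 6, floor: float = 0.5) -> float:
    """Ensemble bandwidth: median distance to the ~6th nearest neighbour.

    A single global bandwidth keeps the uniform distribution a stable fixed
    point of the repulsion dynamics: a per-particle bandwidth lets clusters
    shrink their own interaction range and persist.
    """
    m = len(pts)
    kk = min(k, m - 1)
    if kk < 1:
        return 1.0
    d, _ = cKDTree(pts).query(pts, k=kk + 1)
    return float(max(np.median(d[:, -1]), floor))


def _repulsion(pts: np.ndarray) -> np.ndarray:
    """Sampling-entropy ascent direction: particles repel their neighbours.

    Each neighbour within the Gaussian window contributes a unit vector, so
    the force on a nearly-coincident pair stays finite instead of vanishing
    with the pair distance.
    """
    sigma = _bandwidth(pts)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt(np.sum(diff ** 2, axis=-1))
    w = np.exp(-d ** 2 / (2.0 * sigma ** 2))
    np.fill_diagonal(w, 0.0)
    unit = diff / np.maximum(d, 1e-3 * sigma)[:, :, None]
    force = np.sum(w[:, :, None] * unit, axis=1)
    return force / (np.sum(w, axis=1)[:, None] + 1e-12)


def _sampling_entropy(pts: np.ndarray) -> float:
    """Parzen-window differential entropy of particles on one surface."""
    m = len(pts)
    sigma = _bandwidth(pts)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    kern = np.exp(-d2 / (2.0 * sigma ** 2)) / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
    np.fill_diagonal(kern, 0.0)
    dens = kern.sum(axis=1) / max(m - 1, 1)
    return float(-np.mean(np.log(np.maximum(dens, 1e-300))))


def _ensemble_entropy(vectors: np.ndarray, alpha_rel: float = 1e-3):
    """Gaussian-model entropy of the shape-space ensemble and its gradient.

    Returns (H, grad) where grad has the same shape as `vectors` (N x 3m).
    """
    n = vectors.shape[0]
    y = vectors - vectors.mean(axis=0)
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    lam = s ** 2 / max(n - 1, 1)
    alpha = alpha_rel * max(lam.mean(), 0.0) + 1e-8
    h = 0.5 * float(np.sum(np.log(lam[: n - 1] + alpha)))
    # d/dY 0.5 log det(C + aI) = Y (C + aI)^{-1} / (n-1)
    inv = s / (s ** 2 + alpha * max(n - 1, 1))
    grad = (u * inv) @ vt
    return h, grad, alpha


def _separate_coincident(interp: _SurfaceInterp, pts: np.ndarray,
                         rng: np.random.Generator, h: float) -> np.ndarray:
    """Kick apart (near-)coincident particles.

    Coincident particles feel identical repulsion forces and would move in
    lockstep forever; one of each close pair gets a tangential kick.
    """
    if len(pts) < 2:
        return pts
    d, idx = cKDTree(pts).query(pts, k=2)
    close = np.flatnonzero(d[:, 1] < 0.25 * h)
    close = close[close < idx[close, 1]]        # one kick per pair
    if len(close):
        kick = interp.tangent(pts[close], rng.normal(size=(len(close), 3)))
        norm = np.linalg.norm(kick, axis=1, keepdims=True)
        pts = pts.copy()
        pts[close] = interp.project(
            pts[close] + kick / np.maximum(norm, 1e-12) * 0.5 * h)
    return pts


def initialize_particles(sdf: SignedDistanceField, m_target: int = 256,
                         seed: int = 0, relax_iters: int = 20,
                         step: float = 0.5) -> np.ndarray:
    """Seed particles on a surface by iterative splitting.

    Starting from a single surface point, every particle is duplicated
    with a small random offset, projected back to the zero level set, and
    the set is relaxed by Parzen repulsion until ``m_target`` (a power of
    two >= 16) particles cover the surface.
    """
    if m_target < 16 or (m_target & (m_target - 1)) != 0:
        raise ValueError("m_target must be a power of two >= 16")
    interp = _SurfaceInterp(sdf)
    rng = np.random.default_rng(seed)
    near = np.abs(sdf.grid)
    if not np.isfinite(near).any():
        raise DegenerateMaskError("surface is empty")
    start_idx = np.unravel_index(np.argmin(near), near.shape)
    start = np.asarray(start_idx) * interp.spacing + interp.origin
    pts = interp.project(start[None, :])
    h = float(interp.spacing.min())
    while len(pts) < m_target:
        # split tangentially: a purely normal offset would project the copy
        # back onto its parent, leaving a coincident pair repulsion cannot
        # separate
        offsets = interp.tangent(pts, rng.normal(size=pts.shape))
        norm = np.linalg.norm(offsets, axis=1, keepdims=True)
        offsets = offsets / np.maximum(norm, 1e-12) * 0.5 * h
        pts = np.vstack([pts, interp.project(pts + offsets)])
        for _ in range(relax_iters):
            pts = _separate_coincident(interp, pts, rng, h)
            move = interp.tangent(pts, _repulsion(pts))
            norm = np.linalg.norm(move, axis=1, keepdims=True)
            move = move * np.minimum(1.0, h / np.maximum(norm, 1e-12))
            pts = interp.project(pts + step * move)
    return _separate_coincident(interp, pts, rng, h)


def optimize_correspondences(masks: list[BinaryMask], m: int = 256,
                             iterations: int = 200,
                             step_sampling: float = 0.5,
                             step_ensemble: float = 0.5,
                             seed: int = 0, tol: float = 1e-5,
                             alpha_rel: float = 1e-3):
    """Optimize entropy-based particle correspondences across an ensemble.

    Alternates per-shape Parzen repulsion (sampling-entropy ascent) with a
    Gaussian shape-space compaction step (ensemble-entropy descent), each
    followed by tangent-plane projection back to the zero level set.  Steps
    that increase the total energy Q are reverted with halved step sizes.

    Returns (ParticleSystem, list[EnergyBreakdown]).
    """
    if len(masks) < 1:
        raise EnsembleError("need at least one shape")
    if m < 16:
        raise ValueError("need at least 16 particles")
    n = len(masks)
    if n >= 2:
        aligned = procrustes_align(masks)
        transforms = [t for t, _ in aligned]
        sdfs = [s for _, s in aligned]
    else:
        transforms = [RigidTransform()]
        sdfs = [signed_distance(masks[0])]
    interps = [_SurfaceInterp(s) for s in sdfs]
    h = float(np.min(masks[0].spacing))

    # shared initialization: seed on the canonical first shape, then project
    # the same set onto every other surface so particle indices start
    # roughly in correspondence (and the result is order-invariant)
    anchor = _canonical_order(masks)[0]
    base = initialize_particles(sdfs[anchor], m_target=m, seed=seed)
    pos = np.stack([interp.project(base) for interp in interps])

    def energy(p):
        sampling = [_sampling_entropy(p[k]) for k in range(n)]
        if n >= 2:
            ens = _ensemble_entropy(p.reshape(n, -1), alpha_rel)[0]
        else:
            ens = 0.0
        return EnergyBreakdown(q=ens - sum(sampling), ensemble=ens,
                               sampling=sampling)

    trace = [energy(pos)]
    # per-shape streams keyed by canonical rank keep the optimization
    # invariant to the order shapes are passed in
    ranks = np.argsort(_canonical_order(masks))
    rngs = [np.random.default_rng((seed, 1000 + int(ranks[k])))
            for k in range(n)]
    s_samp, s_ens = step_sampling * h, step_ensemble * h
    for _ in range(iterations):
        trial = pos.copy()
        # (a) sampling-entropy ascent: uniform spread on each surface
        for k in range(n):
            trial[k] = _separate_coincident(interps[k], trial[k], rngs[k], h)
            move = interps[k].tangent(trial[k], _repulsion(trial[k]))
            nrm = np.linalg.norm(move, axis=1, keepdims=True)
            move = move * np.minimum(1.0, h / np.maximum(nrm, 1e-12))
            trial[k] = interps[k].project(trial[k] + s_samp * move)
        # (b) ensemble-entropy descent: compact the shape-space distribution
        if n >= 2:
            _, grad, _ = _ensemble_entropy(trial.reshape(n, -1), alpha_rel)
            grad = grad.reshape(n, m, 3)
            for k in range(n):
                move = interps[k].tangent(trial[k], -grad[k])
                nrm = np.linalg.norm(move, axis=1, keepdims=True)
                move = move * np.minimum(1.0, h / np.maximum(nrm, 1e-12))
                trial[k] = interps[k].project(trial[k] + s_ens * move)
        for k in range(n):
            off = np.abs(interps[k].value(trial[k])).max()
            if off > 2.0 * h:
                raise OptimizationError(
                    f"particle left surface of shape {k} by {off:.2f} mm")
        e_new = energy(trial)
        if e_new.q < trace[-1].q:
            pos = trial
            rel = abs(trace[-1].q - e_new.q) / max(abs(trace[-1].q), 1e-12)
            trace.append(e_new)
            s_samp = min(s_samp * 1.05, step_sampling * h)
            s_ens = min(s_ens * 1.05, step_ensemble * h)
            if rel < tol:
                break
        elif s_samp > 0.01 * h:
            # uniform-spread moves fight ensemble compaction first: shrink
            # the sampling step before touching the ensemble step
            s_samp *= 0.5
        else:
            s_ens *= 0.5
            if s_ens < 1e-4 * h:
                break
    ps = ParticleSystem(positions=pos, sdfs=sdfs, transforms=transforms,
                        spacing=masks[0].spacing)
    return ps, trace


def build_shape_model(ps: ParticleSystem, alpha_rel: float = 1e-3) -> ShapeModel:
    """PCA of the correspondence vectors: mean, modes and eigenvalues.

    With N shapes at most N-1 eigenvalues are strictly positive; the dual
    (N x N) eigenproblem is solved via SVD of the centered data matrix.
    """
    if ps.n_shapes < 2:
        raise EnsembleError("a shape model needs at least 2 shapes")
    x = ps.as_vectors()
    mean = x.mean(axis=0)
    y = x - mean
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    n_keep = ps.n_shapes - 1
    eigenvalues = (s ** 2 / (ps.n_shapes - 1))[:n_keep]
    modes = vt[:n_keep]
    return ShapeModel(mean=mean, modes=modes, eigenvalues=eigenvalues,
                      transforms=list(ps.transforms))


def reconstruct_mean_mask(model: ShapeModel, ps: ParticleSystem,
                          masks: list[BinaryMask],
                          chunk: int = 65536) -> BinaryMask:
    """Voxelize the mean shape in the common frame.

    The ensemble member nearest the mean in shape space is warped by a
    thin-plate-spline interpolant carrying its correspondences onto the
    mean correspondences: the member's aligned SDF is resampled through
    the inverse (mean -> member) displacement and thresholded at zero, so
    the result is a filled mask by construction.
    """
    x = ps.as_vectors()
    k_star = int(np.argmin(np.linalg.norm(x - model.mean, axis=1)))
    member = ps.positions[k_star]                      # (m, 3)
    mean_pts = model.mean.reshape(-1, 3)
    if len(np.unique(np.round(mean_pts, 6), axis=0)) < len(mean_pts):
        raise ReconstructionError("coincident particles make the warp singular")
    try:
        rbf = RBFInterpolator(mean_pts, member - mean_pts,
                              kernel="thin_plate_spline")
    except np.linalg.LinAlgError as exc:
        raise ReconstructionError(f"singular warp system: {exc}") from exc
    sdf = ps.sdfs[k_star]
    interp = _SurfaceInterp(sdf)
    shape = sdf.grid.shape
    coords = np.argwhere(np.ones(shape, dtype=bool)) * interp.spacing + \
        interp.origin
    values = np.empty(len(coords))
    for lo in range(0, len(coords), chunk):
        sl = slice(lo, lo + chunk)
        src = coords[sl] + rbf(coords[sl])
        values[sl] = interp.value(src)
    grid = (values < 0).reshape(shape)
    return BinaryMask(grid=grid, spacing=sdf.spacing, origin=sdf.origin)


def mean_mask_from_sdf_average(ps: ParticleSystem) -> BinaryMask:
    """Fallback mean-shape strategy: average aligned SDFs, threshold at 0."""
    avg = np.mean([s.grid for s in ps.sdfs], axis=0)
    ref = ps.sdfs[0]
    return BinaryMask(grid=avg < 0, spacing=ref.spacing, origin=ref.origin)
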