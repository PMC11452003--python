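"""Seeded generators of muscle-like 3D phantoms and corrupted predictions.

Real thigh muscles are elongated, roughly tubular structures running along
the scanner's axial (knee-to-hip) axis, with smooth inter-subject variation
in girth and centreline.  The generators here emulate exactly that: tapered
tubes whose per-slice radius is a fixed low-order cosine profile plus a
smooth, low-dimensional random perturbation, packed side by side for
multi-label volumes.  Corruption reproduces the two characteristic error
modes of slice-wise segmenters: blank regions (voxels of a muscle left
unassigned) and mis-segmentation (voxels assigned to the wrong muscle),
plus boundary jitter and spurious satellite blobs.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, LabelVolume, signed_distance

#: number of cosine harmonics in the radius perturbation basis
N_HARMONICS = 4


class PhantomSpecError(ValueError):
    """Raised when a phantom cannot be built within its volume."""


@dataclass
class PhantomSpec:
    """Describes a family of tube phantoms.

    base_radius may be a scalar (constant profile scaled by a fusiform
    taper) or an explicit per-slice array of length volume_shape[2].
    variability is the amplitude (voxels) of the per-subject smooth radius
    perturbation; harmonics restricts which cosine harmonics are drawn
    (default: all of 0..N_HARMONICS-1, harmonic 0 being a uniform radius
    offset).
    """

    n_subjects: int = 10
    n_labels: int = 1
    volume_shape: tuple[int, int, int] = (64, 64, 96)
    base_radius: float | np.ndarray = 8.0
    variability: float = 1.5
    bend_amplitude: float = 2.0
    harmonics: tuple[int, ...] = tuple(range(N_HARMONICS))
    gap: int = 2
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def radius_profile(self) -> np.ndarray:
        nz = self.volume_shape[2]
        if np.isscalar(self.base_radius):
            z = np.arange(nz) / max(nz - 1, 1)
            # fusiform taper: full girth mid-belly, rounded tips at the ends
            return float(self.base_radius) * np.sqrt(np.sin(np.pi * z))
        prof = np.asarray(self.base_radius, dtype=float)
        if prof.shape != (nz,):
            raise PhantomSpecError("per-slice radius profile length must match nz")
        return prof


@dataclass
class CorruptionSpec:
    """Controls the synthetic segmentation errors applied to a ground truth."""

    hole_count: int = 5
    hole_radius: float = 6.0
    blob_count: int = 3
    blob_radius: float = 3.0
    boundary_noise: float = 0.3
    swap_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hole_count, self.blob_count) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.swap_fraction <= 1.0:
            raise ValueError("swap_fraction must be in [0, 1]")


def _subject_coefficients(rng: np.random.Generator, spec: PhantomSpec):
    """Draw one subject's radius-harmonic and bend coefficients."""
    coeffs = np.zeros(N_HARMONICS)
    draws = rng.uniform(-1.0, 1.0, size=len(spec.harmonics))
    # the total perturbation amplitude is bounded by `variability`
    for h, c in zip(spec.harmonics, draws):
        coeffs[h] = c * spec.variability / len(spec.harmonics)
    bend = rng.uniform(-1.0, 1.0, size=2) * spec.bend_amplitude
    bend_phase = rng.uniform(0.0, np.pi, size=2)
    return coeffs, bend, bend_phase


def _tube_mask(spec: PhantomSpec, center_xy: tuple[float, float],
               coeffs: np.ndarray, bend: np.ndarray,
               bend_phase: np.ndarray, max_radius: float | None = None
               ) -> np.ndarray:
    nx, ny, nz = spec.volume_shape
    z = np.arange(nz) / max(nz - 1, 1)
    radius = spec.radius_profile().copy()
    for h in range(N_HARMONICS):
        radius = radius + coeffs[h] * np.cos(np.pi * h * z)
    radius = np.clip(radius, 1.0, None)
    if max_radius is not None:
        radius = np.clip(radius, None, max_radius)
    # z-margin: keep one empty slice at each end so the tube is closed
    radius[[0, -1]] = 0.0
    cx = center_xy[0] + bend[0] * np.sin(np.pi * z + bend_phase[0])
    cy = center_xy[1] + bend[1] * np.sin(np.pi * z + bend_phase[1])
    xi = np.arange(nx)[:, None, None]
    yi = np.arange(ny)[None, :, None]
    d2 = (xi - cx[None, None, :]) ** 2 + (yi - cy[None, None, :]) ** 2
    grid = d2 <= radius[None, None, :] ** 2
    # margin check: nothing may touch the lateral faces
    if grid[0].any() or grid[-1].any() or grid[:, 0].any() or grid[:, -1].any():
        raise PhantomSpecError("tube overflows the volume; shrink radius or bend")
    return grid


def generate_shape_family(spec: PhantomSpec, return_params: bool = False):
    """Generate ``spec.n_subjects`` single-tube masks with smooth variability.

    With ``return_params=True`` also returns the (n_subjects, N_HARMONICS)
    matrix of radius-harmonic coefficients actually used, for parameter-
    recovery experiments.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, _ = spec.volume_shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    masks, params = [], []
    for _ in range(spec.n_subjects):
        coeffs, bend, phase = _subject_coefficients(rng, spec)
        grid = _tube_mask(spec, center, coeffs, bend, phase)
        n_comp = ndimage.label(grid, structure=ndimage.generate_binary_structure(3, 1))[1]
        if n_comp != 1:
            raise PhantomSpecError(f"tube is not a single component ({n_comp})")
        masks.append(BinaryMask(grid=grid, spacing=spec.spacing))
        params.append(coeffs)
    if return_params:
        return masks, np.asarray(params)
    return masks


def _label_centers(spec: PhantomSpec) -> list[tuple[float, float]]:
    """Pack L tube centres along x with the configured gap; error if they
    cannot fit with a 2-voxel lateral margin."""
    nx, ny, _ = spec.volume_shape
    L = spec.n_labels
    rmax = float(np.max(spec.radius_profile())) + spec.variability
    pitch = 2 * rmax + spec.gap
    width = pitch * (L - 1)
    if width + 2 * rmax + 4 > nx:
        raise PhantomSpecError(
            f"cannot pack {L} tubes of max radius {rmax:.1f} into nx={nx}")
    x0 = (nx - 1) / 2.0 - width / 2.0
    return [(x0 + i * pitch, (ny - 1) / 2.0) for i in range(L)]


def generate_multilabel_phantom(spec: PhantomSpec) -> LabelVolume:
    """One subject's multi-label phantom: L parallel non-overlapping tubes.

    The subject is selected by ``spec.seed``; per-label shapes get
    independent sub-streams so families across subjects stay smooth.
    """
    if spec.n_labels < 2:
        raise PhantomSpecError("a multi-label phantom needs n_labels >= 2")
    centers = _label_centers(spec)
    rmax = float(np.max(spec.radius_profile())) + spec.variability
    grid = np.zeros(spec.volume_shape, dtype=np.int16)
    for label, c in enumerate(centers, start=1):
        rng = np.random.default_rng((spec.seed, label))
        coeffs, bend, phase = _subject_coefficients(rng, spec)
        bend = bend * 0.5  # limit lateral drift so the packing gap holds
        tube = _tube_mask(spec, c, coeffs, bend, phase, max_radius=rmax)
        if (grid[tube] != 0).any():
            raise PhantomSpecError("tubes overlap; increase gap or shrink radius")
        grid[tube] = label
    return LabelVolume(grid=grid, spacing=spec.spacing)


def _sphere_at(shape, center, radius) -> np.ndarray:
    lo = [max(int(np.floor(c - radius)) - 1, 0) for c in center]
    hi = [min(int(np.ceil(c + radius)) + 2, s) for c, s in zip(center, shape)]
    out = np.zeros(shape, dtype=bool)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    coords = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    d2 = sum((c - cc) ** 2 for c, cc in zip(coords, center))
    out[sl] = d2 <= radius ** 2
    return out


def corrupt_prediction(gt: LabelVolume, c: CorruptionSpec) -> LabelVolume:
    """Apply the configured error modes to a ground-truth label volume.

    Per label: spherical blank regions inside the muscle, spurious satellite
    blobs 2-5 voxels outside it, random flips in a band around the boundary,
    and reassignment of a fraction of contact-zone voxels to the adjacent
    label.  Geometry metadata is never altered.
    """
    rng = np.random.default_rng(c.seed)
    out = gt.grid.copy()
    labels = gt.labels()
    for label in labels:
        mask = gt.grid == label
        if not mask.any():
            continue
        fg = np.argwhere(mask)
        # (a) blank regions: spherical voids set to background
        for _ in range(c.hole_count):
            center = fg[rng.integers(len(fg))]
            out[_sphere_at(gt.shape, center, c.hole_radius) & mask] = 0
        # (b) spurious blobs: spheres of this label 2-5 voxels outside it
        if c.blob_count:
            sdf = signed_distance(BinaryMask(mask, gt.spacing, gt.origin)).grid
            for _ in range(c.blob_count):
                band = np.argwhere((sdf > 2 + c.blob_radius) &
                                   (sdf < 5 + c.blob_radius) & (gt.grid == 0))
                if len(band) == 0:
                    continue
                center = band[rng.integers(len(band))]
                blob = _sphere_at(gt.shape, center, c.blob_radius) & (gt.grid == 0)
                out[blob & (out == 0)] = label
        # (c) boundary noise: flip label<->background in a band of the stated
        # amplitude around the surface, p=0.3 per voxel
        if c.boundary_noise > 0:
            sdf = signed_distance(BinaryMask(mask, gt.spacing, gt.origin)).grid
            band = (np.abs(sdf) <= c.boundary_noise) & ((gt.grid == label) |
                                                        (gt.grid == 0))
            flips = band & (rng.random(gt.shape) < 0.3)
            inner = flips & mask
            outer = flips & ~mask & (out == 0)
            out[inner] = 0
            out[outer] = label
        # (d) mis-segmentation: contact-zone voxels handed to an adjacent
        # label; the zone adapts to the actual inter-label gap so the error
        # mode exists regardless of packing
        if c.swap_fraction > 0 and len(labels) > 1:
            others = [l for l in labels if l != label]
            for other in others:
                d_other = ndimage.distance_transform_edt(gt.grid != other)
                reach = d_other[mask].min() + 2.0
                zone = np.argwhere(mask & (d_other <= reach))
                if len(zone) == 0:
                    continue
                take = rng.random(len(zone)) < c.swap_fraction
                iz = zone[take]
                out[iz[:, 0], iz[:, 1], iz[:, 2]] = other
    return LabelVolume(grid=out, spacing=gt.spacing, origin=gt.origin)


def synth_intensity_image(gt: LabelVolume, class_means: dict[int, float],
                          noise_sd: float = 5.0, seed: int = 0) -> np.ndarray:
    """MRI-like piecewise-constant image with Gaussian noise."""
    missing = set(int(v) for v in np.unique(gt.grid)) - set(class_means)
    if missing:
        raise ValueError(f"class_means lacks labels {sorted(missing)}")
    rng = np.random.default_rng(seed)
    img = np.zeros(gt.shape, dtype=float)
    for label, mean in class_means.items():
        img[gt.grid == label] = mean
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=gt.shape)
    return img


def unaries_from_labels(noisy_labels: LabelVolume, flip_prob: float = 0.1,
                        n_classes: int | None = None) -> np.ndarray:
    """Per-class probability maps [c, x, y, z] from a (noisy) label volume.

    The observed label gets probability 1-flip_prob; the remainder is split
    uniformly over the other classes.
    """
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    if n_classes is None:
        n_classes = int(noisy_labels.grid.max()) + 1
    probs = np.full((n_classes,) + noisy_labels.shape,
                    flip_prob / max(n_classes - 1, 1))
    for cls in range(n_classes):
        probs[cls][noisy_labels.grid == cls] = 1.0 - flip_prob
    if n_classes == 1:
        probs[:] = 1.0
    return probs
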