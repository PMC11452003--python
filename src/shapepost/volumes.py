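"""Core volume types, file I/O, surface extraction and morphological cleanup.

Conventions
-----------
Grids are indexed ``(i, j, k)`` mapping to world ``(x, y, z)`` as
``world = origin + index * spacing`` (axis-aligned geometry only; images with
a non-trivial direction matrix are rejected at load time).  All world
coordinates and distances are in millimetres; morphology operates in voxel
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


class FormatError(ValueError):
    """Raised for files whose content violates the expected label format."""


class UnsupportedOrientationError(ValueError):
    """Raised when an image has a non-axis-aligned orientation matrix."""


class DegenerateMaskError(ValueError):
    """Raised when an operation receives an all-true or all-false mask."""


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class LabelVolume:
    """Multi-class 3D segmentation grid.

    Label 0 is background; labels are non-negative integers.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            if np.issubdtype(self.grid.dtype, np.bool_):
                self.grid = self.grid.astype(np.int16)
            else:
                raise FormatError("label grid must be integer-valued")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def labels(self) -> list[int]:
        """Sorted list of non-background labels present in the grid."""
        return [int(v) for v in np.unique(self.grid) if v != 0]


@dataclass
class BinaryMask:
    """Single-label boolean mask sharing the parent volume's geometry."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.grid.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def volume_mm3(self) -> float:
        return float(self.grid.sum()) * float(np.prod(self.spacing))

    def is_empty(self) -> bool:
        return not bool(self.grid.any())


@dataclass
class SignedDistanceField:
    """Euclidean signed distance in mm: negative inside, positive outside."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class PointCloud:
    """Set of 3D world coordinates in mm (one row per point)."""

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


def _check_axis_aligned(img: sitk.Image) -> None:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise UnsupportedOrientationError(
            "only identity orientation matrices are supported; "
            f"got {direction.tolist()}"
        )


def read_label_volume(path) -> LabelVolume:
    """Read an integer label volume from NIfTI or MetaImage.

    SimpleITK returns arrays indexed ``[z, y, x]``; the grid is transposed to
    the package's ``(x, y, z)`` index order.
    """
    img = sitk.ReadImage(str(path))
    _check_axis_aligned(img)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D volume, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("voxel values are not integers")
        arr = np.round(arr).astype(np.int32)
    grid = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return LabelVolume(grid=grid, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a label volume as NIfTI/MetaImage (chosen by file extension)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.grid.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def read_scalar_volume(path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a float 3D volume; returns (grid[x,y,z], spacing, origin)."""
    img = sitk.ReadImage(str(path))
    _check_axis_aligned(img)
    arr = sitk.GetArrayFromImage(img).astype(float)
    return np.ascontiguousarray(arr.transpose(2, 1, 0)), img.GetSpacing(), img.GetOrigin()


def write_scalar_volume(grid: np.ndarray, path, spacing=(1.0, 1.0, 1.0),
                        origin=(0.0, 0.0, 0.0)) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.asarray(grid, dtype=np.float32).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def read_probability_volume(path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a multi-channel probability volume.

    Returns (probs[c, x, y, z], spacing, origin).  Accepts either a 4D image
    (channels on the slowest axis) or a vector-pixel image.
    """
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(float)
    if arr.ndim == 4 and img.GetNumberOfComponentsPerPixel() > 1:
        # vector image: [z, y, x, c]
        probs = arr.transpose(3, 2, 1, 0)
    elif arr.ndim == 4:
        probs = arr.transpose(0, 3, 2, 1)
    else:
        raise FormatError("expected a 4D or vector-pixel probability image")
    return np.ascontiguousarray(probs), img.GetSpacing()[:3], img.GetOrigin()[:3]


def write_probability_volume(probs: np.ndarray, path, spacing=(1.0, 1.0, 1.0),
                             origin=(0.0, 0.0, 0.0)) -> None:
    """Write probs[c, x, y, z] as a vector-pixel volume."""
    arr = np.ascontiguousarray(
        np.asarray(probs, dtype=np.float32).transpose(3, 2, 1, 0))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def extract_label_mask(vol: LabelVolume, label: int) -> BinaryMask:
    """Binary mask of one label; absent labels give an empty mask."""
    if label < 1:
        raise ValueError("label must be >= 1 (0 is background)")
    return BinaryMask(grid=vol.grid == label, spacing=vol.spacing, origin=vol.origin)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_indices(mask: BinaryMask) -> np.ndarray:
    """Integer (i,j,k) indices of surface voxels, lexicographic order.

    A foreground voxel is on the surface if any of its 6 face neighbours is
    background; voxels on the array border count as surface.
    """
    if mask.is_empty():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask.grid, structure=_FACE_STRUCT,
                                      border_value=0)
    return np.argwhere(mask.grid & ~interior)


def surface_voxels(mask: BinaryMask) -> PointCloud:
    """World-coordinate centres (mm) of the mask's surface voxels."""
    idx = surface_indices(mask)
    pts = idx * np.asarray(mask.spacing) + np.asarray(mask.origin)
    return PointCloud(points=pts)


def signed_distance(mask: BinaryMask) -> SignedDistanceField:
    """Exact Euclidean signed distance field of a mask, in mm.

    Computed as (distance to nearest foreground voxel) minus (distance to
    nearest background voxel), so foreground boundary voxels sit at
    -1 voxel, adjacent background at +1 voxel, and the zero level set lies
    on the interface between them.  Thresholding at 0 recovers the mask.
    """
    grid = mask.grid
    if not grid.any() or grid.all():
        raise DegenerateMaskError("signed distance needs both phases present")
    sampling = mask.spacing
    outside = ndimage.distance_transform_edt(~grid, sampling=sampling)
    inside = ndimage.distance_transform_edt(grid, sampling=sampling)
    return SignedDistanceField(grid=outside - inside, spacing=mask.spacing,
                               origin=mask.origin)


def ball_structuring_element(radius: int) -> np.ndarray:
    """Discrete ball {(di,dj,dk): di^2+dj^2+dk^2 <= r^2} in voxel units."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    di, dj, dk = np.meshgrid(ax, ax, ax, indexing="ij")
    return (di ** 2 + dj ** 2 + dk ** 2) <= r ** 2


def box_structuring_element(radius: int) -> np.ndarray:
    """Chebyshev-metric ball {max(|di|,|dj|,|dk|) <= r}, a (2r+1)^3 box."""
    r = int(radius)
    return np.ones((2 * r + 1,) * 3, dtype=bool)


def cleanup_3d(mask: BinaryMask, radius: int = 1,
               element: str = "box") -> BinaryMask:
    """Rough 3D cleanup: morphological opening (erosion then dilation).

    Removes components and protrusions thinner than the structuring
    element while leaving large convex bodies untouched.  The default
    element is the Chebyshev-metric ball (a box), under which cuboid
    shapes are exactly invariant; ``element="ball"`` selects the
    Euclidean-metric ball, which additionally rounds sharp edges.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if mask.is_empty():
        return replace(mask, grid=mask.grid.copy())
    if element == "box":
        struct = box_structuring_element(radius)
    elif element == "ball":
        struct = ball_structuring_element(radius)
    else:
        raise ValueError("element must be 'box' or 'ball'")
    opened = ndimage.binary_opening(mask.grid, structure=struct)
    return BinaryMask(grid=opened, spacing=mask.spacing, origin=mask.origin)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Largest 6-connected component (ties to the lowest label in scan
    order); empty masks pass through unchanged."""
    if mask.is_empty():
        return replace(mask, grid=mask.grid.copy())
    labels, n = ndimage.label(mask.grid, structure=_FACE_STRUCT)
    if n == 1:
        return replace(mask, grid=mask.grid.copy())
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    return BinaryMask(grid=labels == keep, spacing=mask.spacing,
                      origin=mask.origin)


def remove_small_components(mask: BinaryMask,
                            min_fraction: float = 0.1) -> BinaryMask:
    """Drop 6-connected components smaller than a fraction of the largest.

    Distinguishes spurious satellite blobs (small) from genuine fragments
    of a body severed by blank regions (comparable in size to the main
    component), which must be kept.
    """
    if mask.is_empty():
        return replace(mask, grid=mask.grid.copy())
    labels, n = ndimage.label(mask.grid, structure=_FACE_STRUCT)
    if n == 1:
        return replace(mask, grid=mask.grid.copy())
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts >= min_fraction * counts.max()) + 1
    return BinaryMask(grid=np.isin(labels, keep), spacing=mask.spacing,
                      origin=mask.origin)


def recompose_labels(masks: dict[int, BinaryMask],
                     soft: dict[int, np.ndarray] | None = None,
                     shape: tuple[int, int, int] | None = None,
                     spacing=(1.0, 1.0, 1.0),
                     origin=(0.0, 0.0, 0.0)) -> LabelVolume:
    """Merge per-label masks into one LabelVolume.

    Voxels claimed by several masks are resolved by the highest soft score
    (ties by lowest label id); without soft scores, by lowest label id.
    Unclaimed voxels become background.
    """
    if not masks:
        if shape is None:
            raise ValueError("need at least one mask or an explicit shape")
        return LabelVolume(grid=np.zeros(shape, dtype=np.int16),
                           spacing=spacing, origin=origin)
    first = next(iter(masks.values()))
    out = np.zeros(first.shape, dtype=np.int16)
    best = np.full(first.shape, -np.inf)
    for label in sorted(masks):
        m = masks[label]
        if m.shape != first.shape:
            raise GeometryError("all masks must share the same grid")
        score = soft[label] if soft is not None and label in soft else np.ones(m.shape)
        claim = m.grid & (score > best)
        out[claim] = label
        best[claim] = score[claim]
    return LabelVolume(grid=out, spacing=first.spacing, origin=first.origin)
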