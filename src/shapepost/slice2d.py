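"""Slice-wise 2D morphological post-processing (comparator method).

Per label and per axial slice: erosion with a discrete disk, retention of
the single largest connected component, dilation with the same disk, hole
filling, and smoothing by convolution with a uniform w x w kernel followed
by thresholding.  Defaults (disk radius 3, 8-connectivity, w = 5,
threshold 0.5) follow the published parameterization of this pipeline.
The method assumes each muscle occupies one region per slice with a smooth
outline; muscles that legitimately split into several regions on a slice
lose all but the largest — a known failure mode of this comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, LabelVolume, extract_label_mask, recompose_labels


@dataclass
class Slice2DParams:
    """Tunable parameters of the 2D pipeline."""

    radius: int = 3
    connectivity: int = 8
    smooth_width: int = 5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("disk radius must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def disk_structuring_element(radius: int) -> np.ndarray:
    """Discrete disk {(di,dj): di^2 + dj^2 <= r^2}."""
    ax = np.arange(-radius, radius + 1)
    di, dj = np.meshgrid(ax, ax, indexing="ij")
    return (di ** 2 + dj ** 2) <= radius ** 2


def _largest_component(mask: np.ndarray, connectivity: int) -> np.ndarray:
    structure = np.ones((3, 3), bool) if connectivity == 8 else \
        ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())[1:]
    # ties broken by lowest component label in scan order (argmax is first max)
    keep = int(np.argmax(counts)) + 1
    return labels == keep


def postprocess_slice(mask2d: np.ndarray, p: Slice2DParams | None = None
                      ) -> np.ndarray:
    """Apply the full per-slice operator chain to one binary slice."""
    if p is None:
        p = Slice2DParams()
    se = disk_structuring_element(p.radius)
    out = ndimage.binary_erosion(mask2d.astype(bool), structure=se,
                                 border_value=0)
    if not out.any():
        return np.zeros_like(mask2d, dtype=bool)
    out = _largest_component(out, p.connectivity)
    out = ndimage.binary_dilation(out, structure=se)
    out = ndimage.binary_fill_holes(out)
    w = p.smooth_width
    kernel = np.ones((w, w)) / (w * w)
    smooth = ndimage.convolve(out.astype(float), kernel, mode="constant",
                              cval=0.0)
    return smooth > p.threshold


def postprocess_2d_volume(pred: LabelVolume, p: Slice2DParams | None = None,
                          labels: list[int] | None = None) -> LabelVolume:
    """Slice-wise 2D post-processing of every label, then recomposition.

    Slices are taken along the third (axial) axis.  Overlaps after
    recomposition are resolved exactly as in the mean-shape pipeline
    (lowest label id wins ties; no soft scores here).
    """
    if p is None:
        p = Slice2DParams()
    if labels is None:
        labels = pred.labels()
    masks = {}
    for label in sorted(labels):
        m = extract_label_mask(pred, label)
        out = np.zeros(m.shape, dtype=bool)
        for k in range(m.shape[2]):
            if m.grid[:, :, k].any():
                out[:, :, k] = postprocess_slice(m.grid[:, :, k], p)
        masks[label] = BinaryMask(out, pred.spacing, pred.origin)
    return recompose_labels(masks, shape=pred.shape, spacing=pred.spacing,
                            origin=pred.origin)
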