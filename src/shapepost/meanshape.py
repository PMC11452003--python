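"""Mean-shape post-processing of predicted multi-label segmentations.

Per muscle label the pipeline is: rough 3D morphological cleanup of the
prediction, ICP rigid alignment of the label's mean shape onto the cleaned
prediction (moving: mean shape; fixed: prediction), then nodal-grid
deformable registration of the aligned mean onto the prediction.  The
*registered mean shape* — not the prediction — is the output, so holes and
stray fragments of the prediction cannot survive: the result is a smooth
deformation of the statistical mean.  Per-label outputs are recomposed into
one label volume; contested voxels go to the label with the highest
pre-threshold soft value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .registration import (apply_displacement, apply_rigid,
                           deformable_register, icp_candidates)
from .ssm import ShapeModel
from .volumes import (BinaryMask, LabelVolume, ball_structuring_element,
                      cleanup_3d, extract_label_mask, recompose_labels,
                      remove_small_components, surface_voxels)

logger = logging.getLogger(__name__)


class ModelBankError(KeyError):
    """A requested label has no shape model in the bank."""


@dataclass
class MSModelBank:
    """Per-label shape models and mean masks, with build provenance."""

    mean_masks: dict[int, BinaryMask]
    models: dict[int, ShapeModel] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, m in self.mean_masks.items():
            if m.is_empty():
                raise ValueError(f"mean mask for label {label} is empty")

    def labels(self) -> list[int]:
        return sorted(self.mean_masks)


def ms_postprocess_label(pred_mask: BinaryMask, mean_mask: BinaryMask,
                         ns: float = 5.0, lam: float | str = 10.0,
                         cleanup_radius: int = 1, close_radius: int = 3,
                         drop_satellites: bool = False,
                         max_iter: int = 100, return_soft: bool = False):
    """Warp one label's mean shape onto its predicted mask.

    The rough cleanup is opening (removes thin noise) followed by closing
    plus hole filling (bridges blank-region invaginations so the
    registration target is not dominated by them); ``drop_satellites``
    optionally removes components much smaller than the main body, but is
    off by default because blank regions can sever a genuine muscle into
    comparable fragments that must be kept.

    Returns the registered mean mask; with ``return_soft=True`` also the
    pre-threshold soft image used for multi-label recomposition, and the
    registration diagnostics.  An empty (post-cleanup) prediction yields an
    empty output: ICP has no target to align to.
    """
    cleaned = cleanup_3d(pred_mask, radius=cleanup_radius)
    if drop_satellites:
        cleaned = remove_small_components(cleaned)
    if close_radius and not cleaned.is_empty():
        closed = ndimage.binary_fill_holes(ndimage.binary_closing(
            cleaned.grid, structure=ball_structuring_element(close_radius)))
        cleaned = BinaryMask(closed, cleaned.spacing, cleaned.origin)
    if cleaned.is_empty():
        logger.warning("prediction empty after cleanup; label skipped")
        empty = BinaryMask(np.zeros(pred_mask.shape, dtype=bool),
                           pred_mask.spacing, pred_mask.origin)
        if return_soft:
            return empty, np.zeros(pred_mask.shape), None
        return empty
    # rigid pose: run ICP from every coarse start, but pick the pose by
    # volumetric overlap with the cleaned prediction rather than cloud
    # RMS — blank regions and boundary jitter corrupt the surface cloud
    # and can make ICP converge to an axially slid or flipped pose that
    # scores well on RMS yet misplaces the muscle body
    cands = icp_candidates(moving=surface_voxels(mean_mask),
                           fixed=surface_voxels(cleaned))
    aligned_mean = None
    best_overlap = -1.0
    for rigid, _ in cands:
        cand_mask = apply_rigid(mean_mask, rigid, target=cleaned)
        overlap = int((cand_mask.grid & cleaned.grid).sum())
        if overlap > best_overlap:
            best_overlap = overlap
            aligned_mean = cand_mask
    if aligned_mean.is_empty():
        logger.warning("mean shape left the field of view after ICP")
        empty = BinaryMask(np.zeros(pred_mask.shape, dtype=bool),
                           pred_mask.spacing, pred_mask.origin)
        if return_soft:
            return empty, np.zeros(pred_mask.shape), None
        return empty
    reg = deformable_register(fixed=cleaned, moving=aligned_mean, ns=ns,
                              lam=lam, max_iter=max_iter)
    warped, soft = apply_displacement(aligned_mean, reg.field,
                                      return_soft=True)
    # thresholding the warped image can pinch off sub-voxel specks at thin
    # tips; the output is a deformation of one connected shape, so drop them
    warped = remove_small_components(warped, min_fraction=0.01)
    if return_soft:
        return warped, soft, reg
    return warped


def ms_postprocess_volume(pred: LabelVolume, bank: MSModelBank,
                          ns: float = 5.0, lam: float | str = 10.0,
                          cleanup_radius: int = 1, close_radius: int = 3,
                          max_iter: int = 100,
                          labels: list[int] | None = None) -> LabelVolume:
    """Mean-shape post-processing of every label of a predicted volume.

    Labels are processed in ascending id order; the per-label warped means
    are recomposed with soft-value overlap resolution (ties to the lowest
    label id).  Every label present in the prediction (or in the requested
    subset) must have a model in the bank.
    """
    if labels is None:
        labels = pred.labels()
    missing = [l for l in labels if l not in bank.mean_masks]
    if missing:
        raise ModelBankError(f"no shape model for labels {missing}")
    masks: dict[int, BinaryMask] = {}
    soft: dict[int, np.ndarray] = {}
    for label in sorted(labels):
        pred_mask = extract_label_mask(pred, label)
        warped, soft_img, reg = ms_postprocess_label(
            pred_mask, bank.mean_masks[label], ns=ns, lam=lam,
            cleanup_radius=cleanup_radius, close_radius=close_radius,
            max_iter=max_iter, return_soft=True)
        if reg is not None:
            logger.info("label %d: lambda=%g cost=%g min|J|=%g", label,
                        reg.lam, reg.final_cost, reg.min_jacobian)
        masks[label] = warped
        soft[label] = soft_img
    return recompose_labels(masks, soft=soft, shape=pred.shape,
                            spacing=pred.spacing, origin=pred.origin)
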