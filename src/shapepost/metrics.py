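"""Segmentation evaluation metrics and paired nonparametric testing.

Four standard metrics: Dice similarity coefficient (DSC), relative volume
error (RVE), Hausdorff distance (HD) and average symmetric surface distance
(ASSD).  Surface distances are Euclidean distances in mm between surface
voxel centres, honouring anisotropic spacing.  A Wilcoxon signed-rank test
(exact for small samples, normal approximation with tie and continuity
correction otherwise) supports paired method comparisons at the
conventional significance level alpha = 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .volumes import (BinaryMask, EmptyMaskError, GeometryError, LabelVolume,
                      surface_voxels)


class DegenerateSampleError(ValueError):
    """Raised when a paired sample has no non-zero differences."""


def _check_congruent(ref: BinaryMask, pred: BinaryMask) -> None:
    if ref.shape != pred.shape or not np.allclose(ref.spacing, pred.spacing):
        raise GeometryError("masks must share grid shape and spacing")


def dsc(ref: BinaryMask, pred: BinaryMask) -> float:
    """Dice similarity coefficient 2|R∩P| / (|R|+|P|), in [0, 1].

    Two empty masks are defined as perfectly similar (1.0).
    """
    _check_congruent(ref, pred)
    nr = int(ref.grid.sum())
    np_ = int(pred.grid.sum())
    if nr + np_ == 0:
        return 1.0
    inter = int((ref.grid & pred.grid).sum())
    return 2.0 * inter / (nr + np_)


def rve(ref: BinaryMask, pred: BinaryMask) -> float:
    """Signed relative volume error (V_pred - V_ref) / V_ref."""
    _check_congruent(ref, pred)
    v_ref = ref.volume_mm3()
    if v_ref == 0:
        raise EmptyMaskError("relative volume error needs a non-empty reference")
    return (pred.volume_mm3() - v_ref) / v_ref


def _surface_points(mask: BinaryMask) -> np.ndarray:
    return surface_voxels(mask).points


def hausdorff(ref: BinaryMask, pred: BinaryMask) -> float:
    """Symmetric Hausdorff distance between surface voxel centres, in mm."""
    _check_congruent(ref, pred)
    r = _surface_points(ref)
    p = _surface_points(pred)
    d_rp = cKDTree(p).query(r)[0]
    d_pr = cKDTree(r).query(p)[0]
    return float(max(d_rp.max(), d_pr.max()))


def assd(ref: BinaryMask, pred: BinaryMask) -> float:
    """Average symmetric surface distance in mm.

    Mean of all boundary-to-nearest-boundary distances taken in both
    directions, weighted by surface voxel counts.
    """
    _check_congruent(ref, pred)
    r = _surface_points(ref)
    p = _surface_points(pred)
    d_rp = cKDTree(p).query(r)[0]
    d_pr = cKDTree(r).query(p)[0]
    return float((d_rp.sum() + d_pr.sum()) / (len(r) + len(p)))


@dataclass
class MetricsReport:
    """Per-label and pooled metrics for one reference/prediction pair."""

    per_label: dict[int, dict[str, float]] = field(default_factory=dict)
    pooled: dict[str, float] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skipped_labels: list[int] = field(default_factory=list)
    degenerate_labels: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": lab, **vals} for lab, vals in sorted(self.per_label.items())]
        if self.pooled:
            rows.append({"label": "pooled", **self.pooled})
        return pd.DataFrame(rows)


def pooled_metrics(ref: LabelVolume, pred: LabelVolume,
                   labels: list[int] | None = None,
                   include_pooled_hd: bool = False) -> MetricsReport:
    """Per-label DSC/RVE/HD/ASSD plus pooled (all-labels-union) metrics.

    Pooled HD is omitted by default: on the union of all muscles the
    worst-case surface distance no longer reflects per-muscle local error.
    Labels absent from the reference are skipped with a warning.
    """
    if ref.shape != pred.shape or not np.allclose(ref.spacing, pred.spacing):
        raise GeometryError("volumes must share grid shape and spacing")
    if labels is None:
        labels = ref.labels()
    report = MetricsReport(spacing=ref.spacing)
    used = []
    for lab in labels:
        r = BinaryMask(ref.grid == lab, ref.spacing, ref.origin)
        if r.is_empty():
            warnings.warn(f"label {lab} absent from reference; skipped")
            report.skipped_labels.append(lab)
            continue
        used.append(lab)
        p = BinaryMask(pred.grid == lab, pred.spacing, pred.origin)
        entry = {"dsc": dsc(r, p), "rve": rve(r, p)}
        if p.is_empty():
            entry["hd"] = np.nan
            entry["assd"] = np.nan
            report.degenerate_labels.append(lab)
        else:
            entry["hd"] = hausdorff(r, p)
            entry["assd"] = assd(r, p)
        report.per_label[lab] = entry
    if used:
        r = BinaryMask(np.isin(ref.grid, used), ref.spacing, ref.origin)
        p = BinaryMask(np.isin(pred.grid, used), pred.spacing, pred.origin)
        report.pooled = {"dsc": dsc(r, p), "rve": rve(r, p)}
        if not p.is_empty():
            report.pooled["assd"] = assd(r, p)
            if include_pooled_hd:
                report.pooled["hd"] = hausdorff(r, p)
    return report


def wilcoxon_signed_rank(a, b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  For n <= exact_max_n the
    p-value is exact, by enumeration of all 2^n sign assignments of the
    (possibly tied, midranked) absolute differences; otherwise a normal
    approximation with tie correction and continuity correction is used.

    Returns (W, p) where W is the sum of ranks of positive differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        totals = np.array([sum(r for r, s in zip(ranks, signs) if s)
                           for signs in itertools.product((False, True), repeat=n)])
        p_le = np.mean(totals <= w + 1e-12)
        p_ge = np.mean(totals >= w - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts ** 3 - tie_counts) / 48.0
        from scipy.stats import norm
        z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w, float(p)
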