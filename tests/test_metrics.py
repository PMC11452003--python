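"""Evaluation metrics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from shapepost.metrics import (DegenerateSampleError, assd, dsc, hausdorff,
                               pooled_metrics, rve, wilcoxon_signed_rank)
from shapepost.volumes import BinaryMask, EmptyMaskError, GeometryError, LabelVolume
from .conftest import ball_mask


# ---------------------------------------------------------------- oracles

def _oracle_surface(grid: np.ndarray) -> np.ndarray:
    """Surface voxels by explicit 6-neighbour enumeration."""
    pts = []
    nx, ny, nz = grid.shape
    for i, j, k in np.argwhere(grid):
        on_surface = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                on_surface = True
                break
            if not grid[ii, jj, kk]:
                on_surface = True
                break
        if on_surface:
            pts.append((i, j, k))
    return np.asarray(pts, dtype=float)


def _oracle_metrics(a: np.ndarray, b: np.ndarray, spacing) -> dict:
    """Direct set arithmetic + exhaustive pair distances."""
    sp = np.asarray(spacing)
    na, nb = a.sum(), b.sum()
    inter = (a & b).sum()
    sa = _oracle_surface(a) * sp
    sb = _oracle_surface(b) * sp
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return {
        "dsc": 2.0 * inter / (na + nb),
        "rve": (nb - na) / na,
        "hd": max(d_ab.max(), d_ba.max()),
        "assd": (d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)),
    }


def _random_pair(rng, shape=(16, 16, 16)):
    """Random blobby mask pair guaranteed non-empty."""
    while True:
        a = rng.random(shape) < 0.5
        b = rng.random(shape) < 0.5
        from scipy import ndimage
        a = ndimage.binary_closing(a)
        b = ndimage.binary_closing(b)
        if a.any() and b.any():
            return a, b


# ------------------------------------------------------------------ tests

class TestMetricValues:
    def test_identical_masks(self, sphere8):
        assert dsc(sphere8, sphere8) == 1.0
        assert rve(sphere8, sphere8) == 0.0
        assert hausdorff(sphere8, sphere8) == 0.0
        assert assd(sphere8, sphere8) == 0.0

    def test_disjoint_masks_zero_dice(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[6, 6, 6] = True
        assert dsc(BinaryMask(a), BinaryMask(b)) == 0.0

    def test_half_overlap_dice(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0, 0, :4] = True            # |R| = 4
        b[0, 0, 2:6] = True           # |P| = 4, overlap 2
        assert dsc(BinaryMask(a), BinaryMask(b)) == 0.5

    def test_rve_sign_and_magnitude(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[:110] = True
        assert rve(BinaryMask(a), BinaryMask(b)) == pytest.approx(0.10)
        shrunk = BinaryMask(a.copy())
        shrunk.grid.ravel()[:50] = False
        assert rve(BinaryMask(a), shrunk) < 0

    def test_offset_cubes_hausdorff(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[1, 1, 1] = True
        b[8, 1, 1] = True
        assert hausdorff(BinaryMask(a), BinaryMask(b)) == pytest.approx(7.0)

    def test_single_voxel_assd(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2, 2, 2] = True
        b[2, 2, 7] = True
        assert assd(BinaryMask(a), BinaryMask(b)) == pytest.approx(5.0)

    def test_both_empty_dice_defined(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool))
        assert dsc(e, e) == 1.0

    def test_empty_reference_rve_raises(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool))
        with pytest.raises(EmptyMaskError):
            rve(e, e)

    def test_grid_mismatch_raises(self, sphere8):
        other = BinaryMask(np.ones((4, 4, 4), bool))
        with pytest.raises(GeometryError):
            dsc(sphere8, other)


class TestMetricOracle:
    @pytest.mark.parametrize("spacing", [(1, 1, 1), (0.8, 0.8, 2.4)])
    def test_brute_force_agreement(self, rng, spacing):
        for _ in range(25):
            a, b = _random_pair(rng)
            ma = BinaryMask(a, spacing=spacing)
            mb = BinaryMask(b, spacing=spacing)
            ref = _oracle_metrics(a, b, spacing)
            assert dsc(ma, mb) == pytest.approx(ref["dsc"], abs=1e-9)
            assert rve(ma, mb) == pytest.approx(ref["rve"], abs=1e-9)
            assert hausdorff(ma, mb) == pytest.approx(ref["hd"], abs=1e-9)
            assert assd(ma, mb) == pytest.approx(ref["assd"], abs=1e-9)

    def test_translation_invariance(self, rng):
        a, b = _random_pair(rng, shape=(12, 12, 12))
        pa = BinaryMask(np.pad(a, ((2, 0), (0, 2), (1, 1))))
        pb = BinaryMask(np.pad(b, ((2, 0), (0, 2), (1, 1))))
        qa = BinaryMask(np.pad(a, ((0, 2), (2, 0), (1, 1))))
        qb = BinaryMask(np.pad(b, ((0, 2), (2, 0), (1, 1))))
        assert dsc(pa, pb) == pytest.approx(dsc(qa, qb))
        assert hausdorff(pa, pb) == pytest.approx(hausdorff(qa, qb))

    def test_spacing_scales_distances_not_dice(self, rng):
        a, b = _random_pair(rng)
        m1a, m1b = BinaryMask(a), BinaryMask(b)
        m2a = BinaryMask(a, spacing=(2, 2, 2))
        m2b = BinaryMask(b, spacing=(2, 2, 2))
        assert dsc(m1a, m1b) == dsc(m2a, m2b)
        assert hausdorff(m2a, m2b) == pytest.approx(2 * hausdorff(m1a, m1b))
        assert assd(m2a, m2b) == pytest.approx(2 * assd(m1a, m1b))

    def test_assd_bounded_by_hausdorff(self, rng):
        for _ in range(20):
            a, b = _random_pair(rng)
            assert assd(BinaryMask(a), BinaryMask(b)) <= \
                hausdorff(BinaryMask(a), BinaryMask(b)) + 1e-12


class TestPooledMetrics:
    def _two_label(self):
        grid = np.zeros((16, 16, 16), np.int16)
        grid[2:6, 2:6, 2:6] = 1
        grid[9:13, 9:13, 9:13] = 2
        return LabelVolume(grid)

    def test_perfect_prediction(self):
        vol = self._two_label()
        report = pooled_metrics(vol, vol)
        for vals in report.per_label.values():
            assert vals["dsc"] == 1.0
            assert vals["hd"] == 0.0
        assert report.pooled["dsc"] == 1.0
        assert "hd" not in report.pooled

    def test_pooled_between_per_label_extremes(self):
        ref = self._two_label()
        pred_grid = ref.grid.copy()
        pred_grid[pred_grid == 2] = 0          # label 2 entirely missed
        pred = LabelVolume(pred_grid)
        report = pooled_metrics(ref, pred)
        d1 = report.per_label[1]["dsc"]
        d2 = report.per_label[2]["dsc"]
        assert min(d1, d2) < report.pooled["dsc"] < max(d1, d2)

    def test_label_order_independent(self):
        ref = self._two_label()
        pred = LabelVolume(np.roll(ref.grid, 1, axis=0))
        a = pooled_metrics(ref, pred, labels=[1, 2])
        b = pooled_metrics(ref, pred, labels=[2, 1])
        assert a.per_label == b.per_label
        assert a.pooled == b.pooled

    def test_absent_reference_label_skipped(self):
        ref = self._two_label()
        with pytest.warns(UserWarning):
            report = pooled_metrics(ref, ref, labels=[1, 2, 9])
        assert report.skipped_labels == [9]


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        b = np.array([1.0, 2.0, 3.0, 3.5, 4.0])
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(0.0625)    # 2 * 1/32

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_two_sided_symmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p_ab = wilcoxon_signed_rank(a, b)
        _, p_ba = wilcoxon_signed_rank(b, a)
        assert p_ab == pytest.approx(p_ba)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_scipy_exact(self, rng, n):
        for _ in range(5):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            w, p = wilcoxon_signed_rank(a, b)
            res = scipy_wilcoxon(a, b, method="exact",
                                 alternative="two-sided")
            assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_full_enumeration_oracle(self, rng):
        # independent oracle: enumerate all sign patterns from scratch
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        d = a - b
        d = d[d != 0]
        from scipy.stats import rankdata
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        dist = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([0, 1], repeat=len(d))]
        dist = np.asarray(dist, dtype=float)
        p_expect = min(1.0, 2 * min((dist <= w_obs).mean(),
                                    (dist >= w_obs).mean()))
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(p_expect, abs=1e-12)

    def test_large_sample_normal_approx_close_to_scipy(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=0.3, size=40)
        _, p = wilcoxon_signed_rank(a, b)
        res = scipy_wilcoxon(a, b, method="approx", correction=True,
                             alternative="two-sided")
        assert p == pytest.approx(res.pvalue, rel=0.05)
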