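"""Overlap metrics, contour distances, and the paired t-test, checked against
hand-computed examples and independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from ratunet.io_preprocess import BinaryMask
from ratunet.metrics import (ContourPointSet, average_hausdorff, confusion_counts,
                             dice, evaluate_pair, extract_contour, hausdorff,
                             paired_t_test, sensibility, sensitivity)

from conftest import (oracle_confusion, oracle_contour_points, oracle_dice,
                      oracle_hausdorff, oracle_sensibility, oracle_sensitivity,
                      random_mask_pair)

SP2 = np.array([[[1, 1], [0, 0]]], dtype=np.uint8)
GT2 = np.array([[[1, 0], [1, 0]]], dtype=np.uint8)


def _mask_from_counts(tp, fp, fn, tn=0):
    """Build a 1-D pair of masks realizing given confusion counts."""
    n = tp + fp + fn + tn
    sp = np.zeros((1, 1, n), dtype=np.uint8)
    gt = np.zeros((1, 1, n), dtype=np.uint8)
    sp[0, 0, :tp + fp] = 1
    gt[0, 0, :tp] = 1
    gt[0, 0, tp + fp:tp + fp + fn] = 1
    return sp, gt


class TestOverlapMetrics:
    def test_confusion_2x2_example(self):
        c = confusion_counts(SP2, GT2)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_confusion_identity(self, rng):
        m = (rng.random((2, 16, 16)) > 0.6).astype(np.uint8)
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn) == (int(m.sum()), 0, 0)

    def test_confusion_empty_prediction(self, rng):
        gt = (rng.random((2, 16, 16)) > 0.6).astype(np.uint8)
        c = confusion_counts(np.zeros_like(gt), gt)
        assert (c.tp, c.fp, c.fn) == (0, 0, int(gt.sum()))

    def test_dice_plugin_example(self):
        sp, gt = _mask_from_counts(tp=8, fp=4, fn=2)
        assert dice(sp, gt) == pytest.approx(16 / 22, abs=1e-15)

    def test_dice_limits(self, rng):
        m = (rng.random((2, 16, 16)) > 0.5).astype(np.uint8)
        assert dice(m, m) == 1.0
        a = np.zeros((1, 1, 4), dtype=np.uint8)
        b = np.zeros((1, 1, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[0, 0, 2] = 1
        assert dice(a, b) == 0.0
        assert dice(np.zeros((1, 2, 2)), np.zeros((1, 2, 2))) == 1.0  # both empty

    def test_sensitivity(self):
        sp, gt = _mask_from_counts(tp=8, fp=0, fn=2)
        assert sensitivity(sp, gt) == pytest.approx(0.8, abs=1e-15)
        with pytest.raises(ValueError):
            sensitivity(sp, np.zeros_like(gt))

    def test_sensibility_unclamped(self):
        sp, gt = _mask_from_counts(tp=8, fp=4, fn=2)
        assert sensibility(sp, gt) == pytest.approx(0.6, abs=1e-15)
        sp, gt = _mask_from_counts(tp=1, fp=3, fn=0)
        assert sensibility(sp, gt) == pytest.approx(-2.0, abs=1e-15)
        sp, gt = _mask_from_counts(tp=5, fp=0, fn=1)
        assert sensibility(sp, gt) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))

    def test_dice_symmetric_sensitivity_not(self):
        sp, gt = _mask_from_counts(tp=3, fp=5, fn=1)
        assert dice(sp, gt) == dice(gt, sp)
        assert sensitivity(sp, gt) != sensitivity(gt, sp)
        assert sensibility(sp, gt) != sensibility(gt, sp)


class TestContours:
    def test_single_voxel(self):
        m = np.zeros((1, 16, 16), dtype=np.uint8)
        m[0, 5, 5] = 1
        pts = extract_contour(BinaryMask(m, (1.0, 0.2, 0.2))).points
        assert pts.shape == (1, 3)
        assert pts[0] == pytest.approx([0.0, 1.0, 1.0])

    def test_filled_square_excludes_center(self):
        m = np.zeros((1, 8, 8), dtype=np.uint8)
        m[0, 2:5, 2:5] = 1
        pts = extract_contour(m, spacing_mm=(1.0, 1.0, 1.0)).points
        assert len(pts) == 8
        assert [0.0, 3.0, 3.0] not in pts.tolist()

    def test_thin_line_all_boundary(self):
        m = np.zeros((1, 8, 8), dtype=np.uint8)
        m[0, 3, 1:7] = 1
        pts = extract_contour(m, spacing_mm=(1.0, 1.0, 1.0)).points
        assert len(pts) == 6

    def test_image_edge_is_boundary(self):
        m = np.ones((1, 4, 4), dtype=np.uint8)
        pts = extract_contour(m, spacing_mm=(1.0, 1.0, 1.0)).points
        assert len(pts) == 12  # all but the 2x2 interior

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((1, 4, 4)), spacing_mm=(1.0, 1.0, 1.0))


class TestHausdorff:
    def test_3_4_5_triangle(self):
        a = ContourPointSet(np.array([[0.0, 0.0, 0.0]]))
        b = ContourPointSet(np.array([[0.0, 3.0, 4.0]]))
        assert hausdorff(a, b) == pytest.approx(5.0, abs=1e-12)

    def test_identity_and_asymmetric_sets(self):
        a = ContourPointSet(np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        b = ContourPointSet(np.array([[0.0, 0.0, 0.0]]))
        assert hausdorff(a, a) == 0.0
        assert hausdorff(a, b) == pytest.approx(1.0, abs=1e-12)
        assert average_hausdorff(a, b) == pytest.approx(0.25, abs=1e-12)
        assert average_hausdorff(a, a) == 0.0

    def test_symmetry(self, rng):
        a = ContourPointSet(rng.random((20, 3)))
        b = ContourPointSet(rng.random((30, 3)))
        assert hausdorff(a, b) == hausdorff(b, a)
        assert average_hausdorff(a, b) == average_hausdorff(b, a)

    def test_average_bounded_by_max(self, rng):
        for _ in range(100):
            a = ContourPointSet(rng.random((rng.integers(1, 15), 3)))
            b = ContourPointSet(rng.random((rng.integers(1, 15), 3)))
            assert average_hausdorff(a, b) <= hausdorff(a, b) + 1e-15

    def test_empty_rejected(self):
        a = ContourPointSet(np.zeros((0, 3)))
        b = ContourPointSet(np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError):
            hausdorff(a, b)
        with pytest.raises(ValueError):
            average_hausdorff(b, a)


class TestOracleAgreement:
    def test_overlap_and_distance_oracle(self, rng):
        """Vectorized metrics agree with explicit-loop / O(n*m) oracles."""
        for _ in range(30):
            sp, gt = random_mask_pair(rng)
            c = confusion_counts(sp, gt)
            assert (c.tp, c.fp, c.fn, c.tn) == oracle_confusion(sp.voxels, gt.voxels)
            assert dice(sp, gt) == pytest.approx(oracle_dice(sp.voxels, gt.voxels),
                                                 abs=1e-12)
            assert sensitivity(sp, gt) == pytest.approx(
                oracle_sensitivity(sp.voxels, gt.voxels), abs=1e-12)
            assert sensibility(sp, gt) == pytest.approx(
                oracle_sensibility(sp.voxels, gt.voxels), abs=1e-12)
            sa, ga = extract_contour(sp), extract_contour(gt)
            opts_s = oracle_contour_points(sp.voxels, sp.spacing_mm)
            assert sorted(map(tuple, sa.points)) == sorted(map(tuple, opts_s))
            oh, oah = oracle_hausdorff(sa.points, ga.points)
            assert hausdorff(sa, ga) == pytest.approx(oh, abs=1e-12)
            assert average_hausdorff(sa, ga) == pytest.approx(oah, abs=1e-12)


class TestEvaluatePair:
    def test_identical_masks(self, small_phantom):
        _, gt = small_phantom
        r = evaluate_pair(gt, gt)
        assert (r.dice, r.sensitivity, r.sensibility) == (1.0, 1.0, 1.0)
        assert (r.hausdorff_mm, r.avg_hausdorff_mm) == (0.0, 0.0)

    def test_2x2_example(self):
        sp = BinaryMask(SP2, (1.0, 1.0, 1.0))
        gt = BinaryMask(GT2, (1.0, 1.0, 1.0))
        r = evaluate_pair(sp, gt)
        assert r.dice == pytest.approx(0.5)
        assert r.sensitivity == pytest.approx(0.5)
        assert r.sensibility == pytest.approx(0.5)

    def test_consistent_with_individual_ops(self, rng):
        for _ in range(20):
            sp, gt = random_mask_pair(rng)
            r = evaluate_pair(sp, gt)
            assert r.dice == dice(sp, gt)
            assert r.sensitivity == sensitivity(sp, gt)
            assert r.sensibility == sensibility(sp, gt)
            sa, ga = extract_contour(sp), extract_contour(gt)
            assert r.hausdorff_mm == hausdorff(sa, ga)
            assert r.avg_hausdorff_mm == average_hausdorff(sa, ga)
            assert r.hausdorff_mm >= r.avg_hausdorff_mm >= 0.0


class TestPairedT:
    def test_known_example(self):
        # a-b differences {1,1,2}: t = 4, df = 2
        t, p = paired_t_test([1.0, 2.0, 4.0], [0.0, 1.0, 2.0])
        assert t == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.0572, abs=5e-4)
        t_ref, p_ref = sps.ttest_rel([1.0, 2.0, 4.0], [0.0, 1.0, 2.0])
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0])  # all differences zero
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])  # constant shift
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.5])
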