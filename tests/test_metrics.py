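"""Evaluation metrics against brute-force set-arithmetic and distance oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from canalnet import (BinaryMask, ConfusionCounts, centerline, confusion,
                      evaluate_pair, mean_curve_distance, overlap_metrics,
                      slice_profiles, volume_metrics)


def random_mask_pair(rng, shape=(6, 6, 6), density=0.2):
    pred = rng.random(shape) < density
    truth = rng.random(shape) < density
    return pred, truth


def oracle_metrics(pred, truth):
    """Set-arithmetic reference for all six overlap/volume metrics."""
    P = {tuple(i) for i in np.argwhere(pred)}
    T = {tuple(i) for i in np.argwhere(truth)}
    tp, fp, fn = len(P & T), len(P - T), len(T - P)
    if not P and not T:
        return dict(dsc=1, ji=1, pr=1, rc=1, voe=0, rvd=0)
    dsc = 2 * tp / (2 * tp + fn + fp)
    ji = tp / (tp + fn + fp)
    pr = tp / (tp + fp) if P else 0.0
    rc = tp / (tp + fn) if T else 0.0
    voe = 1 - len(P & T) / len(P | T)
    rvd = abs(len(T) - len(P)) / len(T) if T else np.nan
    return dict(dsc=dsc, ji=ji, pr=pr, rc=rc, voe=voe, rvd=rvd)


class TestConfusionAndOverlap:
    def test_identity_counts(self):
        m = np.arange(27).reshape(3, 3, 3) < 7  # 7 voxels
        c = confusion(m, m)
        assert (c.tp, c.fp, c.fn) == (7, 0, 0)

    def test_set_enumeration_example(self):
        truth = np.zeros((2, 2, 2), bool)
        pred = np.zeros((2, 2, 2), bool)
        for v in [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)]:
            truth[v] = True  # {a,b,c,d}
        for v in [(0, 0, 0), (0, 0, 1), (1, 0, 0)]:
            pred[v] = True  # {a,b,e}
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn) == (2, 1, 2)
        dsc, ji, pr, rc = overlap_metrics(c)
        assert dsc == pytest.approx(4 / 7)
        assert ji == pytest.approx(2 / 5)
        assert pr == pytest.approx(2 / 3)
        assert rc == pytest.approx(1 / 2)

    def test_empty_vs_empty_identity_convention(self):
        c = confusion(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 2), bool))
        assert (c.tp, c.fp, c.fn) == (0, 0, 0)
        assert overlap_metrics(c) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_all_zero(self):
        assert overlap_metrics(ConfusionCounts(0, 3, 4)) == (0.0, 0.0, 0.0, 0.0)

    def test_volume_metrics_hand_example(self):
        truth = np.zeros((1, 1, 5), bool)
        pred = np.zeros((1, 1, 5), bool)
        truth[0, 0, :4] = True
        pred[0, 0, 2:5] = True  # intersection {2,3}, union 5
        voe, rvd = volume_metrics(pred, truth)
        assert voe == pytest.approx(1 - 2 / 5)
        assert rvd == pytest.approx(0.25)

    def test_empty_prediction_extremes(self):
        truth = np.zeros((2, 2, 2), bool)
        truth[0, 0, 0] = True
        voe, rvd = volume_metrics(np.zeros_like(truth), truth)
        assert (voe, rvd) == (1.0, 1.0)
        with pytest.raises(ValueError):
            volume_metrics(truth, np.zeros_like(truth))

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            pred, truth = random_mask_pair(rng)
            if not truth.any():
                continue
            ref = oracle_metrics(pred, truth)
            c = confusion(pred, truth)
            dsc, ji, pr, rc = overlap_metrics(c)
            voe, rvd = volume_metrics(pred, truth)
            for got, want in zip((dsc, ji, pr, rc, voe, rvd),
                                 (ref["dsc"], ref["ji"], ref["pr"], ref["rc"],
                                  ref["voe"], ref["rvd"])):
                assert got == pytest.approx(want, abs=1e-12)
            # algebraic identities of the formulas
            assert dsc == pytest.approx(2 * ji / (1 + ji), abs=1e-12)
            assert voe == pytest.approx(1 - ji, abs=1e-12)

    def test_dsc_symmetric_mcd_not(self, rng):
        pred = np.zeros((8, 5, 5), bool)
        truth = np.zeros((8, 5, 5), bool)
        truth[1:7, 2, 2] = True
        pred[1:4, 2, 3] = True
        c1, c2 = confusion(pred, truth), confusion(truth, pred)
        assert overlap_metrics(c1)[0] == overlap_metrics(c2)[0]
        a = mean_curve_distance(BinaryMask(truth, 1.0), BinaryMask(pred, 1.0))
        b = mean_curve_distance(BinaryMask(pred, 1.0), BinaryMask(truth, 1.0))
        assert a != b

    def test_metrics_invariant_under_mirroring(self, rng):
        pred, truth = random_mask_pair(rng, density=0.3)
        truth[2, 2, 2] = True
        r1 = (overlap_metrics(confusion(pred, truth)),
              volume_metrics(pred, truth))
        r2 = (overlap_metrics(confusion(pred[:, :, ::-1], truth[:, :, ::-1])),
              volume_metrics(pred[:, :, ::-1], truth[:, :, ::-1]))
        assert r1 == r2


class TestCenterline:
    def test_thin_line_is_its_own_skeleton(self):
        m = np.zeros((10, 7, 7), bool)
        m[:, 3, 3] = True
        curve = centerline(BinaryMask(m, 0.2))
        got = {tuple(p) for p in curve.points}
        assert got == {(z, 3, 3) for z in range(10)}

    def test_cylinder_skeleton_hugs_axis(self):
        z, r, c = np.mgrid[0:20, 0:9, 0:9]
        m = (r - 4) ** 2 + (c - 4) ** 2 <= 9  # radius-3 cylinder along axis 0
        curve = centerline(BinaryMask(m, 1.0))
        off_axis = np.linalg.norm(curve.points[:, 1:] - 4, axis=1)
        assert off_axis.max() <= np.sqrt(2) + 1e-9  # within one voxel of the axis

    def test_skeleton_inside_mask_and_nonempty(self, curved_phantom):
        _, mask = curved_phantom
        curve = centerline(mask)
        assert len(curve.points) > 0
        assert mask.values[tuple(curve.points.T)].all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            centerline(np.zeros((3, 3, 3), bool))


class TestMeanCurveDistance:
    def test_identical_masks_zero(self, curved_phantom):
        _, mask = curved_phantom
        assert mean_curve_distance(mask, mask) == 0.0

    def test_parallel_lines_one_voxel_apart(self):
        a = np.zeros((10, 5, 5), bool)
        b = np.zeros((10, 5, 5), bool)
        a[:, 2, 2] = True
        b[:, 2, 3] = True
        assert mean_curve_distance(BinaryMask(a, 0.2),
                                   BinaryMask(b, 0.2)) == pytest.approx(0.2)

    def test_truth_subset_of_longer_prediction_scores_zero(self):
        truth = np.zeros((12, 5, 5), bool)
        pred = np.zeros((12, 5, 5), bool)
        truth[4:8, 2, 2] = True
        pred[:, 2, 2] = True
        assert mean_curve_distance(BinaryMask(truth, 0.2),
                                   BinaryMask(pred, 0.2)) == 0.0

    def test_empty_prediction_is_infinite(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[:, 1, 1] = True
        assert mean_curve_distance(BinaryMask(truth, 0.2),
                                   np.zeros_like(truth)) == np.inf

    def test_matches_all_pairs_oracle(self, rng):
        from canalnet.metrics import centerline as skel
        for _ in range(20):
            pred, truth = random_mask_pair(rng, shape=(10, 10, 10), density=0.1)
            if not pred.any() or not truth.any():
                continue
            spacing = 0.2
            got = mean_curve_distance(BinaryMask(truth, spacing),
                                      BinaryMask(pred, spacing))
            tp = skel(BinaryMask(truth, spacing)).points * spacing
            pp = skel(BinaryMask(pred, spacing)).points * spacing
            want = cdist(tp, pp).min(axis=1).mean()
            assert got == pytest.approx(want, abs=1e-9)


class TestSliceProfiles:
    def test_identity_profile(self, curved_phantom):
        _, mask = curved_phantom
        z, dsc, mcd = slice_profiles(mask, mask)
        occupied = [i for i in range(mask.shape[0]) if mask.values[i].any()]
        assert list(z) == occupied
        np.testing.assert_allclose(dsc, 1.0)
        finite = np.isfinite(mcd) & ~np.isnan(mcd)
        np.testing.assert_allclose(mcd[finite], 0.0)

    def test_error_confined_to_corrupted_slices(self, curved_phantom):
        _, mask = curved_phantom
        pred = mask.values.copy()
        pred[6:10] = False  # mis-segmentation only in slices 6-9
        z, dsc, _ = slice_profiles(BinaryMask(pred, 0.2), mask)
        bad = (z >= 6) & (z < 10)
        assert (dsc[bad] == 0).all()
        np.testing.assert_allclose(dsc[~bad], 1.0)


class TestEvaluatePair:
    def test_report_consistency_on_phantom(self, curved_phantom):
        _, mask = curved_phantom
        noisy = mask.values.copy()
        noisy[3, 10, 10] = True  # one false positive
        rep = evaluate_pair(BinaryMask(noisy, 0.2), mask)
        assert 0 < rep.dsc < 1 or rep.dsc == pytest.approx(1, abs=1e-2)
        assert rep.voe == pytest.approx(1 - rep.ji, abs=1e-12)
        assert rep.dsc == pytest.approx(2 * rep.ji / (1 + rep.ji), abs=1e-12)
        assert rep.mcd_mm >= 0

    def test_probability_input_binarised_at_half(self, curved_phantom):
        _, mask = curved_phantom
        prob = np.where(mask.values, 0.9, 0.1)
        rep = evaluate_pair(prob, mask)
        assert rep.dsc == 1.0 and rep.voe == 0.0 and rep.mcd_mm == 0.0
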