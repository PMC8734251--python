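"""Per-region evaluation metrics against exhaustive oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from agsevnet.metrics import (
    ConfusionCounts,
    confusion,
    dice_score,
    evaluate_case,
    hausdorff95,
    reports_to_frame,
    sensitivity_score,
    specificity_score,
    surface_points,
)


def brute_force_confusion(pred, gt):
    tp = fp = fn = tn = 0
    for idx in np.ndindex(pred.shape):
        p, g = bool(pred[idx]), bool(gt[idx])
        tp += p and g
        fp += p and not g
        fn += (not p) and g
        tn += (not p) and (not g)
    return tp, fp, fn, tn


def brute_force_surface(mask):
    pts = []
    shape = mask.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for ax in range(3):
            for d in (-1, 1):
                nb = list(idx)
                nb[ax] += d
                if not (0 <= nb[ax] < shape[ax]) or not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return np.array(pts) if pts else np.empty((0, 3))


def brute_force_hd(pred, gt, spacing, percentile):
    sp = np.asarray(spacing, float)
    t = brute_force_surface(gt) * sp
    p = brute_force_surface(pred) * sp
    d = cdist(p, t)
    return max(np.percentile(d.min(axis=1), percentile),
               np.percentile(d.min(axis=0), percentile))


class TestConfusion:
    def test_all_ones(self):
        m = np.ones((2, 2, 2), dtype=bool)
        c = confusion(m, m)
        assert (c.TP, c.FP, c.FN, c.TN) == (8, 0, 0, 0)

    def test_complement_masks(self, rng):
        gt = rng.random((3, 3, 3)) > 0.5
        c = confusion(~gt, gt)
        assert c.TP == 0 and c.TN == 0
        assert c.FP + c.FN == gt.size

    def test_matches_brute_force_and_total(self, rng):
        for _ in range(5):
            pred = rng.random((6, 6, 6)) > 0.5
            gt = rng.random((6, 6, 6)) > 0.5
            c = confusion(pred, gt)
            assert (c.TP, c.FP, c.FN, c.TN) == brute_force_confusion(pred, gt)
            assert c.total == pred.size

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            confusion(np.ones((2, 2, 2)), np.ones((3, 3, 3)))


class TestScalarScores:
    def test_dice_arithmetic(self):
        assert dice_score(ConfusionCounts(3, 1, 1, 0)) == pytest.approx(0.75)

    def test_dice_identical_nonempty(self):
        assert dice_score(ConfusionCounts(5, 0, 0, 10)) == 1.0

    def test_dice_empty_prediction(self):
        assert dice_score(ConfusionCounts(0, 0, 7, 10)) == 0.0

    def test_dice_both_empty_convention(self):
        assert dice_score(ConfusionCounts(0, 0, 0, 8)) == 1.0

    def test_sensitivity(self):
        assert sensitivity_score(ConfusionCounts(9, 0, 1, 0)) == pytest.approx(0.9)

    def test_specificity(self):
        assert specificity_score(ConfusionCounts(0, 1, 0, 99)) == pytest.approx(0.99)

    def test_specificity_all_positive_reference_convention(self):
        assert specificity_score(ConfusionCounts(8, 0, 0, 0)) == 1.0

    def test_range(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 10, 4)
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            assert 0.0 <= dice_score(c) <= 1.0


class TestSurfaceAndHausdorff:
    def test_surface_matches_brute_force(self, rng):
        for _ in range(5):
            mask = rng.random((6, 6, 6)) > 0.6
            got = {tuple(p) for p in surface_points(mask)}
            expected = {tuple(p) for p in brute_force_surface(mask)}
            assert got == expected

    def test_identical_masks_zero(self, rng):
        mask = rng.random((6, 6, 6)) > 0.5
        mask[2, 2, 2] = True
        val, flag = hausdorff95(mask, mask)
        assert val == 0.0 and flag == ""

    def test_two_point_masks_distance(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[1, 1, 1] = True
        b[6, 1, 1] = True
        for pct in (50.0, 95.0, 100.0):
            val, _ = hausdorff95(a, b, percentile=pct)
            assert val == pytest.approx(5.0)

    @pytest.mark.parametrize("percentile", [80.0, 95.0, 100.0])
    def test_matches_all_pairs_oracle(self, rng, percentile):
        for _ in range(5):
            pred = rng.random((10, 10, 10)) > 0.7
            gt = rng.random((10, 10, 10)) > 0.7
            if not pred.any() or not gt.any():
                continue
            spacing = (1.0, 0.8, 1.2)
            val, _ = hausdorff95(pred, gt, spacing, percentile)
            assert val == pytest.approx(
                brute_force_hd(pred, gt, spacing, percentile), abs=1e-9)

    def test_percentile_monotone(self, rng):
        pred = rng.random((8, 8, 8)) > 0.7
        gt = rng.random((8, 8, 8)) > 0.7
        vals = [hausdorff95(pred, gt, percentile=p)[0]
                for p in (100.0, 95.0, 75.0, 50.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_symmetry(self, rng):
        pred = rng.random((8, 8, 8)) > 0.7
        gt = rng.random((8, 8, 8)) > 0.7
        assert hausdorff95(pred, gt)[0] == pytest.approx(
            hausdorff95(gt, pred)[0])

    def test_empty_mask_sentinel(self):
        gt = np.zeros((4, 4, 4), dtype=bool)
        gt[1, 1, 1] = True
        val, flag = hausdorff95(np.zeros((4, 4, 4), dtype=bool), gt)
        assert flag == "one_empty"
        assert val == pytest.approx(np.sqrt(3 * 16))

    def test_translation_invariance(self, rng):
        base_p = rng.random((5, 5, 5)) > 0.5
        base_g = rng.random((5, 5, 5)) > 0.5
        big_p = np.zeros((15, 15, 15), dtype=bool)
        big_g = np.zeros((15, 15, 15), dtype=bool)
        big_p[2:7, 2:7, 2:7] = base_p
        big_g[2:7, 2:7, 2:7] = base_g
        ref = hausdorff95(big_p, big_g)[0]
        shift_p = np.roll(big_p, (4, 3, 2), axis=(0, 1, 2))
        shift_g = np.roll(big_g, (4, 3, 2), axis=(0, 1, 2))
        assert hausdorff95(shift_p, shift_g)[0] == pytest.approx(ref)


class TestEvaluateCase:
    def test_perfect_prediction(self, small_phantom_case):
        rep = evaluate_case(small_phantom_case.labels,
                            small_phantom_case.labels)
        for region in ("ET", "TC", "WT"):
            assert rep.dice[region] == 1.0
            assert rep.sensitivity[region] == 1.0
            assert rep.specificity[region] == 1.0
            assert rep.hd95[region] == 0.0

    def test_dilated_prediction_hd_bound(self, small_phantom_case):
        from scipy import ndimage

        labels = small_phantom_case.labels
        dilated = labels.copy()
        wt = np.isin(labels, (1, 2, 4))
        grown = ndimage.binary_dilation(wt)
        dilated[grown & ~wt] = 2  # grow WT by one voxel of edema
        rep = evaluate_case(dilated, labels)
        assert rep.hd95["WT"] <= np.sqrt(3.0) + 1e-9

    def test_all_background_prediction(self, small_phantom_case):
        rep = evaluate_case(np.zeros_like(small_phantom_case.labels),
                            small_phantom_case.labels)
        for region in ("ET", "TC", "WT"):
            assert rep.dice[region] == 0.0

    def test_report_frame_layout(self, small_phantom_case):
        reps = [evaluate_case(small_phantom_case.labels,
                              small_phantom_case.labels, case_id=f"c{i}")
                for i in range(2)]
        frame = reports_to_frame(reps)
        # 2 cases x 3 regions + mean & median summaries x 3 regions
        assert len(frame) == 2 * 3 + 2 * 3
        assert set(frame.region) == {"ET", "TC", "WT"}
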