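"""Object-wise/pixel-wise mask comparison, SC and ThresholdFinder."""

import math

import numpy as np
import pytest

from fascx.evaluation import (
    SCInputs,
    evaluate_masks,
    render_eval_map,
    sc_inputs_from_report,
    similarity_coefficient,
    threshold_finder,
)
from fascx.images import BinaryMask, GrayImage


def mask_with(shape, *rects):
    arr = np.zeros(shape, dtype=bool)
    for r0, r1, c0, c1 in rects:
        arr[r0:r1, c0:c1] = True
    return BinaryMask(arr)


def random_mask(rng, shape=(60, 60), p=0.4):
    from scipy import ndimage

    noise = rng.random(shape) < p
    return BinaryMask(ndimage.binary_opening(noise, np.ones((2, 2), dtype=bool)))


class TestEvaluateMasks:
    def test_identical_masks_all_found(self):
        m = mask_with((40, 40), (5, 15, 5, 15), (25, 35, 25, 35))
        rep = evaluate_masks(m, m)
        assert len(rep.matches) == 2
        assert rep.truth_not_matched == [] and rep.eval_not_matched == []
        assert rep.pixel_counts["false_pos"] == 0 and rep.pixel_counts["false_neg"] == 0

    def test_disjoint_masks_all_missed_and_fp(self):
        t = mask_with((40, 40), (2, 8, 2, 8))
        e = mask_with((40, 40), (20, 30, 20, 30))
        rep = evaluate_masks(t, e)
        assert rep.matches == []
        assert rep.truth_not_matched == [1]
        assert rep.eval_not_matched == [1]

    def test_min_overlap_arithmetic(self):
        # 200-px objects overlapping by exactly 1 px at 1% -> 1 < 2 required
        t = mask_with((40, 60), (10, 20, 5, 25))  # 10x20 = 200 px
        e = mask_with((40, 60), (19, 29, 24, 44))  # 200 px, 1 px overlap at (19,24)
        assert int((t.pixels & e.pixels).sum()) == 1
        rep = evaluate_masks(t, e, min_overlap_pct=1.0)
        assert rep.matches == []
        rep2 = evaluate_masks(t, e, min_overlap_pct=0.5)  # 1 >= 1 required
        assert len(rep2.matches) == 1

    def test_multi_one_to_n_counter(self):
        t = mask_with((30, 30), (5, 25, 5, 25))
        e = mask_with((30, 30), (6, 12, 6, 12), (15, 22, 15, 22))
        rep = evaluate_masks(t, e)
        assert rep.multi_one_to_n == 1
        assert rep.multi_n_to_one == 0

    def test_multi_n_to_one_counter(self):
        t = mask_with((30, 30), (6, 12, 6, 12), (15, 22, 15, 22))
        e = mask_with((30, 30), (5, 25, 5, 25))
        rep = evaluate_masks(t, e)
        assert rep.multi_n_to_one == 1

    def test_thicken_merges_near_misses(self):
        t = mask_with((20, 20), (5, 10, 5, 10))
        e = mask_with((20, 20), (11, 16, 5, 10))  # 1 px apart, no overlap
        assert evaluate_masks(t, e).matches == []
        assert len(evaluate_masks(t, e, thicken_px=1).matches) == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_masks(mask_with((10, 10)), mask_with((12, 10)))

    def test_pixel_counts_partition_and_swap_symmetry(self, rng):
        for _ in range(20):
            t, e = random_mask(rng), random_mask(rng)
            rep = evaluate_masks(t, e)
            pc = rep.pixel_counts
            union = int((t.pixels | e.pixels).sum())
            assert pc["true_pos"] + pc["false_pos"] + pc["false_neg"] == union
            swapped = evaluate_masks(e, t).pixel_counts
            assert swapped["false_pos"] == pc["false_neg"]
            assert swapped["false_neg"] == pc["false_pos"]
            assert swapped["true_pos"] == pc["true_pos"]

    def test_lower_overlap_never_fewer_matches(self, rng):
        t, e = random_mask(rng), random_mask(rng)
        n_prev = -1
        for pct in (80.0, 40.0, 10.0, 1.0):
            n = len(evaluate_masks(t, e, min_overlap_pct=pct).matches)
            assert n >= n_prev
            n_prev = n

    def test_found_plus_missed_conserves_truth_area(self, rng):
        for _ in range(20):
            t, e = random_mask(rng), random_mask(rng)
            rep = evaluate_masks(t, e)
            inp = sc_inputs_from_report(rep)
            assert inp.found_area + inp.missed_area == t.foreground_px


class TestSimilarityCoefficient:
    def test_printed_formula_example(self):
        assert similarity_coefficient(SCInputs(120, 20, 10)) == pytest.approx(4.0)

    def test_zero_found_is_zero(self):
        assert similarity_coefficient(SCInputs(0, 50, 50)) == 0.0
        assert similarity_coefficient(SCInputs(0, 0, 0)) == 0.0

    def test_perfect_segmentation_is_inf(self):
        assert math.isinf(similarity_coefficient(SCInputs(100, 0, 0)))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            SCInputs(-1, 0, 0)

    def test_monotonicity(self, rng):
        for _ in range(20):
            f, m, fp = rng.uniform(1, 100, size=3)
            base = similarity_coefficient(SCInputs(f, m, fp))
            assert similarity_coefficient(SCInputs(f + 5, m, fp)) > base
            assert similarity_coefficient(SCInputs(f, m + 5, fp)) < base
            assert similarity_coefficient(SCInputs(f, m, fp + 5)) < base


class TestEvalMap:
    def test_identical_masks_all_blue(self):
        m = mask_with((30, 30), (5, 15, 5, 15))
        rep = evaluate_masks(m, m)
        rgb = render_eval_map(m, m, rep)
        blue = (rgb == (0, 0, 255)).all(axis=-1)
        assert blue.sum() == m.foreground_px
        assert not (rgb == (255, 0, 0)).all(axis=-1).any()

    def test_disjoint_masks_yellow_and_red(self):
        t = mask_with((30, 30), (2, 8, 2, 8))
        e = mask_with((30, 30), (20, 28, 20, 28))
        rep = evaluate_masks(t, e)
        rgb = render_eval_map(t, e, rep)
        assert (rgb == (255, 255, 0)).all(axis=-1).sum() == t.foreground_px
        assert (rgb == (255, 0, 0)).all(axis=-1).sum() == e.foreground_px

    def test_category_pixel_counts_match_report(self):
        t = mask_with((40, 40), (5, 15, 5, 15), (25, 35, 5, 15))
        e = mask_with((40, 40), (5, 15, 5, 15), (25, 35, 25, 35))  # 1 found, 1 fp
        rep = evaluate_masks(t, e)
        inp = sc_inputs_from_report(rep)
        rgb = render_eval_map(t, e, rep)
        assert (rgb == (0, 0, 255)).all(axis=-1).sum() == inp.found_area
        assert (rgb == (255, 255, 0)).all(axis=-1).sum() == inp.missed_area
        assert (rgb == (255, 0, 0)).all(axis=-1).sum() == inp.fp_area


class TestThresholdFinder:
    def test_exhaustive_scan_recovers_exact_level(self, rng):
        arr = (rng.random((50, 50)) * 255).astype(np.uint8)
        img = GrayImage(arr)
        mask = BinaryMask(arr > 100)
        table = threshold_finder([img], [mask], methods=("otsu", "mean"))
        assert int(table.loc[0, "best_level"]) == 100
        assert table.loc[0, "false_pos_rate"] == 0.0
        assert table.loc[0, "false_neg_rate"] == 0.0

    def test_all_false_mask_degenerate(self, rng):
        arr = (rng.random((30, 30)) * 255).astype(np.uint8)
        table = threshold_finder([GrayImage(arr)], [BinaryMask(np.zeros((30, 30), bool))],
                                 methods=("otsu",))
        assert table.loc[0, "found_rate"] == 0.0

    def test_method_matching_optimal_level_ranks_first(self, rng):
        arr = (rng.random((60, 60)) * 255).astype(np.uint8)
        img = GrayImage(arr)
        mean_level = int(round(arr.mean()))
        mask = BinaryMask(arr > mean_level)  # mask generated by the mean rule
        table = threshold_finder([img], [mask], methods=("otsu", "mean", "triangle"))
        assert table.loc[0, "method"] == "mean"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            threshold_finder([], [])
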