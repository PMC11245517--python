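"""IoU/Dice scoring, group aggregation, and SER/SD fairness arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairseg.metrics import (
    MaskPair,
    compute_dice,
    compute_group_sd,
    compute_iou,
    compute_ser,
    group_mean_scores,
    image_score,
)

from conftest import make_records


def block_mask(n, y0, y1, x0, x1, label=1):
    m = np.zeros((n, n), dtype=np.uint8)
    m[y0:y1, x0:x1] = label
    return m


class TestIoUDice:
    def test_identical_masks_score_one(self):
        m = block_mask(4, 0, 2, 0, 2)
        assert compute_iou(MaskPair(m, m), 1) == 1.0
        assert compute_dice(MaskPair(m, m), 1) == 1.0

    def test_disjoint_blocks_score_zero(self):
        pred = block_mask(4, 0, 2, 0, 2)
        act = block_mask(4, 2, 4, 2, 4)
        assert compute_iou(MaskPair(pred, act), 1) == 0.0
        assert compute_dice(MaskPair(pred, act), 1) == 0.0

    def test_two_pixel_overlap_of_2x2_blocks(self):
        # pred rows 0-1 cols 0-1; actual rows 0-1 cols 1-2: inter 2, union 6
        pred = block_mask(4, 0, 2, 0, 2)
        act = block_mask(4, 0, 2, 1, 3)
        pair = MaskPair(pred, act)
        assert compute_iou(pair, 1) == pytest.approx(2 / 6)
        assert compute_dice(pair, 1) == pytest.approx(2 * 2 / (4 + 4))

    def test_both_empty_class_convention(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        assert compute_iou(MaskPair(m, m), 3) == 1.0
        assert compute_dice(MaskPair(m, m), 3) == 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            MaskPair(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_exhaustive_pixel_count_oracle_on_3x3_grid(self):
        """Brute-force oracle: every 2^9 predicted mask against a fixed gold."""
        gold = block_mask(3, 0, 2, 0, 2)
        gold_set = {(y, x) for y, x in zip(*np.nonzero(gold))}
        for bits in range(2 ** 9):
            pred = np.array([(bits >> k) & 1 for k in range(9)],
                            dtype=np.uint8).reshape(3, 3)
            pred_set = {(y, x) for y, x in zip(*np.nonzero(pred))}
            inter, union = len(pred_set & gold_set), len(pred_set | gold_set)
            pair = MaskPair(pred, gold)
            expect_iou = inter / union if union else 1.0
            expect_dice = (2 * inter / (len(pred_set) + len(gold_set))
                           if pred_set or gold_set else 1.0)
            assert compute_iou(pair, 1) == pytest.approx(expect_iou)
            assert compute_dice(pair, 1) == pytest.approx(expect_dice)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 16 - 1))
    def test_dice_is_algebraic_function_of_iou(self, bits):
        gold = block_mask(4, 1, 3, 1, 3)
        pred = np.array([(bits >> k) & 1 for k in range(16)],
                        dtype=np.uint8).reshape(4, 4)
        pair = MaskPair(pred, gold)
        iou, dice = compute_iou(pair, 1), compute_dice(pair, 1)
        assert 0.0 <= iou <= dice <= 1.0
        assert dice == pytest.approx(2 * iou / (1 + iou))


class TestImageScore:
    def test_perfect_prediction_scores_one(self):
        m = block_mask(4, 0, 2, 0, 2) + block_mask(4, 2, 4, 2, 4, label=2)
        assert image_score(MaskPair(m, m), "iou") == 1.0

    def test_absent_class_counts_as_perfect(self):
        m = block_mask(4, 0, 2, 0, 2)
        assert image_score(MaskPair(m, m), "iou", foreground_classes=[1, 2]) == 1.0

    def test_mean_of_third_half_and_one(self):
        # class 1: IoU 1/3; class 2: IoU 1/2; class 3: IoU 1 -> mean 11/18
        actual = np.zeros((4, 4), dtype=np.uint8)
        pred = np.zeros((4, 4), dtype=np.uint8)
        actual[0, 0:2] = 1; pred[0, 1:3] = 1            # inter 1, union 3
        actual[1, 0:2] = 2; pred[1, 0:4] = 2            # inter 2, union 4
        actual[2, 0] = 3;   pred[2, 0] = 3              # perfect
        score = image_score(MaskPair(pred, actual), "iou", [1, 2, 3])
        assert score == pytest.approx(11 / 18)

    def test_metric_name_validated(self):
        m = block_mask(4, 0, 2, 0, 2)
        with pytest.raises(ValueError, match="metric"):
            image_score(MaskPair(m, m), "hausdorff")


class TestGroupAggregation:
    def test_per_level_means(self):
        records = make_records(3)  # all same level
        m1 = block_mask(4, 0, 2, 0, 2)
        pairs = [MaskPair(m1, m1)] * 3
        gs = group_mean_scores(pairs, records, "sex", "iou")
        assert gs.per_level == {"male": 1.0}
        assert gs.n_per_level == {"male": 3}

    def test_unweighted_mean_within_level(self):
        from fairseg.cohort import Sex

        records = make_records(3, sexes=[Sex.male, Sex.female, Sex.female])
        perfect = block_mask(4, 0, 2, 0, 2)
        empty_pred = np.zeros((4, 4), dtype=np.uint8)
        pairs = [MaskPair(perfect, perfect),          # male: 1.0
                 MaskPair(empty_pred, perfect),       # female: 0.0
                 MaskPair(perfect, perfect)]          # female: 1.0
        gs = group_mean_scores(pairs, records, "sex", "iou",
                               foreground_classes=[1])
        assert gs.per_level == pytest.approx({"male": 1.0, "female": 0.5})


class TestFairnessArithmetic:
    def test_ser_on_published_balanced_row(self):
        # per-level IoU 0.842 / 0.844 -> printed SER 1.013
        ser = compute_ser({"white_caucasian": 0.842,
                           "black_african_american": 0.844})
        assert round(ser, 3) == 1.013

    def test_ser_on_published_three_level_row(self):
        # errors 0.257/0.138/0.157: ratio 1.862, printed 1.854 (3-dec inputs)
        ser = compute_ser({"a": 0.743, "b": 0.862, "c": 0.843})
        assert ser == pytest.approx(0.257 / 0.138)
        assert ser == pytest.approx(1.854, abs=0.01)

    def test_equal_scores_give_ser_one(self):
        assert compute_ser({"a": 0.9, "b": 0.9}) == 1.0

    def test_all_perfect_scores_defined_as_one(self):
        assert compute_ser({"a": 1.0, "b": 1.0}) == 1.0

    def test_single_perfect_level_is_infinite_ser(self):
        with pytest.raises(ZeroDivisionError, match="infinite"):
            compute_ser({"a": 1.0, "b": 0.9})

    def test_ser_needs_two_levels(self):
        with pytest.raises(ValueError):
            compute_ser({"a": 0.9})

    def test_sd_on_published_rows(self):
        assert round(compute_group_sd({"a": 0.842, "b": 0.844}), 3) == 0.001
        assert round(compute_group_sd({"a": 0.743, "b": 0.862, "c": 0.843}), 3) == 0.052

    def test_sd_is_population_normalized(self):
        # errors 0.124/0.133: population SD 0.0045 (sample SD would be 0.0064)
        sd = compute_group_sd({"a": 0.876, "b": 0.867})
        assert sd == pytest.approx(0.0045)

    def test_equal_errors_give_zero_sd(self):
        assert compute_group_sd({"a": 0.8, "b": 0.8}) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10.0),
           st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5))
    def test_ser_invariant_to_error_rescaling(self, c, errors):
        scaled = [min(e * c, 0.999) for e in errors]
        if c * max(errors) >= 1:  # rescaling must stay a valid error rate
            return
        base = compute_ser({f"l{i}": 1 - e for i, e in enumerate(errors)})
        new = compute_ser({f"l{i}": 1 - e for i, e in enumerate(scaled)})
        assert new == pytest.approx(base, rel=1e-9)

    def test_ser_at_least_one_with_equality_iff_equal(self):
        assert compute_ser({"a": 0.7, "b": 0.9}) >= 1.0
        assert compute_ser({"a": 0.7, "b": 0.7}) == 1.0
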