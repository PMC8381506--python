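import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from repgru.evaluation import (
    boundary_match,
    class_rates,
    confusion,
    evaluation_report,
    mcc_k,
    mcc_one_vs_rest,
)
from repgru.io_formats import RepeatClass
from repgru.segmentation import Segment


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        gold = rng.integers(0, 5, size=100)
        conf = confusion(gold, gold)
        assert conf.counts.sum() == 100
        assert np.count_nonzero(conf.counts - np.diag(np.diag(conf.counts))) == 0

    def test_all_zero_versus_all_alu(self):
        conf = confusion(np.zeros(7, dtype=int), np.full(7, int(RepeatClass.ALU)))
        expected = np.zeros((5, 5), dtype=int)
        expected[3, 0] = 7
        np.testing.assert_array_equal(conf.counts, expected)

    def test_hand_counted_matrix(self):
        gold = [0, 0, 1, 1, 1, 3, 3, 4, 4, 0]
        pred = [0, 1, 1, 1, 0, 3, 4, 4, 4, 0]
        conf = confusion(pred, gold)
        assert conf.counts[0, 0] == 2 and conf.counts[0, 1] == 1
        assert conf.counts[1, 1] == 2 and conf.counts[1, 0] == 1
        assert conf.counts[3, 3] == 1 and conf.counts[3, 4] == 1
        assert conf.counts[4, 4] == 2
        assert conf.total == 10

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_mask_excludes_positions(self):
        conf = confusion([0, 3], [3, 3], mask=[False, True])
        assert conf.total == 1
        assert conf.counts[3, 3] == 1

    def test_row_normalisation_divides_by_gold_totals(self):
        conf = confusion([3, 0, 0, 0], [3, 3, 0, 0])
        norm = conf.normalized()
        assert norm[3, 3] == pytest.approx(0.5)
        assert norm[0, 0] == pytest.approx(1.0)


class TestClassRates:
    def test_perfect_prediction(self, rng):
        gold = rng.integers(0, 5, size=50)
        rates = class_rates(gold, gold, RepeatClass.ALU)
        assert rates.fpr == 0.0 and rates.fnr == 0.0

    def test_set_formula_by_hand(self):
        # gold class c at positions 0-4 of 10; prediction at 0-3 and 5
        c = int(RepeatClass.ALU)
        gold = np.zeros(10, dtype=int)
        gold[0:5] = c
        pred = np.zeros(10, dtype=int)
        pred[0:4] = c
        pred[5] = c
        rates = class_rates(pred, gold, c)
        assert rates.fpr == pytest.approx(1 / 5)
        assert rates.fnr == pytest.approx(1 / 5)

    def test_never_predicted_class_has_fnr_one(self):
        gold = np.full(10, int(RepeatClass.HSAT23))
        pred = np.zeros(10, dtype=int)
        assert class_rates(pred, gold, RepeatClass.HSAT23).fnr == 1.0

    def test_zero_denominators_flagged_nan(self):
        gold = np.zeros(5, dtype=int)
        rates = class_rates(np.zeros(5, dtype=int), gold, RepeatClass.ALU)
        assert math.isnan(rates.fnr)
        gold_all_c = np.full(5, int(RepeatClass.ALU))
        rates = class_rates(gold_all_c, gold_all_c, RepeatClass.ALU)
        assert math.isnan(rates.fpr)

    def test_agreement_with_confusion_matrix(self, rng):
        """FNR_c = 1 - counts[c][c] / t_c for every class present."""
        gold = rng.integers(0, 5, size=500)
        pred = rng.integers(0, 5, size=500)
        conf = confusion(pred, gold)
        for c in range(5):
            t_c = conf.counts[c].sum()
            if t_c == 0:
                continue
            rates = class_rates(pred, gold, c)
            assert rates.fnr == pytest.approx(1 - conf.counts[c, c] / t_c)


class TestMcc:
    def test_perfect_diagonal_is_one(self, rng):
        gold = rng.integers(0, 5, size=200)
        assert mcc_k(confusion(gold, gold)) == pytest.approx(1.0)

    def test_independent_prediction_is_near_zero(self, rng):
        gold = rng.integers(0, 5, size=200_00)
        pred = rng.integers(0, 5, size=200_00)
        assert abs(mcc_k(confusion(pred, gold))) < 0.02

    def test_matches_sklearn_reference(self, rng):
        gold = rng.integers(0, 5, size=1000)
        pred = (gold + (rng.random(1000) < 0.3)) % 5
        assert mcc_k(confusion(pred, gold)) == pytest.approx(
            matthews_corrcoef(gold, pred)
        )

    def test_three_class_toy_matrix_against_formula(self):
        # direct Gorodkin computation for a small fixed matrix
        counts = np.zeros((5, 5), dtype=int)
        counts[:3, :3] = [[4, 1, 0], [1, 3, 1], [0, 2, 5]]
        from repgru.evaluation import ConfusionMatrix

        c, s = 12, 17
        t = np.array([5, 5, 7, 0, 0])
        p = np.array([5, 6, 6, 0, 0])
        expected = (c * s - t @ p) / math.sqrt((s**2 - p @ p) * (s**2 - t @ t))
        assert mcc_k(ConfusionMatrix(counts)) == pytest.approx(expected)

    def test_constant_prediction_returns_zero(self):
        gold = np.array([0, 0, 1, 1])
        pred = np.zeros(4, dtype=int)
        assert mcc_k(confusion(pred, gold)) == 0.0

    def test_empty_matrix_raises(self):
        from repgru.evaluation import ConfusionMatrix

        with pytest.raises(ValueError):
            mcc_k(ConfusionMatrix(np.zeros((5, 5), dtype=int)))

    def test_invariant_under_joint_label_permutation(self, rng):
        gold = rng.integers(0, 5, size=300)
        pred = rng.integers(0, 5, size=300)
        permutation = rng.permutation(5)
        original = mcc_k(confusion(pred, gold))
        permuted = mcc_k(confusion(permutation[pred], permutation[gold]))
        assert permuted == pytest.approx(original)

    def test_one_vs_rest_matches_sklearn_binary(self, rng):
        gold = rng.integers(0, 5, size=400)
        pred = rng.integers(0, 5, size=400)
        conf = confusion(pred, gold)
        c = int(RepeatClass.LINE1)
        expected = matthews_corrcoef(gold == c, pred == c)
        assert mcc_one_vs_rest(conf, c) == pytest.approx(expected)


def _segment(start, end, repeat_class=RepeatClass.ALU):
    return Segment(start, end, repeat_class, 1.0)


class TestBoundaryMatch:
    def test_identical_lists_are_perfect(self):
        segments = [_segment(10, 400), _segment(600, 1000, RepeatClass.LINE1)]
        assert boundary_match(segments, segments, delta=0) == (1.0, 1.0)

    def test_shift_beyond_delta_fails(self):
        gold = [_segment(100, 400)]
        pred = [_segment(151, 451)]
        assert boundary_match(pred, gold, delta=50) == (0.0, 0.0)

    def test_shift_of_exactly_delta_matches(self):
        gold = [_segment(100, 400)]
        pred = [_segment(150, 450)]
        assert boundary_match(pred, gold, delta=50) == (1.0, 1.0)

    def test_class_must_agree(self):
        gold = [_segment(100, 400, RepeatClass.ALU)]
        pred = [_segment(100, 400, RepeatClass.LINE1)]
        assert boundary_match(pred, gold, delta=50) == (0.0, 0.0)

    def test_matching_is_one_to_one(self):
        gold = [_segment(100, 400)]
        pred = [_segment(100, 400), _segment(110, 410)]
        sensitivity, specificity = boundary_match(pred, gold, delta=50)
        assert sensitivity == 1.0
        assert specificity == pytest.approx(0.5)


def test_evaluation_report_bundles_all_metrics(rng):
    gold = rng.integers(0, 5, size=300)
    report = evaluation_report(gold, gold,
                               pred_segments=[_segment(0, 60)],
                               gold_segments=[_segment(0, 60)])
    assert report["mcc5"] == pytest.approx(1.0)
    assert set(report["per_class"]) == {"HSAT23", "ALPHOID", "ALU", "LINE1"}
    assert report["boundary"]["sensitivity"] == 1.0
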