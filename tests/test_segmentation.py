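import math
import warnings

import numpy as np
import pytest

from repgru.io_formats import RepeatClass
from repgru.segmentation import (
    MssParams,
    ScoredPositions,
    Segment,
    classify_segments,
    filter_by_length,
    max_scoring_segments,
    probabilities_to_scores,
    segment_track,
)

INF = float("inf")


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def brute_force_all_maximal_segments(scores):
    """All maximal scoring subsequences by exhaustive enumeration:
    recursively extract the maximum-sum interval (computed from all
    O(n^2) interval sums) and recurse into the flanks.  Independent of
    the production scan."""
    scores = np.asarray(scores, dtype=float)

    def best_interval(lo, hi):
        best = (0.0, None, None)
        for i in range(lo, hi):
            total = 0.0
            for j in range(i, hi):
                total += scores[j]
                if total > best[0]:
                    best = (total, i, j + 1)
        return best

    def recurse(lo, hi, out):
        total, i, j = best_interval(lo, hi)
        if i is None or total <= 0:
            return
        recurse(lo, i, out)
        out.append((i, j, total))
        recurse(j, hi, out)

    out: list = []
    recurse(0, len(scores), out)
    return out


def reference_xdrop_segments(scores, min_score, xdrop):
    """Quadratic re-implementation of the stated extension semantics:
    scan for the X-drop cut points naively, solve each closed region by
    brute force, then apply the score floor."""
    scores = np.asarray(scores, dtype=float)
    segments = []
    start = 0
    n = len(scores)
    while start < n:
        cumulative = 0.0
        best = 0.0
        best_pos = start
        cut = None
        for i in range(start, n):
            cumulative += scores[i]
            if cumulative > best:
                best, best_pos = cumulative, i + 1
            if best - cumulative > xdrop:
                cut = i
                break
        region_end = n if cut is None else best_pos
        segments += [
            (s + start, e + start, sc)
            for s, e, sc in brute_force_all_maximal_segments(scores[start:region_end])
        ]
        if cut is None:
            break
        start = region_end if region_end > start else cut + 1
    return [seg for seg in segments if seg[2] >= min_score]


class TestScoreTransform:
    def test_logit_half_is_zero_for_both_branches(self):
        track = np.zeros((2, 5))
        track[0, 0] = 0.5  # no-repeat argmax
        track[1, 3] = 0.5  # repeat argmax
        scored = probabilities_to_scores(track)
        np.testing.assert_allclose(scored.scores, [0.0, 0.0], atol=1e-12)

    def test_cap_at_099_gives_ln99(self):
        track = np.zeros((1, 5))
        track[0, 3] = 1.0
        scored = probabilities_to_scores(track)
        assert scored.classes[0] == 3
        np.testing.assert_allclose(scored.scores[0], math.log(99.0))

    def test_norep_penalty_factor_ten(self):
        track = np.zeros((1, 5))
        track[0, 0] = 0.9
        scored = probabilities_to_scores(track)
        np.testing.assert_allclose(scored.scores[0], -10.0 * math.log(9.0))

    def test_strict_monotonicity_on_q_grid(self):
        q_grid = np.linspace(0.2, 0.99, 50)
        repeat = np.zeros((50, 5))
        repeat[:, 2] = q_grid
        s_repeat = probabilities_to_scores(repeat).scores
        assert (np.diff(s_repeat) > 0).all()
        norep = np.zeros((50, 5))
        norep[:, 0] = q_grid
        s_norep = probabilities_to_scores(norep).scores
        assert (np.diff(s_norep) < 0).all()

    def test_argmax_ties_break_to_smallest_class(self):
        track = np.zeros((1, 5))
        track[0, 2] = 0.4
        track[0, 4] = 0.4
        assert probabilities_to_scores(track).classes[0] == 2


class TestMaxScoringSegments:
    def test_all_negative_scores_yield_nothing(self):
        params = MssParams(min_score=-INF, xdrop=INF)
        assert max_scoring_segments([-1.0, -2.0, -0.5], params) == []

    def test_merge_across_small_dip(self):
        params = MssParams(min_score=1.0, xdrop=100.0)
        segments = max_scoring_segments([2.0, -1.0, 3.0], params)
        assert len(segments) == 1
        assert segments[0][:2] == (0, 3)
        assert segments[0][2] == pytest.approx(4.0)

    def test_xdrop_splits_at_large_drop(self):
        params = MssParams(min_score=1.0, xdrop=3.0)
        segments = max_scoring_segments([5.0, -10.0, 5.0], params)
        assert [(s, e) for s, e, _ in segments] == [(0, 1), (2, 3)]
        assert all(score == pytest.approx(5.0) for _, _, score in segments)

    def test_min_score_floor(self):
        params = MssParams(min_score=6.0, xdrop=INF)
        assert max_scoring_segments([5.0, -10.0, 5.0], params) == []

    def test_empty_input(self):
        assert max_scoring_segments([], MssParams()) == []

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            max_scoring_segments([1.0, float("nan")], MssParams())

    @pytest.mark.parametrize("seed", range(200))
    def test_equals_brute_force_without_xdrop(self, seed):
        """With the X-drop and score floor disabled the scan is the
        classic all-maximal-scoring-subsequences solution."""
        rng = np.random.default_rng(seed)
        scores = rng.uniform(-10, 10, size=rng.integers(1, 61))
        produced = max_scoring_segments(scores, MssParams(min_score=-INF, xdrop=INF))
        expected = brute_force_all_maximal_segments(scores)
        assert [(s, e) for s, e, _ in produced] == [(s, e) for s, e, _ in expected]
        np.testing.assert_allclose(
            [sc for _, _, sc in produced], [sc for _, _, sc in expected]
        )

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_quadratic_reference_with_xdrop(self, seed):
        rng = np.random.default_rng(1000 + seed)
        scores = rng.uniform(-10, 10, size=rng.integers(1, 61))
        params = MssParams(min_score=2.0, xdrop=8.0)
        produced = max_scoring_segments(scores, params)
        expected = reference_xdrop_segments(scores, params.min_score, params.xdrop)
        assert [(s, e) for s, e, _ in produced] == [(s, e) for s, e, _ in expected]

    @pytest.mark.parametrize("seed", range(50))
    def test_output_sorted_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(-10, 10, size=60)
        segments = max_scoring_segments(scores, MssParams(min_score=0.5, xdrop=5.0))
        for (s1, e1, _), (s2, e2, _) in zip(segments, segments[1:]):
            assert e1 <= s2


def _scored(classes, scores=None):
    classes = np.asarray(classes, dtype=np.int8)
    if scores is None:
        scores = np.ones(len(classes))
    return ScoredPositions(classes=classes, scores=np.asarray(scores, dtype=float))


class TestClassifySegments:
    def test_norep_positions_inherit_majority_class(self):
        scored = _scored([3, 3, 0, 3])
        segments = classify_segments([(0, 4, 4.0)], scored)
        assert len(segments) == 1
        assert (segments[0].start, segments[0].end) == (0, 4)
        assert segments[0].repeat_class == RepeatClass.ALU

    def test_mixed_segment_split_after_inheritance(self):
        scored = _scored([3, 3, 0, 4, 4, 4])
        segments = classify_segments([(0, 6, 6.0)], scored)
        assert [(s.start, s.end, s.repeat_class) for s in segments] == [
            (0, 2, RepeatClass.ALU),
            (2, 6, RepeatClass.LINE1),
        ]

    def test_single_class_segment_is_identity(self):
        segments = classify_segments([(0, 1, 1.0)], _scored([3]))
        assert [(s.start, s.end) for s in segments] == [(0, 1)]

    def test_all_norep_segment_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no-repeat"):
            assert classify_segments([(0, 3, 1.0)], _scored([0, 0, 0])) == []

    def test_majority_tie_breaks_to_smallest_class(self):
        segments = classify_segments([(0, 5, 1.0)], _scored([4, 3, 0, 3, 4]))
        inherited = [s for s in segments if s.start <= 2 < s.end]
        assert inherited[0].repeat_class == RepeatClass.ALU

    def test_scores_are_sums_of_member_positions(self):
        scored = _scored([3, 3, 4], scores=[1.0, 2.0, 5.0])
        segments = classify_segments([(0, 3, 8.0)], scored)
        assert segments[0].score == pytest.approx(3.0)
        assert segments[1].score == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_covered_bp_conserved(self, seed):
        rng = np.random.default_rng(seed)
        classes = rng.integers(0, 5, size=50)
        if (classes == 0).all():
            classes[0] = 1
        scored = _scored(classes, rng.normal(size=50))
        raw = [(5, 45, 0.0)]
        segments = classify_segments(raw, scored)
        if any(classes[5:45] != 0):
            assert sum(s.length for s in segments) == 40


class TestFilterByLength:
    def test_threshold_is_strict(self):
        segments = [
            Segment(0, 50, RepeatClass.ALU, 1.0),
            Segment(60, 111, RepeatClass.ALU, 1.0),
        ]
        kept = filter_by_length(segments, 50)
        assert [s.length for s in kept] == [51]

    def test_zero_threshold_is_identity(self):
        segments = [Segment(0, 3, RepeatClass.ALU, 1.0)]
        assert filter_by_length(segments, 0) == segments

    def test_empty_input(self):
        assert filter_by_length([], 50) == []


def test_segment_track_end_to_end_on_synthetic_probabilities():
    """A confident repeat block flanked by confident background comes
    out as one segment with the right class and boundaries."""
    track = np.zeros((300, 5))
    track[:, 0] = 0.95
    track[100:200, 0] = 0.02
    track[100:200, 3] = 0.95
    segments = segment_track(track, MssParams(min_length=50))
    assert [(s.start, s.end, s.repeat_class) for s in segments] == [
        (100, 200, RepeatClass.ALU)
    ]
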