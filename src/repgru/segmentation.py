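"""From aggregated class probabilities to classified repeat segments.

Per position the maximum class probability is capped at 0.99 and mapped
through the logit; positions whose best class is *no repeat* get a
negative score scaled by -10 so that segments do not extend across long
non-repetitive stretches.  All maximal scoring segments of the score
sequence are then found with a Ruzzo-Tompa-style scan extended by a
minimum-score threshold and an X-drop rule: when the running score falls
more than X below the maximum reached in the current extension, the
extension terminates and segments found so far are frozen (they are
never merged into later segments).  Segments inherit the majority repeat
class, mixed segments are split into one segment per class run, and
short segments are discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import RepeatClass

__all__ = [
    "ScoredPositions",
    "Segment",
    "MssParams",
    "probabilities_to_scores",
    "max_scoring_segments",
    "classify_segments",
    "filter_by_length",
    "segment_track",
]

#: Cap on the per-position maximum probability; removes the q = 1
#: singularity of the logit.
PROBABILITY_CAP = 0.99

#: Penalty factor applied to the (negated) logit of no-repeat positions.
NOREP_PENALTY = 10.0

#: Shipped defaults for the segmentation thresholds, expressed in units
#: of the capped logit ln(99): a segment must accumulate at least five
#: saturated repeat positions' worth of score, and an extension
#: tolerates a drop of ten such units.  Both are configuration values.
DEFAULT_MIN_SCORE = 5.0 * math.log(99.0)
DEFAULT_XDROP = 10.0 * math.log(99.0)
DEFAULT_MIN_LENGTH = 50


@dataclass(frozen=True)
class MssParams:
    """Thresholds for segment extraction.

    min_score: segments with a lower total score are discarded.
    xdrop: tolerated drop below the running maximum before an extension
        is terminated (>= 0; ``inf`` disables the rule).
    min_length: only segments strictly longer than this many bp are kept
        (50 by default).
    """

    min_score: float = DEFAULT_MIN_SCORE
    xdrop: float = DEFAULT_XDROP
    min_length: int = DEFAULT_MIN_LENGTH

    def __post_init__(self) -> None:
        if self.xdrop < 0:
            raise ValueError("xdrop must be >= 0")


@dataclass(frozen=True)
class ScoredPositions:
    """Per-position argmax classes and signed logit scores.

    classes[i] is the label with the highest aggregated probability at
    position i (ties broken toward the smallest class id) and scores[i]
    the signed, capped logit score of that probability.
    """

    classes: np.ndarray
    scores: np.ndarray


@dataclass(frozen=True)
class Segment:
    """A classified repeat segment, 0-based half-open."""

    start: int
    end: int
    repeat_class: RepeatClass
    score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.repeat_class == RepeatClass.NOREP:
            raise ValueError("segments carry a repeat class, never NOREP")

    @property
    def length(self) -> int:
        return self.end - self.start


def probabilities_to_scores(track: np.ndarray) -> ScoredPositions:
    """Convert an aggregated n x 5 probability track to signed scores.

    q_i = min(max_c p_i^c, 0.99); c_i = argmax_c p_i^c (smallest class id
    on ties); s_i = logit(q_i) for repeat classes and -10 * logit(q_i)
    for the no-repeat class, with the natural logarithm.
    """
    track = np.asarray(track, dtype=np.float64)
    if track.ndim != 2 or track.shape[1] != 5:
        raise ValueError("expected an n x 5 probability track")
    classes = np.argmax(track, axis=1)  # numpy argmax takes the first = smallest id
    q = np.minimum(track.max(axis=1), PROBABILITY_CAP)
    scores = np.log(q / (1.0 - q))
    norep = classes == 0
    scores[norep] *= -NOREP_PENALTY
    return ScoredPositions(classes=classes.astype(np.int8), scores=scores)


def _ruzzo_tompa(scores: np.ndarray, offset: int) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences of ``scores`` (classic algorithm).

    Returns (start, end, score) triples in ascending start order, with
    ``offset`` added to the coordinates.  Only strictly positive
    segments exist by construction.
    """
    # stack entries: [start, end, L, R] with L/R the cumulative score
    # just before the start and at the end of the candidate subsequence.
    stack: list[list[float]] = []
    cumulative = 0.0
    for i, s in enumerate(scores):
        left = cumulative
        cumulative += s
        if s <= 0:
            continue
        candidate = [i, i + 1, left, cumulative]
        while True:
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= candidate[2]:
                j -= 1
            if j < 0 or stack[j][3] >= candidate[3]:
                stack.append(candidate)
                break
            # merge: the candidate absorbs stack[j] and everything above
            candidate = [stack[j][0], candidate[1], stack[j][2], candidate[3]]
            del stack[j:]
    return [
        (int(start) + offset, int(end) + offset, right - left)
        for start, end, left, right in stack
    ]


def max_scoring_segments(
    scores: Sequence[float] | np.ndarray, params: MssParams
) -> list[tuple[int, int, float]]:
    """Maximal scoring segments with X-drop termination and a score floor.

    The score sequence is scanned left to right while tracking the
    cumulative score of the current extension and its running maximum.
    When the cumulative score falls more than ``params.xdrop`` below
    that maximum, the extension is closed at the position where the
    maximum was attained: the maximal scoring subsequences of the closed
    region are emitted and are never merged with later segments, and
    scanning restarts with fresh bookkeeping.  Finally, segments with a
    total score below ``params.min_score`` are dropped.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    segments: list[tuple[int, int, float]] = []
    n = len(scores)
    region_start = 0
    i = 0
    cumulative = 0.0
    best = 0.0
    best_pos = 0  # position just after the running-maximum prefix
    while i < n:
        cumulative += scores[i]
        if cumulative > best:
            best = cumulative
            best_pos = i + 1
        if best - cumulative > params.xdrop:
            segments.extend(
                _ruzzo_tompa(scores[region_start:best_pos], region_start)
            )
            # restart after the closed region; if it is empty the drop
            # came immediately, so skip the offending position instead
            region_start = best_pos if best_pos > region_start else i + 1
            i = region_start
            cumulative = 0.0
            best = 0.0
            best_pos = region_start
            continue
        i += 1
    segments.extend(_ruzzo_tompa(scores[region_start:n], region_start))
    return [seg for seg in segments if seg[2] >= params.min_score]


def classify_segments(
    raw_segments: Sequence[tuple[int, int, float]], scored: ScoredPositions
) -> list[Segment]:
    """Assign repeat classes to raw segments and split mixed ones.

    Within each raw segment, no-repeat positions inherit the repeat
    class occurring most often in the segment (ties toward the smallest
    class id); each maximal run of one class then becomes its own
    Segment whose score is the sum of its members' position scores.
    Segments containing no repeat-class position at all are dropped with
    a warning.
    """
    classes = scored.classes
    scores = scored.scores
    result: list[Segment] = []
    for start, end, _ in raw_segments:
        if start < 0 or end > len(classes):
            raise ValueError(f"segment [{start}, {end}) outside scored range")
        local = classes[start:end].astype(np.int64)
        counts = np.bincount(local, minlength=5)
        counts[0] = 0
        if counts.sum() == 0:
            warnings.warn(
                f"segment [{start}, {end}) contains only no-repeat positions; dropped",
                stacklevel=2,
            )
            continue
        majority = int(np.argmax(counts))  # first max = smallest class id
        local[local == 0] = majority
        # split into maximal single-class runs
        boundaries = np.flatnonzero(np.diff(local)) + 1
        run_starts = np.concatenate(([0], boundaries))
        run_ends = np.concatenate((boundaries, [len(local)]))
        for rs, re_ in zip(run_starts, run_ends):
            result.append(
                Segment(
                    start=start + int(rs),
                    end=start + int(re_),
                    repeat_class=RepeatClass(int(local[rs])),
                    score=float(scores[start + rs : start + re_].sum()),
                )
            )
    return result


def filter_by_length(segments: Sequence[Segment], min_length: int) -> list[Segment]:
    """Keep segments strictly longer than ``min_length`` bp."""
    return [segment for segment in segments if segment.length > min_length]


def segment_track(track: np.ndarray, params: MssParams | None = None) -> list[Segment]:
    """Full post-processing: probabilities -> scores -> classified segments."""
    if params is None:
        params = MssParams()
    scored = probabilities_to_scores(track)
    raw = max_scoring_segments(scored.scores, params)
    segments = classify_segments(raw, scored)
    return filter_by_length(segments, params.min_length)
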