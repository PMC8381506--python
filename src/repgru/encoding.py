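"""Dual-strand one-hot encoding and the sliding-window layout.

DNA is represented over the five-letter alphabet A, C, G, T, N and
one-hot encoded with five channels per position (channel 5 marks N).
The network consumes fixed-length windows slid over the sequence; the
window length is fixed at training time, the step is free at prediction
time and trades running time against accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "DnaSequence",
    "trim_n_stretches",
    "reverse_complement",
    "one_hot_encode",
    "make_windows",
    "WindowSet",
    "RC_COLUMN_PERMUTATION",
]

ALPHABET = "ACGTN"

#: base -> one-hot column, fixed as A, C, G, T, N.
_BASE_INDEX = {base: i for i, base in enumerate(ALPHABET)}

#: column permutation mapping the encoding of a base to that of its
#: complement (A<->T, C<->G, N->N).
RC_COLUMN_PERMUTATION = np.array([3, 2, 1, 0, 4])

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class DnaSequence:
    """An uppercase ACGTN sequence with its offset in the untrimmed source.

    ``origin`` is the number of leading bases (an initial N-run) removed
    before prediction, so reported coordinates can be shifted back to
    the source coordinate system.
    """

    bases: str
    origin: int = 0

    def __post_init__(self) -> None:
        if self.origin < 0:
            raise ValueError("origin must be >= 0")
        invalid = set(self.bases) - set(ALPHABET)
        if invalid:
            raise ValueError(f"invalid symbols in sequence: {sorted(invalid)}")

    def __len__(self) -> int:
        return len(self.bases)


def trim_n_stretches(raw: str) -> DnaSequence:
    """Remove initial and terminal stretches of Ns, keeping internal Ns.

    The origin records how many leading bases were removed.  An all-N
    input yields an empty sequence (prediction then yields no segments).
    """
    stripped_left = raw.lstrip("N")
    origin = len(raw) - len(stripped_left)
    return DnaSequence(stripped_left.rstrip("N"), origin)


def reverse_complement(seq: DnaSequence | str) -> DnaSequence | str:
    """Watson-Crick reverse complement (N maps to N); an involution."""
    if isinstance(seq, DnaSequence):
        return DnaSequence(seq.bases.translate(_COMPLEMENT)[::-1], seq.origin)
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot_encode(seq: DnaSequence | str) -> np.ndarray:
    """Encode a sequence as an n x 5 one-hot matrix (columns A,C,G,T,N)."""
    bases = seq.bases if isinstance(seq, DnaSequence) else seq
    try:
        indices = [_BASE_INDEX[base] for base in bases]
    except KeyError as exc:
        raise ValueError(f"cannot encode symbol {exc.args[0]!r}") from None
    matrix = np.zeros((len(bases), 5), dtype=np.float32)
    if indices:
        matrix[np.arange(len(indices)), indices] = 1.0
    return matrix


@dataclass(frozen=True)
class WindowSet:
    """Start offsets of fixed-length windows covering a sequence.

    Every position of the sequence is covered by at least one window.
    If the sequence is shorter than one window, the single window is
    padded on the right with N rows up to ``window_length``;
    ``padded_tail`` gives the number of padding rows (excluded from
    aggregation downstream).
    """

    window_length: int
    step: int
    starts: tuple[int, ...]
    padded_tail: int = 0

    def __len__(self) -> int:
        return len(self.starts)


def make_windows(n: int, window_length: int, step: int) -> WindowSet:
    """Lay out sliding windows of ``window_length`` with stride ``step``.

    Regular starts are 0, step, 2*step, ... while the window still fits;
    if the last regular window does not reach position n, one extra
    window is anchored at ``n - window_length`` so the tail is predicted
    with a full-length window.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if n == 0:
        return WindowSet(window_length, step, ())
    if n < window_length:
        return WindowSet(window_length, step, (0,), padded_tail=window_length - n)
    starts = list(range(0, n - window_length + 1, step))
    if starts[-1] + window_length < n:
        starts.append(n - window_length)
    return WindowSet(window_length, step, tuple(starts))


def encode_window(full_one_hot: np.ndarray, start: int, window_length: int) -> np.ndarray:
    """Slice one forward-strand window out of a precomputed encoding.

    Rows beyond the end of the sequence are padded as N.
    """
    n = full_one_hot.shape[0]
    end = start + window_length
    if end <= n:
        return full_one_hot[start:end]
    window = np.zeros((window_length, 5), dtype=full_one_hot.dtype)
    window[: n - start] = full_one_hot[start:]
    window[n - start :, 4] = 1.0  # N padding
    return window


def reverse_complement_window(window: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded window (row reversal + A<->T, C<->G)."""
    return window[::-1, RC_COLUMN_PERMUTATION]
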