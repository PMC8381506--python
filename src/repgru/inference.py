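"""Sliding-window prediction and max-aggregation over a sequence.

Overlapping windows yield several class probabilities per position;
only the maximum over all covering windows is kept, per position and
class.  The aggregation is streaming (a running element-wise maximum),
so memory stays O(n * 5) regardless of the step size.  Smaller steps
mean more covering windows and therefore entries that can only grow —
the step is a trade-off knob between running time and accuracy.
"""

from __future__ import annotations

import numpy as np

from .encoding import (
    DnaSequence,
    encode_window,
    make_windows,
    one_hot_encode,
    reverse_complement_window,
)
from .network import GRUAttentionModel

__all__ = ["predict_sequence"]


def predict_sequence(
    model: GRUAttentionModel,
    seq: DnaSequence | str,
    step: int = 50,
    batch_size: int = 64,
) -> np.ndarray:
    """Aggregated n x 5 probability track for one (trimmed) sequence.

    Rows are per-class maxima over covering windows and need not sum
    to 1.  Padded tail rows of a sub-window-length sequence are
    excluded.  An empty sequence yields an empty track.
    """
    bases = seq.bases if isinstance(seq, DnaSequence) else seq
    n = len(bases)
    window_length = model.config.window_length
    track = np.zeros((n, 5), dtype=np.float32)
    if n == 0:
        return track
    full = one_hot_encode(bases)
    window_set = make_windows(n, window_length, step)
    starts = window_set.starts
    for begin in range(0, len(starts), batch_size):
        chunk = starts[begin : begin + batch_size]
        X_fwd = np.stack(
            [encode_window(full, start, window_length) for start in chunk]
        )
        X_rc = np.stack([reverse_complement_window(w) for w in X_fwd])
        probs = model.predict_proba(X_fwd, X_rc)
        for row, start in enumerate(chunk):
            valid = min(window_length, n - start)
            span = track[start : start + valid]
            np.maximum(span, probs[row, :valid], out=span)
    return track


def dump_track(track: np.ndarray, path) -> None:
    """Write an aggregated track as tab-separated text (position + the
    five per-class maxima) for debugging."""
    header = "position\tNOREP\tHSAT23\tALPHOID\tALU\tLINE1"
    positions = np.arange(track.shape[0])[:, None]
    np.savetxt(path, np.hstack((positions, track)), fmt=["%d"] + ["%.6f"] * 5,
               delimiter="\t", header=header, comments="")
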