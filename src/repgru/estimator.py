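"""Scikit-learn style estimator wrapping the full annotation pipeline.

``RepeatAnnotator`` is a sequence classifier: ``fit`` takes genomic
sequences with per-position gold labels, ``predict`` returns
per-position label tracks derived from the segmented output, and
``annotate`` returns the classified repeat segments themselves.  It
follows the scikit-learn estimator contract (``get_params`` /
``set_params``, fitted attributes with a trailing underscore), so it
composes with sklearn model selection where that is useful.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import DnaSequence, trim_n_stretches
from .inference import predict_sequence
from .io_formats import N_CLASSES
from .network import GRUAttentionModel, ModelConfig
from .segmentation import (
    DEFAULT_MIN_LENGTH,
    DEFAULT_MIN_SCORE,
    DEFAULT_XDROP,
    MssParams,
    Segment,
    segment_track,
)
from .training import TrainConfig, WindowPool, build_pool, train

__all__ = ["RepeatAnnotator"]


def _as_dna(sequence) -> DnaSequence:
    if isinstance(sequence, DnaSequence):
        return sequence
    return trim_n_stretches(str(sequence).upper())


class RepeatAnnotator(ClassifierMixin, BaseEstimator):
    """Per-base repeat annotation with a dual-strand GRU + attention.

    Parameters mirror the pipeline's knobs: architecture
    (recurrent_units, attention_units, window_length), training
    (train_step, batch_size, repeat_fraction, max_epochs, patience,
    learning_rate, steps_per_epoch), prediction (step) and
    segmentation (min_score, xdrop, min_length).

    Fitted attributes: ``model_`` (the trained network), ``history_``
    (per-epoch losses and the best epoch) and ``classes_``.
    """

    def __init__(
        self,
        recurrent_units: int = 32,
        attention_units: int = 8,
        window_length: int = 342,
        train_step: int = 50,
        step: int = 50,
        batch_size: int = 32,
        repeat_fraction: float = 0.5,
        max_epochs: int = 40,
        patience: int = 10,
        learning_rate: float = 0.01,
        dropout: float = 0.0,
        augment_rate: float = 0.05,
        steps_per_epoch: int | None = None,
        min_score: float = DEFAULT_MIN_SCORE,
        xdrop: float = DEFAULT_XDROP,
        min_length: int = DEFAULT_MIN_LENGTH,
        random_state: int = 0,
    ) -> None:
        self.recurrent_units = recurrent_units
        self.attention_units = attention_units
        self.window_length = window_length
        self.train_step = train_step
        self.step = step
        self.batch_size = batch_size
        self.repeat_fraction = repeat_fraction
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.augment_rate = augment_rate
        self.steps_per_epoch = steps_per_epoch
        self.min_score = min_score
        self.xdrop = xdrop
        self.min_length = min_length
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            recurrent_units=self.recurrent_units,
            attention_units=self.attention_units,
            window_length=self.window_length,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            repeat_fraction=self.repeat_fraction,
            max_epochs=self.max_epochs,
            patience=self.patience,
            learning_rate=self.learning_rate,
            dropout=self.dropout,
            augment_rate=self.augment_rate,
            seed=self.random_state,
            steps_per_epoch=self.steps_per_epoch,
        )

    def mss_params(self) -> MssParams:
        return MssParams(
            min_score=self.min_score, xdrop=self.xdrop, min_length=self.min_length
        )

    @staticmethod
    def _trimmed_pairs(X, y) -> list[tuple[DnaSequence, np.ndarray]]:
        pairs = []
        for sequence, labels in zip(X, y, strict=True):
            dna = _as_dna(sequence)
            labels = np.asarray(labels)
            end = dna.origin + len(dna)
            pairs.append((dna, labels[dna.origin : end]))
        return pairs

    def fit(self, X, y, validation_data=None, log=None) -> "RepeatAnnotator":
        """Train on sequences ``X`` with per-position label tracks ``y``.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair used
        for early stopping; without it a random 10% of the training
        windows is held out.
        """
        pool = build_pool(
            self._trimmed_pairs(X, y), self.window_length, self.train_step
        )
        if validation_data is not None:
            X_val, y_val = validation_data
            val_pool = build_pool(
                self._trimmed_pairs(X_val, y_val),
                self.window_length,
                self.train_step,
            )
            train_pool = pool
        else:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(pool))
            n_val = max(1, len(pool) // 10)
            val_idx, train_idx = order[:n_val], order[n_val:]
            train_pool = WindowPool(
                pool.encodings, pool.labels, pool.window_length,
                [pool.windows[i] for i in train_idx],
                [pool.contains[i] for i in train_idx],
            )
            val_pool = WindowPool(
                pool.encodings, pool.labels, pool.window_length,
                [pool.windows[i] for i in val_idx],
                [pool.contains[i] for i in val_idx],
            )
        self.model_ = GRUAttentionModel(self._model_config(), seed=self.random_state)
        self.history_ = train(
            self.model_, train_pool, val_pool, self._train_config(), log=log
        )
        self.classes_ = np.arange(N_CLASSES)
        return self

    # ------------------------------------------------------------------

    def predict_proba(self, X) -> list[np.ndarray]:
        """Aggregated per-position class-probability maxima per sequence.

        Tracks are reported in the untrimmed coordinate system (rows
        for trimmed N-flanks are all-zero).
        """
        check_is_fitted(self, "model_")
        tracks = []
        for sequence in X:
            dna = _as_dna(sequence)
            total = dna.origin + len(dna) + self._trailing(sequence, dna)
            track = np.zeros((total, N_CLASSES), dtype=np.float32)
            track[dna.origin : dna.origin + len(dna)] = predict_sequence(
                self.model_, dna, step=self.step
            )
            tracks.append(track)
        return tracks

    @staticmethod
    def _trailing(sequence, dna: DnaSequence) -> int:
        raw_length = len(sequence.bases if isinstance(sequence, DnaSequence) else sequence)
        return raw_length - dna.origin - len(dna)

    def annotate(self, sequence) -> list[Segment]:
        """Classified repeat segments for one sequence (untrimmed coords)."""
        check_is_fitted(self, "model_")
        dna = _as_dna(sequence)
        track = predict_sequence(self.model_, dna, step=self.step)
        segments = segment_track(track, self.mss_params())
        if dna.origin == 0:
            return segments
        return [
            Segment(
                segment.start + dna.origin,
                segment.end + dna.origin,
                segment.repeat_class,
                segment.score,
            )
            for segment in segments
        ]

    def predict(self, X) -> list[np.ndarray]:
        """Per-position label tracks derived from the segmented output."""
        check_is_fitted(self, "model_")
        tracks = []
        for sequence in X:
            dna = _as_dna(sequence)
            total = dna.origin + len(dna) + self._trailing(sequence, dna)
            track = np.zeros(total, dtype=np.int8)
            for segment in self.annotate(sequence):
                track[segment.start : segment.end] = int(segment.repeat_class)
            tracks.append(track)
        return tracks

    def score(self, X, y) -> float:
        """Multi-class Matthews correlation coefficient over all positions."""
        from .evaluation import confusion, mcc_k

        pred = np.concatenate([track for track in self.predict(X)])
        gold = np.concatenate([np.asarray(labels) for labels in y])
        return mcc_k(confusion(pred, gold))
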