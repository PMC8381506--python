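"""Batch construction, optimisation and early stopping.

Repeat classes are rare and imbalanced along a genome, so batches are
composed with explicit floors: a batch of size n contains at least
floor(n*r) windows with at least one repeat-annotated position, and
among those at least floor(n*r/|C|) windows per repeat class, with r in
[0, 1] a tunable fraction.  Rare classes are thereby sampled more often
than their pool frequency.  The remaining slots are drawn uniformly
from the whole pool.

Training minimises per-position categorical cross-entropy with Adam and
stops early once the validation loss has not improved (strictly
decreased) for ``patience`` consecutive epochs; the parameters of the
best-validation epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import (
    DnaSequence,
    make_windows,
    one_hot_encode,
    reverse_complement_window,
)
from .io_formats import N_CLASSES, REPEAT_CLASSES
from .network import GRUAttentionModel

__all__ = [
    "TrainConfig",
    "BalancingError",
    "TrainingError",
    "WindowPool",
    "build_pool",
    "compose_batch",
    "train",
]


class BalancingError(ValueError):
    """The window pool cannot satisfy the per-class batch floors."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    repeat_fraction is the batch-composition fraction r; patience the
    number of consecutive non-improving validation epochs tolerated
    before stopping; dropout regularises the recurrent outputs (the
    planted repeat families are few, so memorising individual mutated
    copies is a real failure mode).  The learning rate is halved
    (``lr_plateau_factor``) whenever the validation loss has not
    improved for ``lr_plateau_patience`` consecutive epochs, down to
    ``min_learning_rate`` -- the validation curve is noisy at a fixed
    rate.  ``steps_per_epoch`` defaults to pool size // batch_size.
    """

    batch_size: int = 32
    repeat_fraction: float = 0.5
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 0.01
    augment_rate: float = 0.0
    lr_plateau_patience: int = 4
    lr_plateau_factor: float = 0.5
    min_learning_rate: float = 1e-3
    dropout: float = 0.0
    seed: int = 0
    steps_per_epoch: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise ValueError("repeat_fraction must be in [0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if not (0.0 <= self.augment_rate < 1.0):
            raise ValueError("augment_rate must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class WindowPool:
    """Training windows over one or more encoded sequences.

    ``windows`` holds (sequence index, start) pairs; encodings and
    one-hot label targets are sliced out of the per-sequence arrays on
    demand, so the pool is cheap in memory even for dense strides.
    """

    encodings: list[np.ndarray]
    labels: list[np.ndarray]
    window_length: int
    windows: list[tuple[int, int]] = field(default_factory=list)
    contains: list[frozenset[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def by_class(self, repeat_class: int) -> list[int]:
        return [
            i for i, present in enumerate(self.contains) if repeat_class in present
        ]

    def repeat_windows(self) -> list[int]:
        return [i for i, present in enumerate(self.contains) if present]

    def batch_arrays(self, indices) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Assemble (X_fwd, X_rc, Y) arrays for the given window indices."""
        T = self.window_length
        B = len(indices)
        X_fwd = np.empty((B, T, 5), dtype=np.float32)
        X_rc = np.empty((B, T, 5), dtype=np.float32)
        Y = np.zeros((B, T, N_CLASSES), dtype=np.float32)
        for row, index in enumerate(indices):
            seq_index, start = self.windows[index]
            window = self.encodings[seq_index][start : start + T]
            X_fwd[row] = window
            X_rc[row] = reverse_complement_window(window)
            label_slice = self.labels[seq_index][start : start + T]
            Y[row, np.arange(T), label_slice] = 1.0
        return X_fwd, X_rc, Y


def build_pool(
    sequences: list[tuple[DnaSequence | str, np.ndarray]],
    window_length: int = 342,
    step: int = 50,
) -> WindowPool:
    """Window a set of labelled sequences into a training pool.

    Sequences shorter than one window are skipped (they cannot form a
    full-length training window).
    """
    pool = WindowPool(encodings=[], labels=[], window_length=window_length)
    for seq, labels in sequences:
        bases = seq.bases if isinstance(seq, DnaSequence) else seq
        labels = np.asarray(labels, dtype=np.int64)
        if len(bases) != len(labels):
            raise ValueError("sequence and label track lengths differ")
        if len(bases) < window_length:
            continue
        seq_index = len(pool.encodings)
        pool.encodings.append(one_hot_encode(bases))
        pool.labels.append(labels)
        for start in make_windows(len(bases), window_length, step).starts:
            window_labels = labels[start : start + window_length]
            present = frozenset(int(c) for c in np.unique(window_labels) if c != 0)
            pool.windows.append((seq_index, start))
            pool.contains.append(present)
    return pool


def compose_batch(
    pool: WindowPool, n: int, r: float, rng: np.random.Generator
) -> list[int]:
    """Draw one class-balanced batch of window indices.

    Floors: >= floor(n*r) repeat-containing windows, of which
    >= floor(n*r/|C|) per repeat class (sampled without replacement
    within each class); remaining slots uniform over the pool.
    """
    if len(pool) == 0:
        raise ValueError("empty window pool")
    n_repeat = int(np.floor(n * r))
    per_class = int(np.floor(n * r / len(REPEAT_CLASSES)))
    chosen: list[int] = []
    for repeat_class in REPEAT_CLASSES:
        candidates = pool.by_class(int(repeat_class))
        if len(candidates) < per_class:
            raise BalancingError(
                f"pool has only {len(candidates)} windows containing "
                f"{repeat_class.name}, need {per_class}"
            )
        if per_class:
            chosen.extend(
                rng.choice(candidates, size=per_class, replace=False).tolist()
            )
    remainder = n_repeat - len(chosen)
    if remainder > 0:
        repeat_candidates = pool.repeat_windows()
        if not repeat_candidates:
            raise BalancingError("pool contains no repeat-annotated windows")
        chosen.extend(
            rng.choice(repeat_candidates, size=remainder, replace=True).tolist()
        )
    fill = n - len(chosen)
    if fill > 0:
        chosen.extend(rng.integers(0, len(pool), size=fill).tolist())
    rng.shuffle(chosen)
    return chosen


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = learning_rate, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        correction = (
            np.sqrt(1.0 - self.beta2**self.t) / (1.0 - self.beta1**self.t)
        )
        for name, grad in grads.items():
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * grad
            v *= self.beta2
            v += (1.0 - self.beta2) * grad * grad
            params[name] -= self.lr * correction * m / (np.sqrt(v) + self.eps)


def _augment_batch(X_fwd: np.ndarray, rate: float, rng: np.random.Generator):
    """Substitute a random fraction of positions with random bases and
    rebuild the reverse-complement stream consistently."""
    B, T, _ = X_fwd.shape
    mask = rng.random((B, T)) < rate
    n_hits = int(mask.sum())
    if n_hits:
        X_fwd = X_fwd.copy()
        X_fwd[mask] = np.eye(5, dtype=X_fwd.dtype)[rng.integers(0, 4, size=n_hits)]
    from .encoding import RC_COLUMN_PERMUTATION

    X_rc = X_fwd[:, ::-1, :][:, :, RC_COLUMN_PERMUTATION]
    return X_fwd, X_rc


def _evaluate_loss(model: GRUAttentionModel, pool: WindowPool,
                   batch_size: int) -> float:
    """Mean cross-entropy over all windows of a pool (no balancing)."""
    total, weight = 0.0, 0
    for begin in range(0, len(pool), batch_size):
        indices = list(range(begin, min(begin + batch_size, len(pool))))
        X_fwd, X_rc, Y = pool.batch_arrays(indices)
        probs = model.predict_proba(X_fwd, X_rc)
        eps = np.finfo(np.float32).tiny
        total += -float(
            np.log(np.maximum((probs * Y).sum(axis=2), eps)).sum()
        )
        weight += probs.shape[0] * probs.shape[1]
    return total / max(weight, 1)


def train(
    model: GRUAttentionModel,
    train_pool: WindowPool,
    val_pool: WindowPool,
    config: TrainConfig,
    log=None,
) -> dict:
    """Fit the model; returns the training history.

    The history maps ``train_loss`` / ``val_loss`` to per-epoch lists
    and records the best-validation epoch whose parameters the model
    carries on return.
    """
    if len(train_pool) == 0 or len(val_pool) == 0:
        raise ValueError("train and validation pools must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = _Adam(model.params, config.learning_rate)
    steps = config.steps_per_epoch or max(1, len(train_pool) // config.batch_size)
    best_val = np.inf
    best_params = model.copy_params()
    best_epoch = -1
    stall = 0
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    for epoch in range(config.max_epochs):
        epoch_loss = 0.0
        for _ in range(steps):
            indices = compose_batch(
                train_pool, config.batch_size, config.repeat_fraction, rng
            )
            X_fwd, X_rc, Y = train_pool.batch_arrays(indices)
            if config.augment_rate > 0.0:
                X_fwd, X_rc = _augment_batch(X_fwd, config.augment_rate, rng)
            loss, grads = model.loss_and_grads(
                X_fwd, X_rc, Y, dropout=config.dropout, rng=rng
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            optimizer.step(model.params, grads)
            epoch_loss += loss
        val_loss = _evaluate_loss(model, val_pool, config.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(epoch_loss / steps)
        history["val_loss"].append(val_loss)
        if log is not None:
            log(
                f"epoch {epoch}: train_loss={epoch_loss / steps:.4f} "
                f"val_loss={val_loss:.4f}"
            )
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.copy_params()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
            if (
                stall % config.lr_plateau_patience == 0
                and optimizer.lr > config.min_learning_rate
            ):
                optimizer.lr = max(
                    optimizer.lr * config.lr_plateau_factor,
                    config.min_learning_rate,
                )
                if log is not None:
                    log(f"learning rate reduced to {optimizer.lr:.2e}")
    model.set_params_arrays(best_params)
    history["best_epoch"] = best_epoch
    return history
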