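"""The attention-augmented shared-weight bidirectional recurrent model.

One window of DNA enters the network twice: as the forward-strand
one-hot encoding and as the one-hot encoding of its reverse complement.
A single GRU — one weight set — processes both streams, so the learned
features are independent of the orientation of the sequence and the
recurrent parameters are counted only once.  The reverse-complement
stream's per-position outputs are re-reversed into forward coordinates
before the two streams are averaged element-wise (position i of both
streams then refers to the same base); the two final hidden states are
averaged as well.

An additive attention layer scores every averaged position output
against the averaged final hidden state, softmax-normalises the scores
over the window and forms a context vector; the context is concatenated
to each position's features, making a summary of the whole window
available at every position.  A position-wise dense layer with softmax
finally yields a probability distribution over the five labels
(no repeat + four repeat classes) per position.

The implementation is a compact numpy network: forward pass, analytic
backward pass (validated against finite differences in the test suite)
and framework-free checkpointing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["ModelConfig", "GRUAttentionModel", "build_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    recurrent_units: GRU state size (32 by default — a desk-scale
        setting that trains in minutes on one CPU).
    attention_units: dimension of the additive-attention scoring space.
    window_length: fixed input window length in bp (342).
    """

    recurrent_units: int = 32
    attention_units: int = 8
    window_length: int = 342
    n_classes: int = 5
    vocabulary: int = 5

    def __post_init__(self) -> None:
        if self.recurrent_units < 1 or self.attention_units < 1:
            raise ValueError("unit counts must be >= 1")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.n_classes != 5 or self.vocabulary != 5:
            raise ValueError("the model is defined over 5 symbols and 5 labels")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class GRUAttentionModel:
    """Numpy implementation of the dual-strand GRU + attention classifier.

    Parameters live in ``self.params`` (a name -> ndarray dict); the GRU
    gate order in the fused matrices is [update z, reset r, candidate h].
    """

    #: fused parameter names; the GRU weights appear once (shared by
    #: the forward-strand and reverse-complement-strand streams).
    PARAM_NAMES = ("W", "U_zr", "U_h", "b", "Wa", "Ua", "ba", "v", "Wd", "bd")

    def __init__(self, config: ModelConfig, seed: int = 0,
                 dtype=np.float32) -> None:
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        H, A, V, K = (config.recurrent_units, config.attention_units,
                      config.vocabulary, config.n_classes)
        self.params: dict[str, np.ndarray] = {
            "W": _glorot(rng, (V, 3 * H), self.dtype),
            "U_zr": _glorot(rng, (H, 2 * H), self.dtype),
            "U_h": _glorot(rng, (H, H), self.dtype),
            "b": np.zeros(3 * H, dtype=self.dtype),
            "Wa": _glorot(rng, (H, A), self.dtype),
            "Ua": _glorot(rng, (H, A), self.dtype),
            "ba": np.zeros(A, dtype=self.dtype),
            "v": _glorot(rng, (A, 1), self.dtype)[:, 0],
            "Wd": _glorot(rng, (2 * H, K), self.dtype),
            "bd": np.zeros(K, dtype=self.dtype),
        }

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------

    def _gru_forward(self, X: np.ndarray, with_cache: bool):
        """Run the (shared) GRU over one stream.

        X: (B, T, V) one-hot input.  Returns (H_seq, h_last, cache).
        """
        p = self.params
        B, T, _ = X.shape
        H = self.config.recurrent_units
        XW = X.reshape(B * T, -1) @ p["W"]
        XW = (XW + p["b"]).reshape(B, T, 3 * H)
        h = np.zeros((B, H), dtype=self.dtype)
        H_seq = np.empty((T, B, H), dtype=self.dtype)
        cache = None
        if with_cache:
            cache = {
                "z": np.empty((T, B, H), dtype=self.dtype),
                "r": np.empty((T, B, H), dtype=self.dtype),
                "hc": np.empty((T, B, H), dtype=self.dtype),
                "h_prev": np.empty((T, B, H), dtype=self.dtype),
                "rh": np.empty((T, B, H), dtype=self.dtype),
                "X": X,
            }
        for t in range(T):
            a = XW[:, t]
            zr = h @ p["U_zr"]
            z = _sigmoid(a[:, :H] + zr[:, :H])
            r = _sigmoid(a[:, H : 2 * H] + zr[:, H:])
            rh = r * h
            hc = np.tanh(a[:, 2 * H :] + rh @ p["U_h"])
            h_new = z * h + (1.0 - z) * hc
            if with_cache:
                cache["z"][t] = z
                cache["r"][t] = r
                cache["hc"][t] = hc
                cache["h_prev"][t] = h
                cache["rh"][t] = rh
            H_seq[t] = h_new
            h = h_new
        return np.ascontiguousarray(H_seq.transpose(1, 0, 2)), h, cache

    def _gru_backward(self, cache, dH_seq: np.ndarray, dh_last: np.ndarray,
                      grads: dict[str, np.ndarray]) -> None:
        """Backpropagation through time for one stream; accumulates into
        ``grads`` (shared weights: both streams add to the same arrays)."""
        p = self.params
        H = self.config.recurrent_units
        B, T, _ = dH_seq.shape
        dXW = np.empty((T, B, 3 * H), dtype=self.dtype)
        dh = dh_last.astype(self.dtype).copy()
        dH_seq_t = dH_seq.transpose(1, 0, 2)
        for t in range(T - 1, -1, -1):
            dh = dh + dH_seq_t[t]
            z, r = cache["z"][t], cache["r"][t]
            hc, h_prev, rh = cache["hc"][t], cache["h_prev"][t], cache["rh"][t]
            dz = dh * (h_prev - hc)
            dhc = dh * (1.0 - z)
            dh_prev = dh * z
            dah = dhc * (1.0 - hc * hc)
            drh = dah @ p["U_h"].T
            grads["U_h"] += rh.T @ dah
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dXW[t, :, :H] = daz
            dXW[t, :, H : 2 * H] = dar
            dXW[t, :, 2 * H :] = dah
            dzr = np.concatenate((daz, dar), axis=1)
            grads["U_zr"] += h_prev.T @ dzr
            dh_prev += dzr @ p["U_zr"].T
            dh = dh_prev
        dXW_flat = dXW.transpose(1, 0, 2).reshape(B * T, 3 * H)
        grads["W"] += cache["X"].reshape(B * T, -1).T @ dXW_flat
        grads["b"] += dXW_flat.sum(axis=0)

    def forward(self, X_fwd: np.ndarray, X_rc: np.ndarray,
                with_cache: bool = False, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Full forward pass; returns (probs, cache).

        X_fwd / X_rc: (B, T, 5) encodings of the window and of its
        reverse complement.  probs: (B, T, K) row-stochastic.
        ``dropout`` applies inverted dropout to the averaged
        per-position recurrent outputs (training-time regularisation;
        requires ``rng``).
        """
        p = self.params
        X_fwd = np.ascontiguousarray(X_fwd, dtype=self.dtype)
        X_rc = np.ascontiguousarray(X_rc, dtype=self.dtype)
        if X_fwd.shape != X_rc.shape or X_fwd.ndim != 3:
            raise ValueError("expected matching (B, T, 5) strand encodings")
        if X_fwd.shape[2] != self.config.vocabulary:
            raise ValueError("encodings must have 5 channels")
        Hf, hf, cache_f = self._gru_forward(X_fwd, with_cache)
        Hr, hr, cache_r = self._gru_forward(X_rc, with_cache)
        H_avg = 0.5 * (Hf + Hr[:, ::-1, :])  # rc stream back to forward coords
        s = 0.5 * (hf + hr)
        mask = None
        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires a random generator")
            keep = 1.0 - dropout
            mask = (rng.random(H_avg.shape) < keep).astype(self.dtype) / keep
            H_avg = H_avg * mask
        u = np.tanh(H_avg @ p["Wa"] + (s @ p["Ua"])[:, None, :] + p["ba"])
        e = u @ p["v"]
        e = e - e.max(axis=1, keepdims=True)
        alpha = np.exp(e)
        alpha /= alpha.sum(axis=1, keepdims=True)
        context = np.einsum("bt,bth->bh", alpha, H_avg)
        B, T, H = H_avg.shape
        F = np.concatenate(
            (H_avg, np.broadcast_to(context[:, None, :], (B, T, H))), axis=2
        )
        logits = F @ p["Wd"] + p["bd"]
        logits = logits - logits.max(axis=2, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=2, keepdims=True)
        cache = None
        if with_cache:
            cache = {
                "gru_f": cache_f, "gru_r": cache_r, "H_avg": H_avg, "s": s,
                "u": u, "alpha": alpha, "context": context, "F": F,
                "probs": probs, "mask": mask,
            }
        return probs, cache

    def predict_proba(self, X_fwd: np.ndarray, X_rc: np.ndarray) -> np.ndarray:
        """Per-position class probabilities for a batch of windows."""
        probs, _ = self.forward(X_fwd, X_rc, with_cache=False)
        return probs

    # ------------------------------------------------------------------
    # loss and gradients
    # ------------------------------------------------------------------

    def loss_and_grads(self, X_fwd, X_rc, Y, weights=None,
                       dropout: float = 0.0,
                       rng: np.random.Generator | None = None):
        """Weighted categorical cross-entropy and its parameter gradients.

        Y: (B, T, K) one-hot targets; weights: (B, T) position weights
        (zero excludes a position, e.g. padding).  Returns
        (loss, grads dict).
        """
        p = self.params
        probs, cache = self.forward(
            X_fwd, X_rc, with_cache=True, dropout=dropout, rng=rng
        )
        B, T, K = probs.shape
        Y = np.asarray(Y, dtype=self.dtype)
        if weights is None:
            weights = np.ones((B, T), dtype=self.dtype)
        weights = np.asarray(weights, dtype=self.dtype)
        wsum = float(weights.sum())
        if wsum <= 0:
            raise ValueError("all position weights are zero")
        eps = np.finfo(self.dtype).tiny
        loss = -float(
            (weights * np.log(np.maximum((probs * Y).sum(axis=2), eps))).sum()
        ) / wsum
        grads = {name: np.zeros_like(arr) for name, arr in p.items()}

        dlogits = (probs - Y) * (weights / wsum)[:, :, None]
        F = cache["F"]
        H = self.config.recurrent_units
        grads["Wd"] += F.reshape(B * T, 2 * H).T @ dlogits.reshape(B * T, K)
        grads["bd"] += dlogits.sum(axis=(0, 1))
        dF = dlogits @ p["Wd"].T
        dH_avg = dF[:, :, :H].copy()
        dcontext = dF[:, :, H:].sum(axis=1)

        H_avg, alpha, u, s = cache["H_avg"], cache["alpha"], cache["u"], cache["s"]
        dalpha = np.einsum("bh,bth->bt", dcontext, H_avg)
        dH_avg += alpha[:, :, None] * dcontext[:, None, :]
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        grads["v"] += (u * de[:, :, None]).sum(axis=(0, 1))
        da = (de[:, :, None] * p["v"]) * (1.0 - u * u)
        A = self.config.attention_units
        grads["Wa"] += H_avg.reshape(B * T, H).T @ da.reshape(B * T, A)
        dH_avg += da @ p["Wa"].T
        da_sum = da.sum(axis=1)
        grads["Ua"] += s.T @ da_sum
        grads["ba"] += da.sum(axis=(0, 1))
        ds = da_sum @ p["Ua"].T

        if cache["mask"] is not None:
            dH_avg *= cache["mask"]
        dH_f = 0.5 * dH_avg
        dH_r = 0.5 * dH_avg[:, ::-1, :]
        dh_last = 0.5 * ds
        self._gru_backward(cache["gru_f"], dH_f, dh_last, grads)
        self._gru_backward(cache["gru_r"], dH_r, dh_last, grads)
        return loss, grads

    # ------------------------------------------------------------------
    # bookkeeping
    # ------------------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        """Trainable parameter count; GRU weights are counted once."""
        return sum(arr.size for arr in self.params.values())

    def copy_params(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr in self.params.items()}

    def set_params_arrays(self, params: dict[str, np.ndarray]) -> None:
        for name, arr in params.items():
            self.params[name][...] = arr

    def save(self, directory: str | Path, metadata: dict | None = None) -> None:
        """Write the checkpoint: parameter arrays + a config sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params)
        sidecar = {"config": asdict(self.config), "metadata": metadata or {}}
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "GRUAttentionModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        model = cls(ModelConfig(**sidecar["config"]))
        with np.load(directory / "params.npz") as archive:
            for name in model.params:
                model.params[name][...] = archive[name]
        return model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    positive = x >= 0
    out[positive] = 1.0 / (1.0 + np.exp(-x[positive]))
    expx = np.exp(x[~positive])
    out[~positive] = expx / (1.0 + expx)
    return out


def build_model(config: ModelConfig | None = None, seed: int = 0) -> GRUAttentionModel:
    """Construct a freshly initialised model (deterministic in ``seed``)."""
    return GRUAttentionModel(config or ModelConfig(), seed=seed)


def load_model(directory: str | Path) -> GRUAttentionModel:
    return GRUAttentionModel.load(directory)
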