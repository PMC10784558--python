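"""From-scratch bidirectional LSTM classifier (numpy only).

Two independent LSTM cells read the input sequence in opposite directions;
their final hidden states are concatenated and fed to a linear head.  The
head is either a softmax over classes trained with categorical cross-entropy
(one-hot mode) or an elementwise logistic layer trained with summed per-bit
binary cross-entropy against Walsh codewords (walsh mode).  Gradients are
computed by backpropagation through time and applied with Adam; an L2
penalty (lambda / 2N) * sum(w^2) on the head weights regularizes training.

Gate equations, with z_t = [y_{t-1}, x_t]:

    i_t = sigmoid(W_i z_t + b_i)      f_t = sigmoid(W_f z_t + b_f)
    o_t = sigmoid(W_o z_t + b_o)      g_t = tanh(W_c z_t + b_c)
    s_t = f_t * s_{t-1} + i_t * g_t   y_t = o_t * tanh(s_t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .walsh import Codebook, decode

__all__ = [
    "LSTMWeights",
    "BiLSTMModel",
    "TrainConfig",
    "TrainHistory",
    "lstm_step",
    "bilstm_forward",
    "loss",
    "backward",
    "train",
    "predict",
]

_CLIP = 1e-12  # log-stability clipping for probabilities

HEAD_MODES = ("softmax_onehot", "sigmoid_walsh")
LAYOUTS = ("sequence", "vector")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMWeights:
    """Gate weights over the concatenated [previous output, current input]."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1] - self.hidden

    def __post_init__(self) -> None:
        h = self.W_i.shape[0]
        for name in ("W_i", "W_f", "W_o", "W_c"):
            w = getattr(self, name)
            if w.shape != self.W_i.shape:
                raise ValueError(f"{name}: inconsistent gate weight shape {w.shape}")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            b = getattr(self, name)
            if b.shape != (h,):
                raise ValueError(f"{name}: expected shape ({h},), got {b.shape}")

    @classmethod
    def init(cls, hidden: int, input_dim: int, rng: np.random.Generator) -> "LSTMWeights":
        bound = 1.0 / np.sqrt(hidden + input_dim)
        shape = (hidden, hidden + input_dim)
        return cls(
            *(rng.uniform(-bound, bound, shape) for _ in range(4)),
            *(np.zeros(hidden) for _ in range(4)),
        )


def lstm_step(
    weights: LSTMWeights,
    x_t: np.ndarray,
    y_prev: np.ndarray,
    s_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One LSTM cell update on a batch; returns (y_t, s_t, cache).

    ``x_t`` is (batch, input_dim); ``y_prev``/``s_prev`` are (batch, hidden).
    The cache holds the gate activations needed by the backward pass.
    """
    x_t = np.atleast_2d(x_t)
    y_prev = np.atleast_2d(y_prev)
    s_prev = np.atleast_2d(s_prev)
    if x_t.shape[1] != weights.input_dim or y_prev.shape[1] != weights.hidden:
        raise ValueError("input/state shapes do not match the weights")
    z = np.concatenate([y_prev, x_t], axis=1)
    i = _sigmoid(z @ weights.W_i.T + weights.b_i)
    f = _sigmoid(z @ weights.W_f.T + weights.b_f)
    o = _sigmoid(z @ weights.W_o.T + weights.b_o)
    g = np.tanh(z @ weights.W_c.T + weights.b_c)
    s = f * s_prev + i * g
    tanh_s = np.tanh(s)
    y = o * tanh_s
    cache = {"z": z, "i": i, "f": f, "o": o, "g": g, "s_prev": s_prev, "tanh_s": tanh_s}
    return y, s, cache


@dataclass
class BiLSTMModel:
    forward_cell: LSTMWeights
    backward_cell: LSTMWeights
    W_head: np.ndarray
    b_head: np.ndarray
    head_mode: str
    layout: str = "sequence"

    @property
    def hidden(self) -> int:
        return self.forward_cell.hidden

    @property
    def out_dim(self) -> int:
        return self.W_head.shape[0]

    def __post_init__(self) -> None:
        if self.head_mode not in HEAD_MODES:
            raise ValueError(f"head_mode must be one of {HEAD_MODES}")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if self.W_head.shape[1] != 2 * self.hidden:
            raise ValueError("head input size must be 2 x hidden (concatenation)")

    @classmethod
    def init(cls, hidden: int, input_dim: int, out_dim: int, head_mode: str,
             rng: np.random.Generator, layout: str = "sequence") -> "BiLSTMModel":
        bound = 1.0 / np.sqrt(2 * hidden)
        return cls(
            forward_cell=LSTMWeights.init(hidden, input_dim, rng),
            backward_cell=LSTMWeights.init(hidden, input_dim, rng),
            W_head=rng.uniform(-bound, bound, (out_dim, 2 * hidden)),
            b_head=np.zeros(out_dim),
            head_mode=head_mode,
            layout=layout,
        )

    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        for tag, cell in (("fwd", self.forward_cell), ("bwd", self.backward_cell)):
            for name in ("W_i", "W_f", "W_o", "W_c", "b_i", "b_f", "b_o", "b_c"):
                params[f"{tag}.{name}"] = getattr(cell, name)
        params["head.W"] = self.W_head
        params["head.b"] = self.b_head
        return params

    # -- serialization -------------------------------------------------

    def save(self, out_dir: str | Path, extra_meta: dict | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **self.parameters())
        meta = {"head_mode": self.head_mode, "layout": self.layout,
                "hidden": self.hidden, "out_dim": self.out_dim,
                "input_dim": self.forward_cell.input_dim}
        if extra_meta:
            meta.update(extra_meta)
        (out / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> tuple["BiLSTMModel", dict]:
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "meta.json").read_text())
        arrs = np.load(model_dir / "weights.npz")
        cells = {}
        for tag in ("fwd", "bwd"):
            cells[tag] = LSTMWeights(
                *(arrs[f"{tag}.{n}"] for n in ("W_i", "W_f", "W_o", "W_c")),
                *(arrs[f"{tag}.{n}"] for n in ("b_i", "b_f", "b_o", "b_c")),
            )
        model = cls(cells["fwd"], cells["bwd"], arrs["head.W"], arrs["head.b"],
                    head_mode=meta["head_mode"], layout=meta["layout"])
        return model, meta


def _run_direction(weights: LSTMWeights, xs: np.ndarray) -> tuple[np.ndarray, list[dict]]:
    batch, T, _ = xs.shape
    y = np.zeros((batch, weights.hidden))
    s = np.zeros((batch, weights.hidden))
    caches = []
    for t in range(T):
        y, s, c = lstm_step(weights, xs[:, t, :], y, s)
        caches.append(c)
    return y, caches


def bilstm_forward(model: BiLSTMModel, sequence: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run both directions over a (batch, T, D) or (T, D) sequence.

    Returns the head outputs (softmax probabilities or per-bit sigmoids) and
    the caches required by :func:`backward`.
    """
    xs = np.asarray(sequence, dtype=float)
    single = xs.ndim == 2
    if single:
        xs = xs[None]
    if xs.ndim != 3 or xs.shape[1] == 0:
        raise ValueError("sequence must be non-empty with shape (batch, T, D)")
    y_fwd, caches_fwd = _run_direction(model.forward_cell, xs)
    y_bwd, caches_bwd = _run_direction(model.backward_cell, xs[:, ::-1, :])
    h = np.concatenate([y_fwd, y_bwd], axis=1)
    logits = h @ model.W_head.T + model.b_head
    if model.head_mode == "softmax_onehot":
        shifted = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(shifted)
        out = ex / ex.sum(axis=1, keepdims=True)
    else:
        out = _sigmoid(logits)
    caches = {"fwd": caches_fwd, "bwd": caches_bwd, "h": h, "out": out,
              "batch": xs.shape[0], "T": xs.shape[1]}
    return (out[0] if single else out), caches


def loss(outputs: np.ndarray, targets: np.ndarray, model: BiLSTMModel,
         l2_lambda: float = 0.0, n_train: int = 1) -> float:
    """Mean data loss over the batch plus the head-weight L2 penalty.

    One-hot mode: categorical cross-entropy with natural logs.  Walsh mode:
    per-bit binary cross-entropy summed over bits.  Probabilities are clipped
    at 1e-12 so the logs stay finite.
    """
    out = np.atleast_2d(np.asarray(outputs, dtype=float))
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    if out.shape != tgt.shape:
        raise ValueError("outputs and targets must have identical shapes")
    p = np.clip(out, _CLIP, 1.0 - _CLIP)
    if model.head_mode == "softmax_onehot":
        data = -np.sum(tgt * np.log(p), axis=1)
    else:
        data = -np.sum(tgt * np.log(p) + (1.0 - tgt) * np.log(1.0 - p), axis=1)
    l2 = l2_lambda / (2.0 * n_train) * float(np.sum(model.W_head**2))
    return float(data.mean() + l2)


def _backward_direction(weights: LSTMWeights, caches: list[dict],
                        dy_final: np.ndarray) -> dict[str, np.ndarray]:
    grads = {n: np.zeros_like(getattr(weights, n))
             for n in ("W_i", "W_f", "W_o", "W_c", "b_i", "b_f", "b_o", "b_c")}
    hidden = weights.hidden
    dy = dy_final
    ds_carry = np.zeros_like(dy_final)
    for cache in reversed(caches):
        i, f, o, g = cache["i"], cache["f"], cache["o"], cache["g"]
        tanh_s = cache["tanh_s"]
        do = dy * tanh_s
        ds = ds_carry + dy * o * (1.0 - tanh_s**2)
        di = ds * g
        dg = ds * i
        df = ds * cache["s_prev"]
        ds_carry = ds * f
        da_i = di * i * (1.0 - i)
        da_f = df * f * (1.0 - f)
        da_o = do * o * (1.0 - o)
        da_g = dg * (1.0 - g**2)
        z = cache["z"]
        grads["W_i"] += da_i.T @ z
        grads["W_f"] += da_f.T @ z
        grads["W_o"] += da_o.T @ z
        grads["W_c"] += da_g.T @ z
        grads["b_i"] += da_i.sum(axis=0)
        grads["b_f"] += da_f.sum(axis=0)
        grads["b_o"] += da_o.sum(axis=0)
        grads["b_c"] += da_g.sum(axis=0)
        dz = (da_i @ weights.W_i + da_f @ weights.W_f
              + da_o @ weights.W_o + da_g @ weights.W_c)
        dy = dz[:, :hidden]
    return grads


def backward(model: BiLSTMModel, caches: dict, targets: np.ndarray,
             l2_lambda: float = 0.0, n_train: int = 1) -> dict[str, np.ndarray]:
    """BPTT gradients of :func:`loss` for every weight and bias.

    For both head modes the gradient at the logits is (output - target),
    scaled by 1/batch to match the batch-mean data loss.
    """
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    out = caches.get("out")
    if out is None or out.shape != tgt.shape:
        raise ValueError("caches do not match the targets (stale or wrong batch?)")
    batch = caches["batch"]
    dlogits = (out - tgt) / batch
    h = caches["h"]
    grads: dict[str, np.ndarray] = {
        "head.W": dlogits.T @ h + (l2_lambda / n_train) * model.W_head,
        "head.b": dlogits.sum(axis=0),
    }
    dh = dlogits @ model.W_head
    hidden = model.hidden
    for tag, cell, dy in (("fwd", model.forward_cell, dh[:, :hidden]),
                          ("bwd", model.backward_cell, dh[:, hidden:])):
        cell_grads = _backward_direction(cell, caches[tag], dy)
        for name, g in cell_grads.items():
            grads[f"{tag}.{name}"] = g
    return grads


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 100
    learning_rate: float = 5e-4
    hidden: int = 128
    l2_lambda: float = 1e-3
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    feature_noise_sd: float = 0.1
    layout: str = "sequence"

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.hidden) < 1:
            raise ValueError("batch_size, epochs and hidden must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_lambda < 0 or self.feature_noise_sd < 0:
            raise ValueError("l2_lambda and feature_noise_sd must be >= 0")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def _as_sequences(features: np.ndarray, layout: str) -> np.ndarray:
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if layout == "sequence":  # length-D sequence of scalars
        return feats[:, :, None]
    return feats[:, None, :]  # length-1 sequence of D-vectors


def _targets_for(labels: np.ndarray, n_classes: int,
                 codebook: Codebook | None) -> np.ndarray:
    if codebook is None:
        return np.eye(n_classes)[labels]
    return codebook.codewords[labels].astype(float)


def _decode_outputs(outputs: np.ndarray, codebook: Codebook | None) -> np.ndarray:
    if codebook is None:
        return np.argmax(outputs, axis=1)
    return np.array([decode(row, codebook)[0] for row in outputs])


def train(features: np.ndarray, labels: np.ndarray, config: TrainConfig,
          codebook: Codebook | None = None) -> tuple[BiLSTMModel, TrainHistory]:
    """Mini-batch Adam training of a Bi-LSTM on labeled feature vectors.

    Feature vectors are presented as sequences per ``config.layout``; targets
    are one-hot vectors, or Walsh codewords when a codebook is given.
    Gaussian noise of sd ``feature_noise_sd`` is added to the inputs at every
    presentation.  Fully reproducible from ``config.seed``.
    """
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if feats.shape[0] != labels.size:
        raise ValueError("features and labels must have equal length")
    n_classes = int(labels.max()) + 1
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least two classes")
    if codebook is not None and codebook.num_classes < n_classes:
        raise ValueError("codebook has fewer codewords than classes")

    rng = np.random.default_rng(config.seed)
    input_dim = feats.shape[1] if config.layout == "vector" else 1
    out_dim = codebook.order if codebook is not None else n_classes
    head_mode = "softmax_onehot" if codebook is None else "sigmoid_walsh"
    model = BiLSTMModel.init(config.hidden, input_dim, out_dim, head_mode, rng,
                             layout=config.layout)
    targets = _targets_for(labels, n_classes, codebook)
    n_train = feats.shape[0]

    params = model.parameters()
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    history = TrainHistory()
    for _ in range(config.epochs):
        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n_train, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = feats[idx]
            if config.feature_noise_sd > 0:
                xb = xb + rng.normal(0.0, config.feature_noise_sd, xb.shape)
            seqs = _as_sequences(xb, config.layout)
            out, caches = bilstm_forward(model, seqs)
            batch_loss = loss(out, targets[idx], model, config.l2_lambda, n_train)
            grads = backward(model, caches, targets[idx], config.l2_lambda, n_train)
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1.0 - config.adam_beta2**step) / (1.0 - config.adam_beta1**step)
            )
            for key, p in params.items():
                g = grads[key]
                m_state[key] = config.adam_beta1 * m_state[key] + (1 - config.adam_beta1) * g
                v_state[key] = config.adam_beta2 * v_state[key] + (1 - config.adam_beta2) * g**2
                p -= lr_t * m_state[key] / (np.sqrt(v_state[key]) + config.adam_eps)
            epoch_loss += batch_loss * idx.size
            preds = _decode_outputs(np.atleast_2d(out), codebook)
            epoch_correct += int(np.sum(preds == labels[idx]))
        history.loss.append(epoch_loss / n_train)
        history.accuracy.append(epoch_correct / n_train)
    return model, history


def predict(model: BiLSTMModel, features: np.ndarray,
            codebook: Codebook | None = None) -> np.ndarray:
    """Class indices for feature vectors: argmax (one-hot) or nearest codeword."""
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if model.head_mode == "sigmoid_walsh" and codebook is None:
        raise ValueError("walsh-mode model needs a codebook to decode predictions")
    seqs = _as_sequences(feats, model.layout)
    out, _ = bilstm_forward(model, seqs)
    return _decode_outputs(np.atleast_2d(out), codebook)
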