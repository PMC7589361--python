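"""Bidirectional-LSTM sequence classifier with a length-weighted
cross-entropy objective, implemented in NumPy for single-CPU training.

Architecture: raw tri-axial sequences -> bi-LSTM (default 10 hidden units
per direction) -> concatenation of the forward state at the last true step
with the backward state at the first step -> three fully connected layers
(tanh between them) -> softmax over the posture classes.

The training objective is the unnormalized, length-weighted cross-entropy

    L = - sum_i sum_j m_i * y_ij * ln(p_ij),

where ``m_i`` is the length (sample count) of sequence ``i``.  Training uses
Adam (``beta2`` = the squared-gradient decay rate, default 0.99) with either
a piecewise-decaying learning rate (the adaptive configuration) or a
constant one (the fixed-rate baseline).  Mini-batches are formed after
sorting sequences by length so that padding within a batch is minimal;
padded steps are masked out of both recurrent directions.

All gradients are computed analytically by backpropagation through time;
``tests`` verify them against finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from recline.data import DEFAULT_LABELS, Episode
from recline.errors import TrainingError, ValidationError

__all__ = [
    "AdaLSTMConfig",
    "AdaLSTMModel",
    "SequenceBatch",
    "build_model",
    "load_model",
    "predict",
    "predict_proba",
    "save_model",
    "train",
    "weighted_cross_entropy",
]

_EPS_LOG = 1e-12
_ADAM_EPS = 1e-8
_BETA1 = 0.9


@dataclass(frozen=True)
class AdaLSTMConfig:
    """Hyper-parameters of the sequence classifier.

    The defaults mirror the adaptive training recipe: 10 hidden units,
    three fully connected layers, at most 100 epochs, initial learning rate
    0.01, squared-gradient decay 0.99, mini-batch size 27.  Set
    ``lr_schedule="constant"`` for the fixed-learning-rate LSTM baseline.
    """

    n_classes: int
    hidden_units: int = 10
    fc_hidden_sizes: tuple[int, ...] = (10, 10)
    max_epochs: int = 100
    initial_lr: float = 0.01
    squared_grad_decay: float = 0.99
    batch_size: int = 27
    lr_schedule: str = "piecewise"  # "piecewise" | "constant"
    lr_drop_factor: float = 0.5
    lr_drop_every_epochs: int = 20
    input_dim: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        for name in ("hidden_units", "max_epochs", "batch_size", "input_dim"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.squared_grad_decay < 1.0:
            raise ValidationError("squared_grad_decay must be in (0, 1)")
        if self.lr_schedule not in ("piecewise", "constant"):
            raise ValidationError("lr_schedule must be 'piecewise' or 'constant'")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index."""
        if self.lr_schedule == "constant":
            return self.initial_lr
        drops = epoch // self.lr_drop_every_epochs
        return self.initial_lr * (self.lr_drop_factor**drops)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class AdaLSTMModel:
    """Parameter container; build with :func:`build_model`."""

    config: AdaLSTMConfig
    params: dict[str, np.ndarray]
    label_vocabulary: tuple[str, ...] = DEFAULT_LABELS
    loss_trace: list[float] = field(default_factory=list)


def build_model(
    config: AdaLSTMConfig,
    label_vocabulary: Sequence[str] = DEFAULT_LABELS,
) -> AdaLSTMModel:
    """Initialize parameters deterministically from ``config.seed``."""
    vocab = tuple(label_vocabulary)
    if len(vocab) < config.n_classes:
        raise ValidationError(
            f"label vocabulary {vocab} smaller than n_classes={config.n_classes}"
        )
    rng = np.random.default_rng(config.seed)
    H, D = config.hidden_units, config.input_dim
    params: dict[str, np.ndarray] = {}
    for tag in ("fwd", "bwd"):
        params[f"Wx_{tag}"] = _glorot(rng, (D, 4 * H))
        params[f"Wh_{tag}"] = _glorot(rng, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        params[f"b_{tag}"] = b
    sizes = (2 * H, *config.fc_hidden_sizes, config.n_classes)
    for i in range(len(sizes) - 1):
        params[f"Wfc{i}"] = _glorot(rng, (sizes[i], sizes[i + 1]))
        params[f"bfc{i}"] = np.zeros(sizes[i + 1])
    return AdaLSTMModel(config=config, params=params, label_vocabulary=vocab)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


@dataclass
class SequenceBatch:
    """Padded variable-length sequences with one-hot labels and length
    weights ``m_i``; ``mask[b, t]`` is 1 on true samples, 0 on padding."""

    x: np.ndarray       # (B, T, D)
    mask: np.ndarray    # (B, T)
    onehot: np.ndarray  # (B, K)
    weights: np.ndarray  # (B,)

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[np.ndarray],
        labels: Optional[Sequence[str]],
        vocab: Sequence[str],
    ) -> "SequenceBatch":
        lengths = [s.shape[0] for s in sequences]
        if min(lengths) < 1:
            raise ValidationError("sequences must have length >= 1")
        B, T = len(sequences), max(lengths)
        D = sequences[0].shape[1]
        x = np.zeros((B, T, D))
        mask = np.zeros((B, T))
        for b, seq in enumerate(sequences):
            x[b, : lengths[b]] = seq
            mask[b, : lengths[b]] = 1.0
        K = len(vocab)
        onehot = np.zeros((B, K))
        if labels is not None:
            index = {lab: j for j, lab in enumerate(vocab)}
            for b, lab in enumerate(labels):
                onehot[b, index[lab]] = 1.0
        weights = np.asarray(lengths, dtype=float)
        return cls(x=x, mask=mask, onehot=onehot, weights=weights)


def weighted_cross_entropy(
    batch_predictions: np.ndarray, batch: SequenceBatch
) -> float:
    """The length-weighted cross-entropy ``-sum_i sum_j m_i y_ij ln p_ij``.

    Probabilities at the true class equal to 0 are clamped at 1e-12 with a
    warning rather than producing an infinite loss.
    """
    p = np.asarray(batch_predictions, dtype=float)
    if p.shape != batch.onehot.shape:
        raise ValidationError(
            f"predictions shape {p.shape} != labels shape {batch.onehot.shape}"
        )
    true_p = (p * batch.onehot).sum(axis=1)
    if np.any(true_p <= 0.0):
        warnings.warn(
            "true-class probability of 0 clamped at 1e-12", RuntimeWarning
        )
        true_p = np.clip(true_p, _EPS_LOG, None)
    return float(-(batch.weights * np.log(true_p)).sum())


# ---------------------------------------------------------------------------
# Forward / backward passes
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _lstm_forward(x, mask, Wx, Wh, b):
    """Masked LSTM scan.  Padded steps hold h and c unchanged, so the final
    state equals the state at each sequence's last true step.

    Returns the final hidden state and the cache needed for backprop.
    """
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        m = mask[:, t][:, None]
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((x[:, t], h, c, i, f, g, o, tanh_c, m))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
    return h, cache


def _lstm_backward(dh_out, cache, Wx, Wh):
    """BPTT through a masked LSTM scan; returns parameter gradients."""
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh_next = dh_out
    dc_next = np.zeros_like(dh_out)
    for x_t, h_prev, c_prev, i, f, g, o, tanh_c, m in reversed(cache):
        dh = m * dh_next
        dc = m * dc_next
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ Wh.T + (1.0 - m) * dh_next
        dc_next = dc * f + (1.0 - m) * dc_next
    return dWx, dWh, db


def _reverse_within_lengths(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reverse each sequence inside its true length, keeping padding at the
    tail.  Running the forward scan on this input realizes the backward
    direction: its final state is the state at the original first step."""
    out = np.zeros_like(x)
    lengths = mask.sum(axis=1).astype(int)
    for b, n in enumerate(lengths):
        out[b, :n] = x[b, :n][::-1]
    return out


def _forward(model: AdaLSTMModel, batch: SequenceBatch, *, need_cache: bool):
    p = model.params
    hf, cache_f = _lstm_forward(
        batch.x, batch.mask, p["Wx_fwd"], p["Wh_fwd"], p["b_fwd"]
    )
    x_rev = _reverse_within_lengths(batch.x, batch.mask)
    hb, cache_b = _lstm_forward(
        x_rev, batch.mask, p["Wx_bwd"], p["Wh_bwd"], p["b_bwd"]
    )
    u = np.concatenate([hf, hb], axis=1)
    acts = [u]
    n_fc = len(model.config.fc_hidden_sizes) + 1
    a = u
    for i in range(n_fc):
        z = a @ p[f"Wfc{i}"] + p[f"bfc{i}"]
        a = z if i == n_fc - 1 else np.tanh(z)
        acts.append(a)
    logits = acts[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    probs = expz / expz.sum(axis=1, keepdims=True)
    if not need_cache:
        return probs, None
    return probs, (cache_f, cache_b, acts)


def _backward(model, batch, probs, cache):
    """Gradient of the length-weighted cross-entropy w.r.t. all parameters."""
    p = model.params
    cache_f, cache_b, acts = cache
    H = model.config.hidden_units
    n_fc = len(model.config.fc_hidden_sizes) + 1
    grads: dict[str, np.ndarray] = {}

    dlogits = batch.weights[:, None] * (probs - batch.onehot)
    d = dlogits
    for i in reversed(range(n_fc)):
        a_in = acts[i]
        grads[f"Wfc{i}"] = a_in.T @ d
        grads[f"bfc{i}"] = d.sum(axis=0)
        d = d @ p[f"Wfc{i}"].T
        if i > 0:
            d = d * (1.0 - acts[i] ** 2)  # tanh'
    du = d
    dWx, dWh, db = _lstm_backward(du[:, :H], cache_f, p["Wx_fwd"], p["Wh_fwd"])
    grads["Wx_fwd"], grads["Wh_fwd"], grads["b_fwd"] = dWx, dWh, db
    dWx, dWh, db = _lstm_backward(du[:, H:], cache_b, p["Wx_bwd"], p["Wh_bwd"])
    grads["Wx_bwd"], grads["Wh_bwd"], grads["b_bwd"] = dWx, dWh, db
    return grads


def loss_and_gradients(
    model: AdaLSTMModel, batch: SequenceBatch
) -> tuple[float, dict[str, np.ndarray]]:
    """One forward/backward pass; exposed for gradient checking."""
    probs, cache = _forward(model, batch, need_cache=True)
    loss = weighted_cross_entropy(probs, batch)
    grads = _backward(model, batch, probs, cache)
    return loss, grads


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def _episode_sequences(episodes: Sequence[Episode]) -> list[np.ndarray]:
    return [ep.samples for ep in episodes]


def train(
    model: AdaLSTMModel,
    data: Sequence[tuple[Episode, str]],
    config: Optional[AdaLSTMConfig] = None,
) -> AdaLSTMModel:
    """Train in place; returns the model with a per-epoch loss trace.

    Sequences are sorted by length and chunked into mini-batches of
    ``batch_size``; batch order is shuffled every epoch with the seeded
    generator, so training is fully deterministic for a fixed seed.
    """
    if config is None:
        config = model.config
    if not data:
        raise ValidationError("no training data")
    labels = {lab for _, lab in data}
    if len(labels) < 2:
        raise ValidationError("training requires >= 2 classes")
    vocab = model.label_vocabulary

    episodes = [ep for ep, _ in data]
    labs = [lab for _, lab in data]
    order = np.argsort([ep.n_samples for ep in episodes], kind="stable")
    batches = []
    for start in range(0, len(order), config.batch_size):
        idx = order[start : start + config.batch_size]
        batches.append(
            SequenceBatch.from_sequences(
                [episodes[i].samples for i in idx],
                [labs[i] for i in idx],
                vocab,
            )
        )

    rng = np.random.default_rng(config.seed + 1)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    model.loss_trace = []
    for epoch in range(config.max_epochs):
        lr = config.learning_rate(epoch)
        epoch_loss = 0.0
        for bi in rng.permutation(len(batches)):
            batch = batches[bi]
            loss, grads = loss_and_gradients(model, batch)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            epoch_loss += loss
            step += 1
            for k, g in grads.items():
                m_state[k] = _BETA1 * m_state[k] + (1 - _BETA1) * g
                v_state[k] = (
                    config.squared_grad_decay * v_state[k]
                    + (1 - config.squared_grad_decay) * g**2
                )
                m_hat = m_state[k] / (1 - _BETA1**step)
                v_hat = v_state[k] / (1 - config.squared_grad_decay**step)
                model.params[k] -= lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
        model.loss_trace.append(epoch_loss)
    return model


def predict_proba(
    model: AdaLSTMModel, episodes: Sequence[Episode]
) -> np.ndarray:
    """Per-sequence class probabilities, rows summing to 1."""
    if not episodes:
        return np.zeros((0, model.config.n_classes))
    batch = SequenceBatch.from_sequences(
        _episode_sequences(episodes), None, model.label_vocabulary
    )
    probs, _ = _forward(model, batch, need_cache=False)
    return probs


def predict(model: AdaLSTMModel, episodes: Sequence[Episode]) -> list[str]:
    """Argmax posture per sequence; ties break to the earliest vocabulary
    label (argmax returns the first maximal index)."""
    probs = predict_proba(model, episodes)
    return [model.label_vocabulary[j] for j in np.argmax(probs, axis=1)]


def save_model(model: AdaLSTMModel, path: "str | Path") -> Path:
    """Checkpoint: config + vocabulary + parameters in one .npz archive."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = {k: getattr(model.config, k) for k in model.config.__dataclass_fields__}
    cfg["fc_hidden_sizes"] = list(cfg["fc_hidden_sizes"])
    np.savez(
        path,
        __meta__=np.frombuffer(
            json.dumps(
                {
                    "format_version": 1,
                    "config": cfg,
                    "label_vocabulary": list(model.label_vocabulary),
                    "loss_trace": model.loss_trace,
                }
            ).encode(),
            dtype=np.uint8,
        ),
        **model.params,
    )
    return path


def load_model(path: "str | Path") -> AdaLSTMModel:
    import json

    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["fc_hidden_sizes"] = tuple(cfg["fc_hidden_sizes"])
    model = AdaLSTMModel(
        config=AdaLSTMConfig(**cfg),
        params=params,
        label_vocabulary=tuple(meta["label_vocabulary"]),
    )
    model.loss_trace = list(meta["loss_trace"])
    return model
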