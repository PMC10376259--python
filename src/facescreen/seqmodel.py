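"""Recurrent sequence classifier over per-frame feature vectors.

A single-layer LSTM consumes one feature vector per time step; the hidden
state at the last step feeds a dense layer producing two class scores,
trained with softmax cross-entropy and Adam.  The cell uses the
two-bias-vectors-per-gate parameterization (separate input-to-hidden and
hidden-to-hidden biases), so the trainable parameter count for input size
d, hidden size h and c classes is ``4h(d+h) + 8h + hc + c``.

Implemented directly on NumPy (forward pass, backpropagation through time,
Adam) — no GPU framework is required, and tests can enumerate the exact
parameter tensors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .synthetic import Cohort, DEMENTIA, LABELS, Session

__all__ = [
    "SeqModelConfig",
    "TrainedSeqModel",
    "count_parameters",
    "subject_disjoint_split",
    "train_sequence_classifier",
    "predict_subjectwise",
    "frame_count_ablation",
]

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8
_GRAD_CLIP = 5.0


@dataclass(frozen=True)
class SeqModelConfig:
    input_dim: int
    hidden_dim: int = 32
    n_classes: int = 2
    learning_rate: float = 0.001
    batch_size: int | Literal["full"] = "full"
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden_dim", "n_classes", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size != "full" and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or 'full'")


def count_parameters(cfg: SeqModelConfig) -> int:
    """Closed-form trainable parameter count: ``4h(d+h) + 8h + hc + c``.

    Four gates, each with input-to-hidden and hidden-to-hidden weights and
    two separate bias vectors, plus the dense head with bias.
    """
    d, h, c = cfg.input_dim, cfg.hidden_dim, cfg.n_classes
    return 4 * h * (d + h) + 8 * h + h * c + c


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _LSTMParams:
    """Parameter container. Gate order within the stacked 4h axis: input,
    forget, cell, output."""

    def __init__(self, cfg: SeqModelConfig, rng: np.random.Generator):
        d, h, c = cfg.input_dim, cfg.hidden_dim, cfg.n_classes
        bound = 1.0 / np.sqrt(h)
        self.W_ih = rng.uniform(-bound, bound, size=(4 * h, d))
        self.W_hh = rng.uniform(-bound, bound, size=(4 * h, h))
        self.b_ih = np.zeros(4 * h)
        self.b_hh = np.zeros(4 * h)
        # Forget-gate bias starts at +1 total, keeping gradients alive on
        # long sequences.
        self.b_ih[h : 2 * h] = 0.5
        self.b_hh[h : 2 * h] = 0.5
        self.W_out = rng.uniform(-bound, bound, size=(h, c))
        self.b_out = np.zeros(c)

    def tensors(self) -> dict[str, np.ndarray]:
        return {
            "W_ih": self.W_ih,
            "W_hh": self.W_hh,
            "b_ih": self.b_ih,
            "b_hh": self.b_hh,
            "W_out": self.W_out,
            "b_out": self.b_out,
        }


@dataclass
class TrainedSeqModel:
    """A trained classifier: config, parameter tensors, per-epoch loss log."""

    config: SeqModelConfig
    params: _LSTMParams
    training_log: list[float] = field(default_factory=list)

    def parameters(self) -> dict[str, np.ndarray]:
        return self.params.tensors()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    def predict_proba(self, sequences: Sequence[np.ndarray]) -> np.ndarray:
        """Class probabilities per sequence, rows summing to 1."""
        logits = np.vstack([_forward(self.params, _as_batch([s]))[0] for s in sequences])
        return _softmax(logits)

    def predict(self, sequences: Sequence[np.ndarray]) -> np.ndarray:
        return self.predict_proba(sequences).argmax(axis=1)


def _as_batch(sequences: Sequence[np.ndarray]) -> np.ndarray:
    """Stack sequences into (N, T, d), truncating to the batch minimum
    length when lengths differ."""
    arrays = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    t_min = min(a.shape[0] for a in arrays)
    if t_min < 1:
        raise ValueError("sequences must contain at least one frame")
    return np.stack([a[:t_min] for a in arrays])


def _forward(p: _LSTMParams, X: np.ndarray, keep_cache: bool = False):
    """Run the cell over (N, T, d); return logits and (optionally) the
    per-step cache for backpropagation."""
    N, T, _ = X.shape
    h_size = p.W_hh.shape[1]
    h = np.zeros((N, h_size))
    c = np.zeros((N, h_size))
    bias = p.b_ih + p.b_hh
    cache = [] if keep_cache else None
    for t in range(T):
        z = X[:, t] @ p.W_ih.T + h @ p.W_hh.T + bias
        i = _sigmoid(z[:, :h_size])
        f = _sigmoid(z[:, h_size : 2 * h_size])
        g = np.tanh(z[:, 2 * h_size : 3 * h_size])
        o = _sigmoid(z[:, 3 * h_size :])
        c_prev = c
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        h_prev = h
        h = o * tanh_c
        if keep_cache:
            cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
    logits = h @ p.W_out + p.b_out
    return logits, (cache, h)


def _backward(p: _LSTMParams, X: np.ndarray, y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy loss and gradients via BPTT (loss at last step)."""
    N, T, _ = X.shape
    h_size = p.W_hh.shape[1]
    logits, (cache, h_last) = _forward(p, X, keep_cache=True)
    probs = _softmax(logits)
    loss = float(-np.log(np.clip(probs[np.arange(N), y], 1e-12, None)).mean())

    dlogits = probs.copy()
    dlogits[np.arange(N), y] -= 1.0
    dlogits /= N
    grads = {
        "W_out": h_last.T @ dlogits,
        "b_out": dlogits.sum(axis=0),
        "W_ih": np.zeros_like(p.W_ih),
        "W_hh": np.zeros_like(p.W_hh),
        "b_ih": np.zeros_like(p.b_ih),
        "b_hh": np.zeros_like(p.b_hh),
    }
    dh = dlogits @ p.W_out.T
    dc = np.zeros((N, h_size))
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tanh_c, h_prev = cache[t]
        dc = dc + dh * o * (1.0 - tanh_c**2)
        do = dh * tanh_c
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["W_ih"] += dz.T @ X[:, t]
        grads["W_hh"] += dz.T @ h_prev
        db = dz.sum(axis=0)
        grads["b_ih"] += db
        grads["b_hh"] += db
        dh = dz @ p.W_hh
        dc = dc * f
    return loss, grads


def _labels_to_int(labels: Iterable) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}")
            out.append(LABELS.index(lab))
        else:
            out.append(int(lab))
    return np.asarray(out, dtype=int)


def train_sequence_classifier(
    sequences: Sequence[np.ndarray],
    labels: Sequence,
    cfg: SeqModelConfig,
) -> TrainedSeqModel:
    """Train the recurrent classifier with Adam on softmax cross-entropy.

    ``sequences`` are (T_i, input_dim) arrays; ``labels`` are class indices
    or the cohort label strings (dementia encoded as the positive class 1).
    Deterministic given ``cfg.seed`` on a fixed platform.  Gradients are
    clipped to a global norm of 5 before each update.
    """
    if len(sequences) == 0:
        raise ValueError("training set must not be empty")
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels must align")
    arrays = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    for idx, a in enumerate(arrays):
        if a.shape[1] != cfg.input_dim:
            raise ValueError(
                f"sequence {idx} has width {a.shape[1]}, expected input_dim={cfg.input_dim}"
            )
    y = _labels_to_int(labels)
    rng = np.random.default_rng(cfg.seed)
    p = _LSTMParams(cfg, rng)
    tensors = p.tensors()
    m = {k: np.zeros_like(v) for k, v in tensors.items()}
    v = {k: np.zeros_like(t) for k, t in tensors.items()}
    step = 0
    n = len(arrays)
    batch = n if cfg.batch_size == "full" else min(int(cfg.batch_size), n)
    log: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            X = _as_batch([arrays[i] for i in idx])
            loss, grads = _backward(p, X, y[idx])
            epoch_losses.append(loss)
            gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
            if gnorm > _GRAD_CLIP:
                grads = {k: g * (_GRAD_CLIP / gnorm) for k, g in grads.items()}
            step += 1
            for k, tensor in tensors.items():
                m[k] = _ADAM_BETA1 * m[k] + (1 - _ADAM_BETA1) * grads[k]
                v[k] = _ADAM_BETA2 * v[k] + (1 - _ADAM_BETA2) * grads[k] ** 2
                m_hat = m[k] / (1 - _ADAM_BETA1**step)
                v_hat = v[k] / (1 - _ADAM_BETA2**step)
                tensor -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
        log.append(float(np.mean(epoch_losses)))
    return TrainedSeqModel(cfg, p, log)


def predict_subjectwise(
    model: TrainedSeqModel, sequences: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence class probabilities (rows sum to 1) and argmax labels."""
    arrays = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    for idx, a in enumerate(arrays):
        if a.shape[1] != model.config.input_dim:
            raise ValueError(
                f"sequence {idx} has width {a.shape[1]}, expected "
                f"input_dim={model.config.input_dim}"
            )
    probs = model.predict_proba(arrays)
    return probs, probs.argmax(axis=1)


def subject_disjoint_split(
    cohort: Cohort, test_fraction: float, seed: int
) -> tuple[list[Session], list[Session]]:
    """Split sessions by subject with balanced per-class test counts.

    Every session of a test subject lands in the test set; per-class test
    subject counts differ by at most one; deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[str]] = {}
    for subject, label in sorted(cohort.subject_labels.items()):
        per_class.setdefault(label, []).append(subject)
    if len(per_class) < 2 or any(len(v) < 2 for v in per_class.values()):
        raise ValueError("need at least 2 subjects in each of the two classes")
    counts = {
        label: max(1, round(test_fraction * len(subjects)))
        for label, subjects in per_class.items()
    }
    # Balance: test-side class counts may differ by at most 1.
    floor = min(counts.values())
    counts = {label: min(c, floor + 1) for label, c in counts.items()}
    test_subjects: set[str] = set()
    for label, subjects in per_class.items():
        if counts[label] >= len(subjects):
            raise ValueError(f"test fraction leaves no training subjects for class {label!r}")
        picked = rng.choice(subjects, size=counts[label], replace=False)
        test_subjects.update(picked.tolist())
    train = [s for s in cohort if s.subject_id not in test_subjects]
    test = [s for s in cohort if s.subject_id in test_subjects]
    return train, test


def _session_features(session: Session, stream: str) -> np.ndarray:
    value = getattr(session, stream)
    if value is None:
        raise ValueError(f"session {session.session_id!r} lacks the {stream!r} stream")
    return value.values if hasattr(value, "values") else np.asarray(value)


def frame_count_ablation(
    cohort: Cohort,
    frame_counts: Sequence[int],
    cfg: SeqModelConfig,
    feature_fn=None,
    test_fraction: float = 0.3,
    split_seed: int = 0,
) -> dict[int, float]:
    """Train/evaluate the classifier using only the first ``n`` frames.

    For each requested count, every session's feature sequence is truncated
    to its first ``n`` frames, a model is trained on the subject-disjoint
    training split and session-level accuracy is measured on the test
    split.  ``feature_fn`` maps a session to its (T, input_dim) features
    (default: the appearance stream).
    """
    if feature_fn is None:
        feature_fn = lambda s: _session_features(s, "appearance")  # noqa: E731
    train, test = subject_disjoint_split(cohort, test_fraction, split_seed)
    train_feats = [feature_fn(s) for s in train]
    test_feats = [feature_fn(s) for s in test]
    min_len = min(a.shape[0] for a in train_feats + test_feats)
    results: dict[int, float] = {}
    for n in frame_counts:
        if n < 1 or n > min_len:
            raise ValueError(f"frame count {n} outside the available range [1, {min_len}]")
        model = train_sequence_classifier(
            [a[:n] for a in train_feats], [s.label for s in train], cfg
        )
        _, pred = predict_subjectwise(model, [a[:n] for a in test_feats])
        truth = _labels_to_int([s.label for s in test])
        results[int(n)] = float((pred == truth).mean())
    return results


def model_to_dict(model: TrainedSeqModel) -> dict:
    """JSON-serializable checkpoint: config, parameters, training log."""
    return {
        "config": dataclasses.asdict(model.config),
        "parameters": {k: v.tolist() for k, v in model.parameters().items()},
        "training_log": model.training_log,
    }
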