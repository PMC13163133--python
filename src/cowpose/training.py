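"""Class-prior debiased training of the behavior classifier.

Long-tailed behavior data biases a plain cross-entropy classifier toward
majority classes. Logit adjustment counteracts this at training time by
adding ``tau * log(pi_c)`` to the raw logit of every class before the
softmax, where ``pi_c = n_c / N`` is the class prior estimated from the
*training split only* (validation and test are never read, so no leakage).
Minimizing the resulting cross-entropy shifts the learned decision boundary
toward the minority classes; at inference the raw, unadjusted logits are
used, so the correction costs nothing at deployment.

The training loop follows the fixed protocol: AdamW (lr 1e-3, weight decay
1e-4), batch size 8, up to 40 epochs, with the checkpoint chosen as the
epoch that maximizes validation Macro-F1. Everything is seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import macro_f1_from_labels
from .network import BehaviorNet, predict_logits
from .skeleton import BEHAVIORS, DatasetManifest


@dataclass(frozen=True)
class ClassPriors:
    """Training-split class frequencies ``pi_c = n_c / N`` in canonical order."""

    counts: tuple[int, int, int]
    total: int
    priors: tuple[float, float, float]

    @classmethod
    def from_counts(cls, counts) -> "ClassPriors":
        counts = tuple(int(c) for c in counts)
        if len(counts) != 3:
            raise ValueError("exactly 3 class counts required")
        if any(c <= 0 for c in counts):
            raise ValueError(f"every class must be present in train, got {counts}")
        total = sum(counts)
        return cls(counts=counts, total=total, priors=tuple(c / total for c in counts))

    @property
    def log_priors(self) -> np.ndarray:
        return np.log(np.asarray(self.priors))


def compute_class_priors(manifest: DatasetManifest) -> ClassPriors:
    """Estimate priors from the manifest's train split only."""
    counts = manifest.class_counts.get("train")
    if counts is None:
        raise ValueError("manifest has no train split")
    return ClassPriors.from_counts(counts)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def adjust_logits(z: np.ndarray, priors: ClassPriors, tau: float) -> np.ndarray:
    """``z'_c = z_c + tau * log(pi_c)`` (elementwise along the class axis)."""
    return np.asarray(z, dtype=float) + tau * priors.log_priors


def adjusted_probabilities(z: np.ndarray, priors: ClassPriors, tau: float) -> np.ndarray:
    """The post-adjustment softmax probabilities (exposed for inspection)."""
    return softmax(adjust_logits(z, priors, tau))


def logit_adjusted_loss(z: np.ndarray, labels, priors: ClassPriors, tau: float) -> float:
    """Cross-entropy of the adjusted-logit softmax at the true label(s).

    Accepts a single logit vector with an integer/str label or a batch of
    logits with an integer label array; returns the mean loss.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    labels = np.atleast_1d(labels)
    if labels.dtype.kind in "US":
        labels = np.array([BEHAVIORS.index(l) for l in labels])
    za = adjust_logits(z, priors, tau)
    logp = za - _logsumexp(za)
    return float(-logp[np.arange(len(labels)), labels].mean())


def _logsumexp(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the fixed training recipe."""

    tau: float = 1.0
    lr: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 40
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.wd * p.data)


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_macro_f1: float
    history: list[dict] = field(default_factory=list)


def train(
    model: BehaviorNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    priors: ClassPriors,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Fit the classifier with the logit-adjusted loss; return the best epoch.

    ``train_data`` / ``val_data`` are ``(X, y)`` with ``X`` of shape
    ``(N, 46, H, W)`` float32 and integer labels ``y``. The checkpoint kept
    is the epoch argmax of validation Macro-F1 (ties to the earlier epoch).
    Validation always scores *raw* logits: the prior term exists only inside
    the training loss. Raises on divergence (non-finite loss).
    """
    x_train, y_train = train_data
    y_train = np.asarray(y_train)
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    shift = (config.tau * priors.log_priors).astype(x_train.dtype)

    best_state: dict[str, np.ndarray] | None = None
    best_f1 = -1.0
    best_epoch = -1
    history: list[dict] = []
    n = len(x_train)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            z = model.forward(xb, train=True)
            za = z + shift
            za64 = za.astype(np.float64)
            logp = za64 - _logsumexp(za64)
            loss = float(-logp[np.arange(len(yb)), yb].mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss {loss}"
                )
            p = np.exp(logp)
            p[np.arange(len(yb)), yb] -= 1.0
            model.backward((p / len(yb)).astype(xb.dtype))
            opt.step()
            epoch_loss += loss * len(yb)
        val_f1 = evaluate_macro_f1(model, val_data)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_macro_f1": val_f1}
        )
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_epoch = epoch
            best_state = model.state_dict()

    assert best_state is not None
    model.load_state_dict(best_state)
    return TrainResult(
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_macro_f1=best_f1,
        history=history,
    )


def evaluate_macro_f1(model: BehaviorNet, data: tuple[np.ndarray, np.ndarray]) -> float:
    """Raw-logit Macro-F1 of a model on an (X, y) split."""
    x, y = data
    preds = predict_logits(model, x).argmax(axis=1)
    return macro_f1_from_labels(np.asarray(y), preds)


def write_training_log(history: list[dict], path) -> None:
    """CSV log: epoch, train loss, validation Macro-F1."""
    lines = ["epoch,train_loss,val_macro_f1"]
    for row in history:
        lines.append(f"{row['epoch']},{row['train_loss']:.6f},{row['val_macro_f1']:.6f}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
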