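"""Knowledge distillation of the AB ensemble teacher into one student.

The five-member ensemble teacher is accurate but costs five forward passes
per frame. Distillation transfers its behavior to a single student of the
same lightweight architecture: the student minimizes

``L = (1 - lambda) * CE(softmax(z_s), y) + lambda * T^2 * KL(p_t || p_s)``

where ``p_t = softmax(z_t / T)`` and ``p_s = softmax(z_s / T)`` are the
temperature-softened teacher and student distributions. The ``T^2`` factor
keeps the soft-target gradient magnitude comparable across temperatures
(the KL gradient alone shrinks as ``1/T``); the teacher term is a constant
for optimization — gradients flow only through the student logits. The
hard-label cross-entropy uses the *unsoftened* student logits (T = 1).

The student trains without logit adjustment: the teacher's averaged logits
already encode the debiased decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble import average_logits
from .metrics import macro_f1_from_labels
from .network import BehaviorNet, ModelSpec, build_model, predict_logits
from .training import AdamW, TrainConfig, TrainResult, _logsumexp, softmax


@dataclass(frozen=True)
class KDConfig:
    temperature: float = 4.0
    lam: float = 0.7
    student_seed: int = 0
    train: TrainConfig = TrainConfig()

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must be in [0, 1]")


def soften(z: np.ndarray, temperature: float) -> np.ndarray:
    """Temperature-softened distribution ``softmax(z / T)``."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return softmax(np.asarray(z, dtype=float) / temperature)


def kd_loss(z_t: np.ndarray, z_s: np.ndarray, temperature: float) -> float:
    """``T^2 * KL(soften(z_t, T) || soften(z_s, T))`` (mean over a batch).

    Finite for all inputs because softmax outputs are strictly positive.
    """
    p_t = np.atleast_2d(soften(z_t, temperature))
    z_s = np.atleast_2d(np.asarray(z_s, dtype=float)) / temperature
    log_p_s = z_s - _logsumexp(z_s)
    kl = (p_t * (np.log(p_t) - log_p_s)).sum(axis=-1)
    return float(temperature**2 * kl.mean())


def combined_loss(
    z_s: np.ndarray, z_t: np.ndarray, labels, config: KDConfig
) -> float:
    """``(1 - lambda) * CE + lambda * kd_loss`` (CE at T = 1 on raw student logits)."""
    z_s2 = np.atleast_2d(np.asarray(z_s, dtype=float))
    labels = np.atleast_1d(labels)
    logp = z_s2 - _logsumexp(z_s2)
    ce = float(-logp[np.arange(len(labels)), labels].mean())
    return (1 - config.lam) * ce + config.lam * kd_loss(z_t, z_s, config.temperature)


def _combined_grad(
    z_s: np.ndarray, p_t: np.ndarray, y_onehot: np.ndarray, config: KDConfig
) -> np.ndarray:
    """Analytic gradient of :func:`combined_loss` w.r.t. the student logits.

    d/dz_s of the T^2-scaled KL term is ``T * (softmax(z_s/T) - p_t)``.
    """
    lam, t = config.lam, config.temperature
    # exp(log-softmax) mirrors the supervised loop bit-for-bit at lam = 0
    p_hard = np.exp(z_s - _logsumexp(z_s))
    grad = (1 - lam) * (p_hard - y_onehot)
    grad += lam * t * (soften(z_s, t) - p_t)
    return grad / len(z_s)


@dataclass
class DistillResult:
    student: BehaviorNet
    train_result: TrainResult
    teacher_cost_multiplier: int
    student_cost_multiplier: int = 1


def distill_student(
    teacher_members: list[BehaviorNet],
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    config: KDConfig = KDConfig(),
    model_spec: ModelSpec | None = None,
) -> DistillResult:
    """Train a single student against the ensemble teacher's soft targets.

    Teacher logits (the member average) are computed once per training
    sample up front, so student epochs never re-run the teacher. Checkpoint
    selection mirrors supervised training: the epoch with the best
    validation Macro-F1 (raw student logits, hard labels).
    """
    x_train, y_train = data["train"]
    y_train = np.asarray(y_train)
    spec = model_spec or teacher_members[0].spec
    z_teacher = average_logits([predict_logits(m, x_train) for m in teacher_members])
    p_t_all = soften(z_teacher, config.temperature)

    student = build_model(spec, seed=config.student_seed)
    tc = config.train
    rng = np.random.default_rng(config.student_seed)
    opt = AdamW(student.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    onehot = np.eye(spec.n_classes)[y_train]

    best_state = None
    best_f1, best_epoch = -1.0, -1
    history: list[dict] = []
    n = len(x_train)
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = x_train[idx]
            student.zero_grad()
            z = student.forward(xb, train=True).astype(np.float64)
            loss = combined_loss(z, z_teacher[idx], y_train[idx], config)
            if not np.isfinite(loss):
                raise RuntimeError(f"distillation diverged at epoch {epoch}")
            grad = _combined_grad(z, p_t_all[idx], onehot[idx], config)
            student.backward(grad.astype(xb.dtype))
            opt.step()
            epoch_loss += loss * len(idx)
        xv, yv = data["val"]
        val_f1 = macro_f1_from_labels(
            np.asarray(yv), predict_logits(student, xv).argmax(axis=1)
        )
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_macro_f1": val_f1}
        )
        if val_f1 > best_f1:
            best_f1, best_epoch = val_f1, epoch
            best_state = student.state_dict()

    assert best_state is not None
    student.load_state_dict(best_state)
    return DistillResult(
        student=student,
        train_result=TrainResult(
            best_state=best_state,
            best_epoch=best_epoch,
            best_val_macro_f1=best_f1,
            history=history,
        ),
        teacher_cost_multiplier=len(teacher_members),
    )
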