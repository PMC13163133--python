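"""Multi-random-seed logits ensembling and the A / B / AB configurations.

With limited data, single networks fluctuate with initialization and
shuffling randomness. Training M otherwise-identical models that differ
only in their random seed and *averaging their logits* (then softmaxing the
mean) suppresses these incidental errors. Averaging happens in logit
space, not probability space — the two are not equivalent, and the logit
mean is the definition used here.

Configuration names:

* ``baseline`` — one model, plain cross-entropy (tau = 0);
* ``A``        — M-seed logits ensemble of baseline members;
* ``B``        — one model trained with logit adjustment (tau > 0);
* ``AB``       — M-seed ensemble of logit-adjusted members (the teacher
  handed to knowledge distillation).

Single-model configurations are summarized as mean ± sd of Macro-F1 over
the member seeds; ensembles yield one number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import macro_f1_from_labels
from .network import BehaviorNet, ModelSpec, build_model, predict_logits
from .training import ClassPriors, TrainConfig, TrainResult, softmax, train

DEFAULT_MEMBER_SEEDS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class EnsembleConfig:
    m: int = 5
    member_seeds: tuple[int, ...] = DEFAULT_MEMBER_SEEDS
    training_mode: str = "baseline"  # or "logit_adjust"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("M must be >= 1")
        if len(self.member_seeds) != self.m:
            raise ValueError("need exactly M member seeds")
        if len(set(self.member_seeds)) != self.m:
            raise ValueError("member seeds must be distinct")
        if self.training_mode not in ("baseline", "logit_adjust"):
            raise ValueError(f"unknown training_mode {self.training_mode!r}")


def average_logits(members: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise arithmetic mean of member logit arrays."""
    members = list(np.asarray(m, dtype=float) for m in members)
    if not members:
        raise ValueError("empty member list")
    shapes = {m.shape for m in members}
    if len(shapes) != 1:
        raise ValueError(f"member logits disagree in shape: {shapes}")
    return np.mean(members, axis=0)


def ensemble_predict(
    members: list[BehaviorNet], x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class and probabilities from the averaged logits.

    All members must share the same :class:`ModelSpec`. Ties in the argmax
    resolve to the lowest class index (numpy's convention), which keeps the
    decision deterministic.
    """
    specs = {m.spec for m in members}
    if len(specs) != 1:
        raise ValueError("ensemble members must share a ModelSpec")
    z = average_logits([predict_logits(m, x) for m in members])
    p = softmax(z)
    return p.argmax(axis=1), p


@dataclass
class Configuration:
    """A trained, evaluable predictor for one strategy arm."""

    name: str
    members: list[BehaviorNet]
    member_results: list[TrainResult]
    tau: float
    is_ensemble: bool

    @property
    def inference_cost_multiplier(self) -> int:
        return len(self.members) if self.is_ensemble else 1

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        if self.is_ensemble:
            return average_logits([predict_logits(m, x) for m in self.members])
        return predict_logits(self.members[0], x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_logits(x).argmax(axis=1)

    def member_macro_f1s(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-member single-model Macro-F1 (for mean ± sd reporting)."""
        return np.array(
            [
                macro_f1_from_labels(y, predict_logits(m, x).argmax(axis=1))
                for m in self.members
            ]
        )


def build_configuration(
    name: str,
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    priors: ClassPriors,
    seeds: tuple[int, ...] = DEFAULT_MEMBER_SEEDS,
    model_spec: ModelSpec = ModelSpec(),
    train_config: TrainConfig = TrainConfig(),
) -> Configuration:
    """Train one of the {baseline, A, B, AB} strategy arms.

    ``data`` maps split names to ``(X, y)``. Single-model arms (baseline,
    B) still train all listed seeds so that mean ± sd can be reported, but
    predict with the first seed's model; ensemble arms (A, AB) average all
    member logits. B and AB train with the configured tau; baseline and A
    force tau = 0.
    """
    if name not in ("baseline", "A", "B", "AB"):
        raise ValueError(f"unknown configuration {name!r}")
    tau = train_config.tau if name in ("B", "AB") else 0.0
    is_ensemble = name in ("A", "AB")
    members: list[BehaviorNet] = []
    results: list[TrainResult] = []
    for seed in seeds:
        model = build_model(model_spec, seed=seed)
        cfg = replace(train_config, tau=tau, seed=seed)
        results.append(train(model, data["train"], data["val"], priors, cfg))
        members.append(model)
    return Configuration(
        name=name, members=members, member_results=results, tau=tau,
        is_ensemble=is_ensemble,
    )
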