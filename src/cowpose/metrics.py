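"""Evaluation: confusion analysis, Macro-F1, bootstrap CIs, PCK, reports.

Per-class precision, recall and F1 are read off the 3x3 confusion matrix
(rows = true class, columns = predicted class, canonical order stand /
walk / lying); 0/0 ratios are 0 by convention in point estimates. Macro-F1
— the unweighted mean of the three per-class F1 scores — is the primary
metric throughout the package. ``key_confusion`` isolates the stand-walk
off-diagonal mass, the dominant error mode of frame-level behavior
recognition.

Uncertainty for small classes is quantified with a seeded percentile
bootstrap over test samples (default B = 20,000 resamples, 95 % level);
resamples where a metric is undefined (0/0) are skipped rather than scored
as zero, so the convention cannot bias the interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton import BEHAVIORS, PoseInstance

N_CLASSES = 3
_METRICS = ("precision", "recall", "f1")


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("labels and predictions must be aligned")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf1(cm: np.ndarray, cls: int) -> tuple[float, float, float]:
    """(precision, recall, F1) for one class; 0/0 ratios return 0."""
    tp = int(cm[cls, cls])
    fp = int(cm[:, cls].sum() - tp)
    fn = int(cm[cls, :].sum() - tp)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, f1_from_pr(precision, recall)


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1 over all classes."""
    return float(np.mean([prf1(cm, c)[2] for c in range(cm.shape[0])]))


def macro_f1_from_labels(y_true, y_pred) -> float:
    return macro_f1(confusion_matrix(y_true, y_pred))


def key_confusion(cm: np.ndarray) -> int:
    """Total stand<->walk off-diagonal confusion (the dominant error mode)."""
    return int(cm[0, 1] + cm[1, 0])


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals

@dataclass(frozen=True)
class BootstrapConfig:
    b: int = 20_000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


def bootstrap_ci(
    y_true,
    y_pred,
    cls: int,
    metric: str,
    config: BootstrapConfig = BootstrapConfig(),
) -> tuple[float, float, float]:
    """Percentile bootstrap ``(point, lo, hi)`` for one per-class metric.

    Test indices are resampled with replacement B times; the metric is
    recomputed per resample, resamples with an undefined (0/0) value are
    skipped, and the interval is the (2.5 %, 97.5 %) percentile pair at the
    default level. Deterministic given the seed.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if cls not in y_true:
        raise ValueError(f"class {cls} absent from labels")

    point = dict(zip(_METRICS, prf1(confusion_matrix(y_true, y_pred), cls)))[metric]

    tp = ((y_true == cls) & (y_pred == cls)).astype(np.int64)
    fp = ((y_true != cls) & (y_pred == cls)).astype(np.int64)
    fn = ((y_true == cls) & (y_pred != cls)).astype(np.int64)
    n = len(y_true)
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.b, n))
    TP = tp[idx].sum(axis=1)
    FP = fp[idx].sum(axis=1)
    FN = fn[idx].sum(axis=1)

    if metric == "precision":
        denom = TP + FP
        num = TP
    elif metric == "recall":
        denom = TP + FN
        num = TP
    else:  # f1
        denom = 2 * TP + FP + FN
        num = 2 * TP
    valid = denom > 0
    values = num[valid] / denom[valid]
    if values.size == 0:
        return float(point), float(point), float(point)
    alpha = (1 - config.level) / 2
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# PCK for the pose stage

def pck(
    predicted: list[np.ndarray],
    truth: list[PoseInstance],
    alpha: float,
) -> float:
    """Percentage of correct keypoints at threshold ``alpha``.

    A visible truth keypoint counts as correct when the prediction lies
    within ``alpha`` times the normalization length — the diagonal of the
    visible-truth-keypoint bounding box. Per-sample fractions are averaged
    over samples; samples without visible keypoints are skipped with a
    warning.
    """
    import warnings

    fractions = []
    for pred, inst in zip(predicted, truth):
        vis = inst.visibility
        if not vis.any():
            warnings.warn(f"{inst.sample_id}: no visible keypoints, skipped", stacklevel=2)
            continue
        pts = inst.keypoints[vis]
        span = pts.max(axis=0) - pts.min(axis=0)
        norm = float(np.hypot(*span))
        if norm == 0:
            norm = 1.0
        dist = np.linalg.norm(np.asarray(pred)[vis] - pts, axis=1)
        fractions.append(float((dist <= alpha * norm).mean()))
    if not fractions:
        raise ValueError("no samples with visible keypoints")
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# Report assembly

@dataclass
class EvalReport:
    """Everything reported for one evaluated configuration."""

    name: str
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro_f1: float
    key_confusion: int
    n_params: int | None = None
    fp32_mebibytes: float | None = None
    inference_cost_multiplier: int = 1
    macro_f1_sd: float | None = None
    bootstrap: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro_f1": self.macro_f1,
            "key_confusion": self.key_confusion,
            "n_params": self.n_params,
            "fp32_mebibytes": self.fp32_mebibytes,
            "inference_cost_multiplier": self.inference_cost_multiplier,
            "macro_f1_sd": self.macro_f1_sd,
            "bootstrap": self.bootstrap,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        d = dict(d)
        d["confusion"] = np.asarray(d["confusion"], dtype=int)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def confusion_csv(self, path) -> None:
        lines = ["true\\pred," + ",".join(BEHAVIORS)]
        for i, b in enumerate(BEHAVIORS):
            lines.append(b + "," + ",".join(map(str, self.confusion[i])))
        Path(path).write_text("\n".join(lines) + "\n")


def assemble_report(
    y_true,
    y_pred,
    name: str = "model",
    n_params: int | None = None,
    inference_cost_multiplier: int = 1,
    macro_f1_sd: float | None = None,
    bootstrap_classes: tuple[int, ...] = (),
    bootstrap_config: BootstrapConfig | None = None,
    notes: dict | None = None,
) -> EvalReport:
    """Build the full :class:`EvalReport` from aligned labels/predictions."""
    cm = confusion_matrix(y_true, y_pred)
    per_class = {}
    for c, b in enumerate(BEHAVIORS):
        p, r, f = prf1(cm, c)
        per_class[b] = {"precision": p, "recall": r, "f1": f}
    boot: dict[str, dict[str, list[float]]] = {}
    if bootstrap_classes:
        cfg = bootstrap_config or BootstrapConfig()
        for c in bootstrap_classes:
            boot[BEHAVIORS[c]] = {
                m: list(bootstrap_ci(y_true, y_pred, c, m, cfg)) for m in _METRICS
            }
    all_notes = {"pck_normalization": "visible-truth bounding-box diagonal"}
    all_notes.update(notes or {})
    return EvalReport(
        name=name,
        confusion=cm,
        per_class=per_class,
        macro_f1=macro_f1(cm),
        key_confusion=key_confusion(cm),
        n_params=n_params,
        fp32_mebibytes=None if n_params is None else 4 * n_params / 2**20,
        inference_cost_multiplier=inference_cost_multiplier,
        macro_f1_sd=macro_f1_sd,
        bootstrap=boot,
        notes=all_notes,
    )


def report_markdown(reports: list[EvalReport]) -> str:
    """A compact Markdown comparison table over configurations."""
    lines = [
        "| Method | Macro-F1 | key stand-walk confusion | Inference cost |",
        "|---|---|---|---|",
    ]
    for r in reports:
        f1 = f"{r.macro_f1:.4f}"
        if r.macro_f1_sd is not None:
            f1 += f" ± {r.macro_f1_sd:.4f}"
        lines.append(
            f"| {r.name} | {f1} | {r.key_confusion} | {r.inference_cost_multiplier}x |"
        )
    return "\n".join(lines) + "\n"
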