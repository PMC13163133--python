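"""Scripted end-to-end experiments on synthetic data.

Two studies are provided: the strategy ablation (baseline / A / B / AB with
an ensemble-size sweep) and the deployment comparison (B-single vs the AB
ensemble teacher vs the distilled student, with inference-cost
multipliers). Both run entirely on the synthetic benchmark and write JSON
plus a Markdown summary, together with a resolved-configuration manifest
sufficient to replay the run.

CPU footprint: the default ``benchmark_config`` uses a 12 x 12 pose grid
(input side 96 at stride 8), a narrow variant of the classifier
(16/32/64 channels, 32 hidden units) and 4 epochs at batch 32, sizes at
which a full ablation completes in minutes on one core. The behavioral
conclusions these runs support (debiasing helps the minority class,
ensembles cut variance, the student lands between single and teacher) are
scale-free; the architecture-pinned complexity figures always use the full
default :class:`~cowpose.network.ModelSpec`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .distill import KDConfig, distill_student
from .ensemble import Configuration, build_configuration
from .metrics import assemble_report, report_markdown
from .network import ModelSpec, build_model, count_parameters
from .render import RenderConfig, render_instance
from .skeleton import BEHAVIORS, DatasetManifest
from .synthetic import SyntheticConfig, generate_dataset
from .training import ClassPriors, TrainConfig, compute_class_priors

#: Narrow classifier used by the CPU benchmark runs.
BENCH_MODEL_SPEC = ModelSpec(block_channels=(16, 32, 64), fc_hidden=32)
#: 12 x 12 grid = 96-px letterbox side at stride 8.
BENCH_RENDER = RenderConfig(grid_size=(12, 12), sigma=1.0, limb_width=1.0, input_side=96)
BENCH_TRAIN = TrainConfig(batch_size=32, max_epochs=4)


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration for one experiment run."""

    synthetic: SyntheticConfig = SyntheticConfig()
    render: RenderConfig = BENCH_RENDER
    crop_margin: float = 0.125
    model_spec: ModelSpec = BENCH_MODEL_SPEC
    train: TrainConfig = BENCH_TRAIN
    kd: KDConfig = KDConfig(train=BENCH_TRAIN)
    member_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["member_seeds"] = list(self.member_seeds)
        return d


def benchmark_config(seed: int = 0) -> ExperimentConfig:
    """Default benchmark: split-structured synthetic data, reduced grid/model.

    The global seed derives the data seed and offsets the member / student
    seeds so that different global seeds give fully disjoint randomness.
    """
    base = seed * 1009 % (2**31 - 7)
    return ExperimentConfig(
        synthetic=SyntheticConfig(seed=base),
        train=replace(BENCH_TRAIN, seed=base),
        kd=KDConfig(train=BENCH_TRAIN, student_seed=base + 50),
        member_seeds=tuple(base + i for i in range(5)),
        seed=seed,
    )


def render_dataset(
    manifest: DatasetManifest,
    render_config: RenderConfig = BENCH_RENDER,
    crop_margin: float | None = 0.125,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Render every record; returns ``{split: (X, y)}`` with float32 tensors."""
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for split in ("train", "val", "test"):
        recs = manifest.subset(split)
        if not recs:
            continue
        x = np.stack([render_instance(r, render_config, crop_margin) for r in recs])
        y = np.array([BEHAVIORS.index(r.label) for r in recs])
        data[split] = (x, y)
    return data


def prepare_benchmark(
    config: ExperimentConfig,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], ClassPriors, DatasetManifest]:
    manifest = generate_dataset(config.synthetic)
    data = render_dataset(manifest, config.render, config.crop_margin)
    priors = compute_class_priors(manifest)
    return data, priors, manifest


def _evaluate_arm(
    arm: Configuration, data, n_params: int
) -> dict:
    x_test, y_test = data["test"]
    preds = arm.predict(x_test)
    report = assemble_report(
        y_test,
        preds,
        name=arm.name,
        n_params=n_params,
        inference_cost_multiplier=arm.inference_cost_multiplier,
    )
    if not arm.is_ensemble:
        member_f1 = arm.member_macro_f1s(x_test, y_test)
        report.macro_f1 = float(member_f1.mean())
        report.macro_f1_sd = float(member_f1.std(ddof=1))
    return {"configuration": arm, "report": report}


def run_ablation(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Baseline / A / B / AB comparison plus the M in {1, 3, 5} sweep.

    A and AB reuse the members trained for baseline and B (the ensemble is
    an inference-time construct over the same five seed models), so the
    whole study trains 2 x 5 networks. Arms fail independently: an error in
    one arm is logged in the output and the others still report.
    """
    data, priors, manifest = prepare_benchmark(config)
    n_params, _ = count_parameters(build_model(config.model_spec))
    results: dict = {"config": config.to_dict(), "rows": {}, "sweep": {}, "errors": {}}
    arms: dict[str, Configuration] = {}
    x_test, y_test = data["test"]

    for base_arm, ens_arm in (("baseline", "A"), ("B", "AB")):
        try:
            cfg = build_configuration(
                ens_arm, data, priors, config.member_seeds,
                config.model_spec, config.train,
            )
        except Exception as exc:  # pragma: no cover - partial-failure path
            results["errors"][base_arm] = results["errors"][ens_arm] = repr(exc)
            continue
        single = Configuration(
            name=base_arm, members=cfg.members, member_results=cfg.member_results,
            tau=cfg.tau, is_ensemble=False,
        )
        arms[base_arm], arms[ens_arm] = single, cfg
        results["rows"][base_arm] = _evaluate_arm(single, data, n_params)["report"].to_dict()
        results["rows"][ens_arm] = _evaluate_arm(cfg, data, n_params)["report"].to_dict()
        # Ensemble-size sweep over leading member subsets.
        from .ensemble import average_logits
        from .metrics import macro_f1_from_labels
        from .network import predict_logits

        member_logits = [predict_logits(m, x_test) for m in cfg.members]
        for m in (1, 3, 5):
            z = average_logits(member_logits[:m])
            results["sweep"][f"{ens_arm}_M{m}"] = macro_f1_from_labels(
                y_test, z.argmax(axis=1)
            )

    results["_arms"] = arms  # live objects for callers; stripped before writing
    if out_dir is not None:
        _write_outputs(results, Path(out_dir), "ablation")
    return results


def run_deployment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    arms: dict[str, Configuration] | None = None,
) -> dict:
    """B-single vs AB-teacher vs KD-student with cost multipliers (1x/5x/1x)."""
    data, priors, manifest = prepare_benchmark(config)
    n_params, _ = count_parameters(build_model(config.model_spec))
    if arms is None or "AB" not in arms:
        ab = build_configuration(
            "AB", data, priors, config.member_seeds, config.model_spec, config.train
        )
    else:
        ab = arms["AB"]
    b_single = Configuration(
        name="B-single", members=ab.members, member_results=ab.member_results,
        tau=ab.tau, is_ensemble=False,
    )
    kd = distill_student(ab.members, data, config.kd, config.model_spec)

    x_test, y_test = data["test"]
    results: dict = {"config": config.to_dict(), "rows": {}}
    results["rows"]["B-single"] = _evaluate_arm(b_single, data, n_params)["report"].to_dict()
    ab_report = _evaluate_arm(ab, data, n_params)["report"]
    ab_report.name = "AB-teacher"
    results["rows"]["AB-teacher"] = ab_report.to_dict()
    student_preds = kd.student.forward(x_test).argmax(axis=1)
    student_report = assemble_report(
        y_test, student_preds, name="KD-student",
        n_params=count_parameters(kd.student)[0],
        inference_cost_multiplier=kd.student_cost_multiplier,
    )
    results["rows"]["KD-student"] = student_report.to_dict()
    results["_student"] = kd.student
    results["_ab"] = ab
    if out_dir is not None:
        _write_outputs(results, Path(out_dir), "deployment")
    return results


def deployment_replicate(
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    priors: ClassPriors,
    member_seeds: tuple[int, ...],
    student_seed: int,
    model_spec: ModelSpec = BENCH_MODEL_SPEC,
    train_config: TrainConfig = BENCH_TRAIN,
    kd_config: KDConfig | None = None,
) -> dict:
    """One teacher/student replicate on pre-rendered data.

    Trains the five logit-adjusted members, forms the AB ensemble, distills
    a student, and returns test Macro-F1 of every piece: ``member_f1s``
    (each member scored as a single model — the first one is the B-single
    arm), ``ab_f1`` and ``student_f1``. Used by the replicated variance /
    ordering studies, which rerun this with disjoint seed pools.
    """
    from .network import predict_logits

    ab = build_configuration(
        "AB", data, priors, member_seeds, model_spec, train_config
    )
    x_test, y_test = data["test"]
    member_f1s = ab.member_macro_f1s(x_test, y_test)
    from .metrics import macro_f1_from_labels

    ab_f1 = macro_f1_from_labels(y_test, ab.predict(x_test))
    kd_cfg = kd_config or KDConfig(train=train_config)
    kd_cfg = replace(kd_cfg, student_seed=student_seed)
    kd = distill_student(ab.members, data, kd_cfg, model_spec)
    student_f1 = macro_f1_from_labels(
        y_test, predict_logits(kd.student, x_test).argmax(axis=1)
    )
    return {
        "member_f1s": member_f1s,
        "ab_f1": float(ab_f1),
        "student_f1": float(student_f1),
    }


def _write_outputs(results: dict, out_dir: Path, stem: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {k: v for k, v in results.items() if not k.startswith("_")}
    (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=2))
    from .metrics import EvalReport

    reports = [EvalReport.from_dict(r) for r in payload["rows"].values()]
    md = report_markdown(reports)
    if payload.get("sweep"):
        md += "\nEnsemble-size sweep (test Macro-F1):\n\n"
        md += "| cell | Macro-F1 |\n|---|---|\n"
        for k, v in payload["sweep"].items():
            md += f"| {k} | {v:.4f} |\n"
    (out_dir / f"{stem}.md").write_text(md)
    (out_dir / f"{stem}_config.json").write_text(json.dumps(payload["config"], indent=2))
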