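"""Confusion-matrix metrics, bootstrap CIs, PCK and report assembly.

scikit-learn serves as the independent oracle for the precision / recall /
F1 arithmetic; the bootstrap and PCK are checked against their defining
properties.
"""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from cowpose.metrics import (
    BootstrapConfig,
    EvalReport,
    assemble_report,
    bootstrap_ci,
    confusion_matrix,
    f1_from_pr,
    key_confusion,
    macro_f1,
    macro_f1_from_labels,
    pck,
    prf1,
    report_markdown,
)
from cowpose.skeleton import PoseInstance

from conftest import make_instance


def random_labels(rng, n=200):
    return rng.integers(0, 3, size=n), rng.integers(0, 3, size=n)


class TestPRF1:
    def test_f1_is_harmonic_mean_of_printed_precision_recall(self):
        assert round(f1_from_pr(0.8095, 0.8947), 4) == 0.8500

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(10):
            y, yhat = random_labels(rng)
            cm = confusion_matrix(y, yhat)
            p, r, f, _ = precision_recall_fscore_support(
                y, yhat, labels=[0, 1, 2], zero_division=0
            )
            for c in range(3):
                assert prf1(cm, c) == pytest.approx((p[c], r[c], f[c]), abs=1e-12)

    def test_diagonal_matrix_is_perfect(self):
        cm = np.diag([10, 20, 5])
        for c in range(3):
            assert prf1(cm, c) == (1.0, 1.0, 1.0)

    def test_zero_support_class_returns_zeros(self):
        cm = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        assert prf1(cm, 2) == (0.0, 0.0, 0.0)


class TestMacroF1:
    def test_unweighted_mean_against_brute_force(self, rng):
        for _ in range(10):
            y, yhat = random_labels(rng)
            cm = confusion_matrix(y, yhat)
            brute = np.mean([prf1(cm, c)[2] for c in range(3)])
            assert macro_f1(cm) == pytest.approx(brute, abs=1e-12)
            assert macro_f1_from_labels(y, yhat) == macro_f1(cm)

    def test_invariant_to_uniform_replication(self, rng):
        """Replicating the whole evaluation set leaves every per-class F1 —
        and hence Macro-F1 — unchanged (scale invariance of the ratios)."""
        y, yhat = random_labels(rng)
        y2, yhat2 = np.tile(y, 3), np.tile(yhat, 3)
        cm, cm2 = confusion_matrix(y, yhat), confusion_matrix(y2, yhat2)
        for c in range(3):
            assert prf1(cm2, c) == pytest.approx(prf1(cm, c), abs=1e-12)
        assert macro_f1_from_labels(y2, yhat2) == pytest.approx(
            macro_f1_from_labels(y, yhat), abs=1e-12
        )

    def test_perfect_predictions(self):
        assert macro_f1(np.diag([1, 1, 1])) == 1.0


class TestKeyConfusion:
    def test_examples(self):
        assert key_confusion(np.diag([9, 9, 9])) == 0
        cm = np.array([[10, 7, 1], [5, 20, 0], [2, 0, 8]])
        assert key_confusion(cm) == 12
        total_errors = cm.sum() - np.trace(cm)
        assert total_errors >= key_confusion(cm)


class TestBootstrap:
    def test_perfect_predictions_collapse_to_unit_interval(self):
        y = np.array([0, 1, 2] * 20)
        cfg = BootstrapConfig(b=500, seed=1)
        for metric in ("precision", "recall", "f1"):
            point, lo, hi = bootstrap_ci(y, y, 2, metric, cfg)
            assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_single_resample_degenerate_interval(self, rng):
        y, yhat = random_labels(rng, n=60)
        point, lo, hi = bootstrap_ci(y, yhat, 0, "recall", BootstrapConfig(b=1, seed=4))
        assert lo == hi

    def test_deterministic_given_seed(self, rng):
        y, yhat = random_labels(rng, n=80)
        cfg = BootstrapConfig(b=2000, seed=9)
        assert bootstrap_ci(y, yhat, 1, "f1", cfg) == bootstrap_ci(y, yhat, 1, "f1", cfg)

    def test_point_estimate_inside_interval(self, rng):
        for _ in range(5):
            y, yhat = random_labels(rng, n=150)
            point, lo, hi = bootstrap_ci(y, yhat, 1, "f1", BootstrapConfig(b=2000, seed=2))
            assert lo - 1e-12 <= point <= hi + 1e-12

    def test_rare_class_undefined_resamples_are_skipped(self):
        # class 2 appears once: many resamples miss it entirely (0/0 recall)
        y = np.array([0] * 30 + [2])
        yhat = np.array([0] * 30 + [2])
        point, lo, hi = bootstrap_ci(y, yhat, 2, "recall", BootstrapConfig(b=500, seed=0))
        assert point == 1.0 and np.isfinite(lo) and np.isfinite(hi)

    def test_absent_class_rejected(self):
        y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="absent"):
            bootstrap_ci(y, y, 2, "recall")


class TestPCK:
    def test_exact_predictions_score_one(self, clean_instance):
        preds = [clean_instance.keypoints.copy()]
        assert pck(preds, [clean_instance], 0.05) == 1.0

    def test_far_predictions_score_zero(self, clean_instance):
        preds = [clean_instance.keypoints + 1e4]
        assert pck(preds, [clean_instance], 0.05) == 0.0

    def test_nondecreasing_in_alpha(self, clean_instance, rng):
        preds = [clean_instance.keypoints + rng.normal(0, 15, size=(16, 2))]
        values = [pck(preds, [clean_instance], a) for a in (0.02, 0.05, 0.1, 0.2, 0.5)]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_invisible_keypoints_excluded(self):
        inst = make_instance(invisible=(0, 1))
        preds = [inst.keypoints.copy()]
        preds[0][0] += 1e4  # error only on an invisible keypoint
        assert pck(preds, [inst], 0.05) == 1.0


class TestReport:
    def test_perfect_predictor_report(self):
        y = np.array([0, 1, 2] * 10)
        report = assemble_report(y, y, name="perfect")
        assert report.macro_f1 == 1.0
        assert report.key_confusion == 0

    def test_cost_multiplier_and_complexity_fields(self):
        y = np.array([0, 1, 2] * 10)
        report = assemble_report(
            y, y, name="ens", n_params=429_315, inference_cost_multiplier=5
        )
        assert report.inference_cost_multiplier == 5
        assert round(report.fp32_mebibytes, 2) == 1.64

    def test_json_round_trip(self, tmp_path, rng):
        y, yhat = random_labels(rng, n=90)
        report = assemble_report(
            y, yhat, name="m", n_params=1000,
            bootstrap_classes=(2,), bootstrap_config=BootstrapConfig(b=200, seed=3),
        )
        p = tmp_path / "r.json"
        report.to_json(p)
        loaded = EvalReport.from_json(p)
        assert loaded.to_dict() == report.to_dict()
        assert np.array_equal(loaded.confusion, report.confusion)

    def test_markdown_table_lists_all_configurations(self, rng):
        y, yhat = random_labels(rng, n=30)
        reports = [assemble_report(y, yhat, name=n) for n in ("baseline", "AB")]
        md = report_markdown(reports)
        assert "baseline" in md and "AB" in md
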