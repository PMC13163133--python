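"""Temperature softening, KD / combined losses, and student distillation."""

import numpy as np
import pytest
from dataclasses import replace

from cowpose.distill import (
    KDConfig,
    _combined_grad,
    combined_loss,
    distill_student,
    kd_loss,
    soften,
)
from cowpose.experiments import BENCH_MODEL_SPEC, BENCH_TRAIN
from cowpose.network import build_model, count_parameters, predict_logits
from cowpose.training import softmax, train


class TestSoften:
    def test_unit_temperature_is_plain_softmax(self, rng):
        z = rng.normal(size=3)
        assert soften(z, 1.0) == pytest.approx(softmax(z))

    def test_high_temperature_approaches_uniform(self):
        assert soften(np.array([5.0, 0.0, -5.0]), 1e6) == pytest.approx(
            (1 / 3,) * 3, abs=1e-5
        )

    def test_hand_computed_softening(self):
        assert soften(np.array([2.0, 0.0, 0.0]), 2.0) == pytest.approx(
            (0.5761, 0.2119, 0.2119), abs=5e-5
        )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            soften(np.zeros(3), 0.0)


class TestKDLoss:
    def test_zero_iff_equal_softened_distributions(self, rng):
        z = rng.normal(size=3)
        assert kd_loss(z, z, 3.0) == pytest.approx(0.0, abs=1e-12)
        # a constant logit shift softens to the same distribution
        assert kd_loss(z + 1.7, z + 1.7 - 4.0, 2.0) == pytest.approx(
            kd_loss(z, z - 4.0, 2.0)
        )
        assert kd_loss(z, z + 5.0, 2.0) == pytest.approx(0.0, abs=1e-12)
        assert kd_loss(z, z + np.array([1.0, 0.0, 0.0]), 2.0) > 1e-4

    def test_hand_computed_kl(self):
        z_t = np.log([0.5, 0.25, 0.25])
        z_s = np.log([0.25, 0.5, 0.25])
        assert kd_loss(z_t, z_s, 1.0) == pytest.approx(0.25 * np.log(2), abs=1e-9)

    def test_nonnegative_for_random_pairs(self, rng):
        for _ in range(100):
            assert kd_loss(rng.normal(size=3), rng.normal(size=3), 2.5) >= 0

    def test_gradient_matches_finite_differences(self, rng):
        z_t = rng.normal(size=(1, 3))
        z_s = rng.normal(size=(1, 3))
        cfg = KDConfig(temperature=4.0, lam=1.0)
        grad = _combined_grad(z_s, soften(z_t, 4.0), np.zeros((1, 3)), cfg)[0]
        eps = 1e-6
        for c in range(3):
            zp, zm = z_s.copy(), z_s.copy()
            zp[0, c] += eps
            zm[0, c] -= eps
            fd = (kd_loss(z_t, zp, 4.0) - kd_loss(z_t, zm, 4.0)) / (2 * eps)
            assert grad[c] == pytest.approx(fd, abs=1e-6)

    def test_t_squared_factor_preserves_gradient_scale(self, rng):
        """Without the T^2 factor soft-target gradients shrink like 1/T^2;
        with it they stay on the hard-loss scale across temperatures."""
        z_s = rng.normal(size=(1, 3))
        eps_vec = 1e-3 * rng.normal(size=(1, 3))
        z_t = z_s + eps_vec

        def grad_norm(t):
            cfg = KDConfig(temperature=t, lam=1.0)
            return np.linalg.norm(_combined_grad(z_s, soften(z_t, t), np.zeros((1, 3)), cfg))

        g1, g8 = grad_norm(1.0), grad_norm(8.0)
        assert 0.2 < g8 / g1 < 5.0          # same order with the factor
        assert g8 / 64 < 0.05 * g1          # the unscaled KL gradient would not be


class TestCombinedLoss:
    def test_lambda_endpoints(self, rng):
        z_s, z_t = rng.normal(size=3), rng.normal(size=3)
        y = 1
        ce = combined_loss(z_s, z_t, y, KDConfig(lam=0.0))
        kd = combined_loss(z_s, z_t, y, KDConfig(lam=1.0, temperature=4.0))
        assert ce == pytest.approx(-np.log(softmax(z_s)[y]))
        assert kd == pytest.approx(kd_loss(z_t, z_s, 4.0))

    def test_identical_logits_halve_to_ce(self, rng):
        z = rng.normal(size=3)
        half = combined_loss(z, z, 0, KDConfig(lam=0.5))
        assert half == pytest.approx(0.5 * -np.log(softmax(z)[0]))

    def test_convex_combination_bracket(self, rng):
        for _ in range(50):
            z_s, z_t = rng.normal(size=3), rng.normal(size=3)
            y = int(rng.integers(0, 3))
            cfg = KDConfig(lam=0.3, temperature=2.0)
            ce = combined_loss(z_s, z_t, y, KDConfig(lam=0.0))
            kd = combined_loss(z_s, z_t, y, KDConfig(lam=1.0, temperature=2.0))
            mix = combined_loss(z_s, z_t, y, cfg)
            assert min(ce, kd) - 1e-12 <= mix <= max(ce, kd) + 1e-12

    @pytest.mark.parametrize("kwargs", [{"temperature": 0.0}, {"lam": 1.5}])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KDConfig(**kwargs)


class TestDistillStudent:
    def test_lambda_zero_reduces_to_plain_training(self, small_rendered_dataset):
        """With lam = 0 the teacher is ignored: the student's trajectory is
        identical to supervised tau = 0 training at the same seed."""
        data, priors, _ = small_rendered_dataset
        tc = replace(BENCH_TRAIN, max_epochs=2, seed=5, tau=0.0)
        teacher = [build_model(BENCH_MODEL_SPEC, seed=99)]
        kd = distill_student(
            teacher, data, KDConfig(lam=0.0, student_seed=5, train=tc), BENCH_MODEL_SPEC
        )
        ref = build_model(BENCH_MODEL_SPEC, seed=5)
        train(ref, data["train"], data["val"], priors, tc)
        x_test, _ = data["test"]
        assert np.allclose(
            predict_logits(kd.student, x_test), predict_logits(ref, x_test), atol=1e-5
        )

    def test_pure_kd_loss_decreases_against_clone_teacher(self, small_rendered_dataset):
        data, _, _ = small_rendered_dataset
        teacher_net = build_model(BENCH_MODEL_SPEC, seed=1)
        tc = replace(BENCH_TRAIN, max_epochs=8, seed=2)
        kd = distill_student(
            [teacher_net] * 5, data,
            KDConfig(lam=1.0, temperature=2.0, student_seed=2, train=tc),
            BENCH_MODEL_SPEC,
        )
        losses = [h["train_loss"] for h in kd.train_result.history]
        drops = sum(b < a for a, b in zip(losses, losses[1:]))
        assert drops / (len(losses) - 1) >= 0.8
        assert kd.teacher_cost_multiplier == 5

    def test_student_has_single_model_complexity(self, small_rendered_dataset):
        data, _, _ = small_rendered_dataset
        teacher = [build_model(BENCH_MODEL_SPEC, seed=s) for s in range(2)]
        tc = replace(BENCH_TRAIN, max_epochs=1)
        kd = distill_student(teacher, data, KDConfig(student_seed=0, train=tc), BENCH_MODEL_SPEC)
        assert count_parameters(kd.student) == count_parameters(teacher[0])
        assert kd.student_cost_multiplier == 1
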