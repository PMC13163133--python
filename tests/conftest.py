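"""Shared fixtures: tiny deterministic poses, datasets and rendered splits."""

import numpy as np
import pytest

from cowpose.skeleton import BEHAVIORS, PoseInstance
from cowpose.synthetic import SyntheticConfig, generate_dataset, generate_pose


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_instance(
    sample_id="s0",
    image_size=(360, 520),
    label="stand",
    split=None,
    invisible=(),
    seed=0,
):
    """A jitter-free template pose with selected keypoints hidden."""
    cfg = SyntheticConfig(jitter_sd=0.0, dropout_prob=0.0)
    inst = generate_pose(label, np.random.default_rng(seed), cfg, sample_id, split)
    if invisible:
        vis = inst.visibility.copy()
        kp = inst.keypoints.copy()
        for i in invisible:
            vis[i] = False
            kp[i] = 0.0
        inst = PoseInstance(sample_id, kp, vis, inst.image_size, label, split)
    return inst


@pytest.fixture
def clean_instance():
    return make_instance()


@pytest.fixture
def tiny_manifest():
    """A 40/12/12 three-class manifest, deterministic."""
    cfg = SyntheticConfig(
        n_train=40, n_val=12, n_test=12,
        class_proportions=(0.4, 0.35, 0.25),
        val_proportions=(0.4, 0.35, 0.25),
        test_proportions=(0.4, 0.35, 0.25),
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_rendered_dataset():
    """A rendered 150/60/60 dataset at benchmark resolution (session-cached)."""
    from cowpose.experiments import BENCH_RENDER, render_dataset
    from cowpose.training import compute_class_priors

    cfg = SyntheticConfig(
        n_train=150, n_val=60, n_test=60,
        class_proportions=(1 / 3, 1 / 3, 1 / 3),
        val_proportions=(1 / 3, 1 / 3, 1 / 3),
        test_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=5,
    )
    manifest = generate_dataset(cfg)
    data = render_dataset(manifest, BENCH_RENDER)
    priors = compute_class_priors(manifest)
    return data, priors, manifest
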