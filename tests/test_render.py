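"""Letterbox / crop geometry and the HM/PAF rasterizers vs brute force."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowpose.render import (
    RenderConfig,
    assemble_tensor,
    crop_window,
    inverse_letterbox,
    keypoint_crop,
    letterbox,
    read_tensor_store,
    render_heatmap,
    render_instance,
    render_paf,
    write_tensor_store,
)
from cowpose.skeleton import COW16, PoseInstance

from conftest import make_instance

SMALL = RenderConfig(grid_size=(32, 32), sigma=2.0, limb_width=2.5, input_side=32)


class TestLetterbox:
    def test_square_image_scales_without_padding(self):
        pts, scale, pads = letterbox(np.array([[100.0, 200.0]]), (500, 500), 368)
        assert scale == pytest.approx(0.736)
        assert pads == (0.0, 0.0)
        assert np.allclose(pts, [[73.6, 147.2]])

    def test_landscape_image_pads_the_short_axis(self):
        _, scale, (pad_x, pad_y) = letterbox(np.zeros((1, 2)), (360, 520), 368)
        assert scale == pytest.approx(368 / 520)
        assert pad_x == 0.0
        assert 2 * pad_y == pytest.approx(368 - 360 * 368 / 520)

    @settings(derandomize=True, max_examples=30)
    @given(
        h=st.integers(10, 2000),
        w=st.integers(10, 2000),
        side=st.integers(16, 1000),
    )
    def test_forward_inverse_round_trip(self, h, w, side):
        rng = np.random.default_rng(h * 7919 + w)
        pts = rng.uniform(0, [w, h], size=(16, 2))
        fwd, scale, pads = letterbox(pts, (h, w), side)
        back = inverse_letterbox(fwd, scale, pads)
        assert np.abs(back - pts).max() < 0.5

    def test_degenerate_image_size_rejected(self):
        with pytest.raises(ValueError):
            letterbox(np.zeros((1, 2)), (0, 100), 368)


class TestKeypointCrop:
    def test_zero_margin_equals_tight_bounding_box(self, clean_instance):
        x0, y0, ch, cw = crop_window(clean_instance, 0.0)
        vis = clean_instance.keypoints[clean_instance.visibility]
        assert (x0, y0) == pytest.approx(tuple(vis.min(axis=0)))
        assert ch == int(np.ceil(vis[:, 1].max() - y0))

    def test_window_clipped_at_image_border(self):
        kp = np.tile([[2.0, 3.0]], (16, 1)) + np.arange(16)[:, None]
        inst = PoseInstance("corner", kp, np.ones(16, bool), (360, 520))
        x0, y0, ch, cw = crop_window(inst, 0.25)
        assert x0 == 0.0 and y0 == 0.0  # margin would go negative, clipped

    def test_fewer_than_two_visible_rejected(self):
        inst = PoseInstance(
            "solo", np.zeros((16, 2)), np.eye(16, dtype=bool)[0], (100, 100)
        )
        with pytest.raises(ValueError, match="2 visible"):
            keypoint_crop(inst, 0.1)

    def test_crop_then_render_matches_render_with_offset(self, clean_instance):
        cropped = keypoint_crop(clean_instance, 0.2)
        x0, y0, ch, cw = crop_window(clean_instance, 0.2)
        shifted = PoseInstance(
            "shifted",
            np.clip(clean_instance.keypoints - [x0, y0], 0, [cw - 1e-6, ch - 1e-6]),
            clean_instance.visibility,
            (ch, cw),
            clean_instance.label,
        )
        a = assemble_tensor(cropped, SMALL).combined
        b = assemble_tensor(shifted, SMALL).combined
        assert np.array_equal(a, b)


class TestHeatmap:
    def test_on_grid_center_peaks_at_one(self):
        hm = render_heatmap((10.0, 7.0), SMALL)
        assert hm[7, 10] == pytest.approx(1.0)
        assert hm.max() == hm[7, 10]

    def test_value_at_distance_sigma_is_exp_minus_one(self):
        hm = render_heatmap((10.0, 7.0), SMALL)
        assert hm[7, 12] == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_matches_per_pixel_brute_force(self, rng):
        cfg = RenderConfig(grid_size=(64, 64), sigma=3.0, limb_width=1.5, input_side=64)
        for _ in range(3):
            cx, cy = rng.uniform(0, 64, 2)
            hm = render_heatmap((cx, cy), cfg)
            brute = np.empty((64, 64))
            for i in range(64):
                for j in range(64):
                    brute[i, j] = np.exp(-((j - cx) ** 2 + (i - cy) ** 2) / cfg.sigma**2)
            assert np.abs(hm - brute).max() < 1e-6


class TestPAF:
    def test_horizontal_limb_midpoint_is_unit_x(self):
        paf = render_paf((10.0, 20.0), (30.0, 20.0), SMALL)
        assert paf[0, 20, 20] == pytest.approx(1.0)
        assert paf[1, 20, 20] == pytest.approx(0.0)

    def test_pixel_beyond_limb_width_is_zero(self):
        cfg = RenderConfig(grid_size=(32, 32), sigma=1.0, limb_width=2.0, input_side=32)
        paf = render_paf((5.0, 10.0), (25.0, 10.0), cfg)
        assert paf[0, 13, 15] == 0.0  # perpendicular distance 3 > limb_width 2
        assert paf[0, 12, 15] != 0.0  # distance 2, inside

    def test_matches_per_pixel_brute_force(self, rng):
        cfg = RenderConfig(grid_size=(32, 32), sigma=1.0, limb_width=2.0, input_side=32)
        for _ in range(3):
            a = rng.uniform(2, 30, 2)
            b = rng.uniform(2, 30, 2)
            paf = render_paf(tuple(a), tuple(b), cfg)
            u = (b - a) / np.linalg.norm(b - a)
            brute = np.zeros((2, 32, 32))
            for i in range(32):
                for j in range(32):
                    d = np.array([j, i]) - a
                    along = d @ u
                    perp = abs(d[0] * u[1] - d[1] * u[0])
                    if 0 <= along <= np.linalg.norm(b - a) and perp <= cfg.limb_width:
                        brute[:, i, j] = u
            assert np.array_equal(paf.astype(float), brute.astype(np.float32).astype(float))

    def test_coincident_endpoints_yield_zero_with_warning(self):
        with pytest.warns(UserWarning, match="coincident"):
            paf = render_paf((5.0, 5.0), (5.0, 5.0), SMALL)
        assert not paf.any()


class TestAssemble:
    def test_channel_arity_and_ranges(self, clean_instance):
        t = assemble_tensor(clean_instance)
        assert t.combined.shape[0] == 46
        assert t.heatmaps.shape[0] == 16 and t.pafs.shape[0] == 30
        assert t.heatmaps.min() >= 0 and t.heatmaps.max() <= 1
        mag = np.sqrt(t.pafs[0::2] ** 2 + t.pafs[1::2] ** 2)
        assert mag.max() <= 1 + 1e-6

    def test_all_invisible_renders_zero_tensor(self):
        inst = PoseInstance("ghost", np.zeros((16, 2)), np.zeros(16, bool), (100, 100))
        assert not assemble_tensor(inst, SMALL).combined.any()

    def test_hiding_one_keypoint_only_clears_its_channels(self, clean_instance):
        base = assemble_tensor(clean_instance, SMALL).combined
        hidden_idx = COW16.index("nose")
        inst = make_instance(invisible=(hidden_idx,))
        masked = assemble_tensor(inst, SMALL).combined
        touched = {hidden_idx} | {
            16 + 2 * e + k
            for e, (a, b) in enumerate(COW16.edges)
            if hidden_idx in (a, b)
            for k in (0, 1)
        }
        for c in range(46):
            if c in touched:
                assert not masked[c].any()
            else:
                assert np.array_equal(masked[c], base[c])

    def test_translation_equivariance_on_unit_scale_grid(self):
        cfg = RenderConfig(grid_size=(32, 32), sigma=1.5, limb_width=1.0, input_side=32)
        rng = np.random.default_rng(1)
        kp = rng.uniform(8, 20, size=(16, 2))
        inst = PoseInstance("t0", kp, np.ones(16, bool), (32, 32))
        shifted = PoseInstance("t1", kp + [3, 2], np.ones(16, bool), (32, 32))
        a = assemble_tensor(inst, cfg).combined
        b = assemble_tensor(shifted, cfg).combined
        rolled = np.roll(np.roll(a, 2, axis=1), 3, axis=2)
        # compare away from the wrapped borders
        assert np.allclose(rolled[:, 4:30, 4:28], b[:, 4:30, 4:28], atol=1e-6)

    def test_render_instance_full_pipeline_shape(self, clean_instance):
        x = render_instance(clean_instance)
        assert x.shape == (46, 46, 46) and x.dtype == np.float32


def test_tensor_store_round_trip(tmp_path, tiny_manifest):
    path = tmp_path / "t.h5"
    cfg = RenderConfig(grid_size=(12, 12), sigma=1.0, limb_width=1.0, input_side=96)
    write_tensor_store(path, tiny_manifest, cfg)
    store = read_tensor_store(path)
    assert len(store) == len(tiny_manifest)
    rec = tiny_manifest.records[0]
    tensor, label, split = store[rec.sample_id]
    assert tensor.shape == (46, 12, 12)
    assert label == rec.label and split == rec.split
    assert np.array_equal(tensor, render_instance(rec, cfg))
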