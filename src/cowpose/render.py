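"""HM/PAF pose-tensor rendering and crop / letterbox geometry.

A :class:`~cowpose.skeleton.PoseInstance` is converted into a 46-channel
grid: one Gaussian heatmap per keypoint (16 channels, values in [0, 1],
peak 1 at the annotation) followed by one two-channel part affinity field
per skeleton edge (15 x 2 = 30 channels). A PAF stores the unit vector
along the limb at every grid pixel whose projection falls on the segment
and whose perpendicular distance is within ``limb_width``; elsewhere zero.
Channels belonging to invisible keypoints — and to edges with at least one
invisible endpoint — are all-zero.

Geometry follows the standard two-step preprocessing of pose pipelines:
keypoint-guided cropping (bounding box of the visible keypoints expanded by
a margin) followed by aspect-preserving square letterbox resizing, then a
fixed-stride mapping onto the output grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeleton import COW16, PoseInstance, SkeletonSchema

DTYPE = np.float32


@dataclass(frozen=True)
class RenderConfig:
    """Output-grid geometry and rasterization parameters.

    ``sigma`` and ``limb_width`` are expressed in *grid* pixels. The default
    46 x 46 grid corresponds to the 368-pixel letterbox side at stride 8.
    """

    grid_size: tuple[int, int] = (46, 46)   # (H, W)
    sigma: float = 2.0
    limb_width: float = 1.5
    input_side: int = 368

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.limb_width <= 0:
            raise ValueError("limb_width must be > 0")
        if min(self.grid_size) <= 0 or self.input_side <= 0:
            raise ValueError("grid_size and input_side must be positive")

    @property
    def stride(self) -> float:
        return self.input_side / max(self.grid_size)


@dataclass
class PoseTensor:
    """The 46-channel pose representation consumed by the classifier."""

    heatmaps: np.ndarray  # (16, H, W) in [0, 1]
    pafs: np.ndarray      # (30, H, W) in [-1, 1]

    @property
    def combined(self) -> np.ndarray:
        """46 x H x W concatenation, heatmaps first."""
        return np.concatenate([self.heatmaps, self.pafs], axis=0)


def letterbox(
    points: np.ndarray,
    image_size: tuple[int, int],
    input_side: int,
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Map image-plane points into square letterbox coordinates.

    Returns ``(scaled_points, scale, (pad_x, pad_y))`` where
    ``scale = input_side / max(height, width)`` and the padding centers the
    short axis. The mapping is exactly invertible (:func:`inverse_letterbox`).
    """
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError(f"degenerate image_size {image_size}")
    scale = input_side / max(h, w)
    pad_x = (input_side - w * scale) / 2.0
    pad_y = (input_side - h * scale) / 2.0
    pts = np.asarray(points, dtype=float) * scale + np.array([pad_x, pad_y])
    return pts, scale, (pad_x, pad_y)


def inverse_letterbox(
    points: np.ndarray, scale: float, pads: tuple[float, float]
) -> np.ndarray:
    return (np.asarray(points, dtype=float) - np.array(pads)) / scale


def crop_window(
    instance: PoseInstance, margin_frac: float
) -> tuple[float, float, int, int]:
    """Crop window ``(x0, y0, height, width)`` for :func:`keypoint_crop`."""
    if instance.n_visible < 2:
        raise ValueError(
            f"{instance.sample_id}: keypoint crop needs >= 2 visible keypoints, "
            f"got {instance.n_visible}"
        )
    h, w = instance.image_size
    vis = instance.keypoints[instance.visibility]
    x0, y0 = vis.min(axis=0)
    x1, y1 = vis.max(axis=0)
    mx = margin_frac * (x1 - x0)
    my = margin_frac * (y1 - y0)
    x0 = max(0.0, x0 - mx)
    y0 = max(0.0, y0 - my)
    x1 = min(float(w), x1 + mx)
    y1 = min(float(h), y1 + my)
    crop_w = max(x1 - x0, 1.0)
    crop_h = max(y1 - y0, 1.0)
    return float(x0), float(y0), int(np.ceil(crop_h)), int(np.ceil(crop_w))


def keypoint_crop(instance: PoseInstance, margin_frac: float = 0.125) -> PoseInstance:
    """Crop to the visible-keypoint bounding box expanded by ``margin_frac``.

    The window is clipped to the image; keypoints are re-expressed in crop
    coordinates and invisible keypoints stay at (0, 0). Requires at least
    two visible keypoints (the box is undefined otherwise).
    """
    x0, y0, ch, cw = crop_window(instance, margin_frac)
    shifted = instance.keypoints - np.array([x0, y0])
    shifted = np.where(instance.visibility[:, None], shifted, 0.0)
    # Keep visible points strictly inside the (ceiled) window.
    shifted[:, 0] = np.clip(shifted[:, 0], 0.0, cw - 1e-6)
    shifted[:, 1] = np.clip(shifted[:, 1], 0.0, ch - 1e-6)
    return PoseInstance(
        sample_id=instance.sample_id,
        keypoints=shifted,
        visibility=instance.visibility.copy(),
        image_size=(ch, cw),
        label=instance.label,
        split=instance.split,
    )


def render_heatmap(center: tuple[float, float], config: RenderConfig) -> np.ndarray:
    """One Gaussian heatmap channel: ``exp(-||p - center||^2 / sigma^2)``."""
    gh, gw = config.grid_size
    ys = np.arange(gh, dtype=DTYPE)[:, None]
    xs = np.arange(gw, dtype=DTYPE)[None, :]
    cx, cy = center
    d2 = (xs - DTYPE(cx)) ** 2 + (ys - DTYPE(cy)) ** 2
    return np.exp(-d2 / DTYPE(config.sigma**2))


def render_paf(
    endpoint_a: tuple[float, float],
    endpoint_b: tuple[float, float],
    config: RenderConfig,
) -> np.ndarray:
    """Two PAF channels (x-component, y-component) for one limb segment."""
    gh, gw = config.grid_size
    out = np.zeros((2, gh, gw), dtype=DTYPE)
    a = np.asarray(endpoint_a, dtype=float)
    b = np.asarray(endpoint_b, dtype=float)
    seg = b - a
    length = float(np.hypot(*seg))
    if length < 1e-6:
        warnings.warn("coincident PAF endpoints; emitting zero channels", stacklevel=2)
        return out
    u = seg / length
    ys = np.arange(gh, dtype=float)[:, None]
    xs = np.arange(gw, dtype=float)[None, :]
    dx = xs - a[0]
    dy = ys - a[1]
    along = dx * u[0] + dy * u[1]
    perp = np.abs(dx * u[1] - dy * u[0])
    support = (along >= 0.0) & (along <= length) & (perp <= config.limb_width)
    out[0][support] = u[0]
    out[1][support] = u[1]
    return out


def assemble_tensor(
    instance: PoseInstance,
    config: RenderConfig = RenderConfig(),
    schema: SkeletonSchema = COW16,
) -> PoseTensor:
    """Render one instance into the full 16 + 30 channel pose tensor.

    Channel order: 16 heatmaps in schema keypoint order, then per-edge PAF
    blocks in schema edge order with the x-component before the y-component.
    Keypoints are taken through letterbox + stride-to-grid mapping first.
    """
    gh, gw = config.grid_size
    pts, _, _ = letterbox(instance.keypoints, instance.image_size, config.input_side)
    grid_pts = pts / config.stride

    heatmaps = np.zeros((schema.n_keypoints, gh, gw), dtype=DTYPE)
    # Vectorized over keypoints: distance stack (K, H, W).
    vis_idx = np.flatnonzero(instance.visibility)
    if vis_idx.size:
        ys = np.arange(gh, dtype=DTYPE)[None, :, None]
        xs = np.arange(gw, dtype=DTYPE)[None, None, :]
        cx = grid_pts[vis_idx, 0].astype(DTYPE)[:, None, None]
        cy = grid_pts[vis_idx, 1].astype(DTYPE)[:, None, None]
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        heatmaps[vis_idx] = np.exp(-d2 / DTYPE(config.sigma**2))

    pafs = np.zeros((2 * schema.n_edges, gh, gw), dtype=DTYPE)
    for e, (a, b) in enumerate(schema.edges):
        if instance.visibility[a] and instance.visibility[b]:
            pafs[2 * e : 2 * e + 2] = render_paf(grid_pts[a], grid_pts[b], config)

    return PoseTensor(heatmaps=heatmaps, pafs=pafs)


def render_instance(
    instance: PoseInstance,
    config: RenderConfig = RenderConfig(),
    crop_margin: float | None = 0.125,
    schema: SkeletonSchema = COW16,
) -> np.ndarray:
    """Full preprocessing pipeline: crop (optional) -> letterbox -> rasterize.

    Returns the combined ``(46, H, W)`` float32 array. Instances with fewer
    than two visible keypoints skip the crop (the letterbox still applies).
    """
    if crop_margin is not None and instance.n_visible >= 2:
        instance = keypoint_crop(instance, crop_margin)
    return assemble_tensor(instance, config, schema).combined


# ---------------------------------------------------------------------------
# HDF5 tensor store

def write_tensor_store(
    path,
    manifest,
    config: RenderConfig = RenderConfig(),
    crop_margin: float | None = 0.125,
    schema: SkeletonSchema = COW16,
) -> None:
    """Render every manifest record into an HDF5 file.

    Layout: one ``(46, H, W)`` float32 dataset per sample_id with ``label``
    and ``split`` attributes; render settings stored as file attributes.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["grid_h"], fh.attrs["grid_w"] = config.grid_size
        fh.attrs["sigma"] = config.sigma
        fh.attrs["limb_width"] = config.limb_width
        fh.attrs["input_side"] = config.input_side
        fh.attrs["crop_margin"] = -1.0 if crop_margin is None else crop_margin
        for rec in manifest.records:
            ds = fh.create_dataset(
                rec.sample_id,
                data=render_instance(rec, config, crop_margin, schema),
            )
            ds.attrs["label"] = rec.label or ""
            ds.attrs["split"] = rec.split or ""


def read_tensor_store(path) -> dict[str, tuple[np.ndarray, str, str]]:
    """Load a tensor store back as ``{sample_id: (tensor, label, split)}``."""
    import h5py

    out: dict[str, tuple[np.ndarray, str, str]] = {}
    with h5py.File(path, "r") as fh:
        for sid in fh:
            ds = fh[sid]
            out[sid] = (ds[()], ds.attrs.get("label", ""), ds.attrs.get("split", ""))
    return out
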