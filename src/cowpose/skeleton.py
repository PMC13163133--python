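"""cow16 skeleton schema, pose samples, and annotation / manifest I/O.

The cow16 scheme describes a side-view bovine skeleton with 16 named
keypoints joined by 15 edges that form a tree rooted at the withers.
Figure-level keypoint identities vary between annotation projects, so the
names below are schema *data*: any 16-name / 15-edge tree is accepted by
:func:`validate_schema`, and readers take the schema as an argument.

Conventions used throughout the package:

* coordinates are 0-based pixel units, ``x`` rightward, ``y`` downward,
  stored as ``(x, y)`` pairs (the Labelme convention);
* invisible keypoints are stored as ``(0, 0)`` with a ``False`` visibility
  flag, never as sentinel negatives;
* the behavior label order is ``(stand, walk, lying)`` everywhere — class
  priors, logits, and confusion-matrix axes all share this single order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Canonical behavior categories, in the global class order.
BEHAVIORS = ("stand", "walk", "lying")

N_KEYPOINTS = 16
N_EDGES = 15

DEFAULT_KEYPOINT_NAMES = (
    "nose",
    "forehead",
    "neck",
    "withers",
    "mid_spine",
    "tail_base",
    "left_front_shoulder",
    "right_front_shoulder",
    "left_front_knee",
    "right_front_knee",
    "left_front_hoof",
    "right_front_hoof",
    "left_hind_hip",
    "right_hind_hip",
    "left_hind_hoof",
    "right_hind_hoof",
)

# A 15-edge tree over the 16 keypoints, rooted at the withers: head chain,
# spine, two front legs (shoulder-knee-hoof) and two hind legs (hip-hoof).
DEFAULT_EDGES = (
    (0, 1),    # nose - forehead
    (1, 2),    # forehead - neck
    (2, 3),    # neck - withers
    (3, 4),    # withers - mid_spine
    (4, 5),    # mid_spine - tail_base
    (3, 6),    # withers - left_front_shoulder
    (3, 7),    # withers - right_front_shoulder
    (6, 8),    # left_front_shoulder - left_front_knee
    (7, 9),    # right_front_shoulder - right_front_knee
    (8, 10),   # left_front_knee - left_front_hoof
    (9, 11),   # right_front_knee - right_front_hoof
    (5, 12),   # tail_base - left_hind_hip
    (5, 13),   # tail_base - right_hind_hip
    (12, 14),  # left_hind_hip - left_hind_hoof
    (13, 15),  # right_hind_hip - right_hind_hoof
)


class ParseError(ValueError):
    """Raised when an annotation or manifest file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed content violates a schema or data invariant."""


@dataclass(frozen=True)
class SkeletonSchema:
    """Named keypoints plus the edge list connecting them.

    ``edges`` are ordered pairs of keypoint indices; their order fixes the
    PAF channel order downstream.
    """

    keypoint_names: tuple[str, ...] = DEFAULT_KEYPOINT_NAMES
    edges: tuple[tuple[int, int], ...] = DEFAULT_EDGES
    name: str = "cow16"

    def index(self, keypoint_name: str) -> int:
        return self.keypoint_names.index(keypoint_name)

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoint_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


#: The default cow16 schema instance.
COW16 = SkeletonSchema()


@dataclass(frozen=True)
class SchemaValidation:
    ok: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def validate_schema(schema: SkeletonSchema) -> SchemaValidation:
    """Check the cow16 structural invariants.

    A valid schema has exactly 16 uniquely-named keypoints and exactly 15
    edges whose undirected graph is a spanning tree (connected, acyclic,
    no self-loops, no duplicates). The check is insensitive to edge order
    and to the orientation of individual edges.
    """
    reasons: list[str] = []
    n = schema.n_keypoints
    if n != N_KEYPOINTS:
        reasons.append(f"expected {N_KEYPOINTS} keypoints, got {n}")
    if len(set(schema.keypoint_names)) != n:
        reasons.append("keypoint names are not unique")
    if schema.n_edges != N_EDGES:
        reasons.append(f"expected {N_EDGES} edges, got {schema.n_edges}")

    undirected = set()
    for a, b in schema.edges:
        if not (0 <= a < n and 0 <= b < n):
            reasons.append(f"edge ({a}, {b}) out of range")
            continue
        if a == b:
            reasons.append(f"edge ({a}, {b}) is a self-loop")
            continue
        key = (min(a, b), max(a, b))
        if key in undirected:
            reasons.append(f"edge {key} duplicated")
        undirected.add(key)

    if not reasons:
        # Union-find connectivity: a 15-edge, loop-free, duplicate-free graph
        # over 16 nodes is a tree iff it is connected.
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in undirected:
            ra, rb = find(a), find(b)
            if ra == rb:
                reasons.append(f"edge ({a}, {b}) closes a cycle")
            else:
                parent[ra] = rb
        if not reasons and len({find(i) for i in range(n)}) != 1:
            reasons.append("edge graph is disconnected")

    return SchemaValidation(ok=not reasons, reasons=tuple(reasons))


@dataclass
class PoseInstance:
    """One annotated sample: keypoints, visibility, geometry and label.

    ``keypoints`` is a ``(16, 2)`` float array of ``(x, y)`` pixel
    coordinates in the source image; ``image_size`` is ``(height, width)``.
    """

    sample_id: str
    keypoints: np.ndarray
    visibility: np.ndarray
    image_size: tuple[int, int]
    label: str | None = None
    split: str | None = None

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        if self.keypoints.shape != (N_KEYPOINTS, 2):
            raise ValidationError(
                f"{self.sample_id}: keypoints must be (16, 2), got {self.keypoints.shape}"
            )
        if self.visibility.shape != (N_KEYPOINTS,):
            raise ValidationError(f"{self.sample_id}: visibility must be (16,)")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValidationError(f"{self.sample_id}: degenerate image_size {self.image_size}")
        vis = self.keypoints[self.visibility]
        if vis.size:
            if (vis[:, 0] < 0).any() or (vis[:, 0] >= w).any() or (
                vis[:, 1] < 0
            ).any() or (vis[:, 1] >= h).any():
                bad = [
                    i
                    for i in np.flatnonzero(self.visibility)
                    if not (0 <= self.keypoints[i, 0] < w and 0 <= self.keypoints[i, 1] < h)
                ]
                raise ValidationError(
                    f"{self.sample_id}: visible keypoints {bad} outside [0, {w}) x [0, {h})"
                )
        if self.label is not None and self.label not in BEHAVIORS:
            raise ValidationError(f"{self.sample_id}: unknown label {self.label!r}")
        if self.split is not None and self.split not in ("train", "val", "test"):
            raise ValidationError(f"{self.sample_id}: unknown split {self.split!r}")

    @property
    def n_visible(self) -> int:
        return int(self.visibility.sum())

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "keypoints": self.keypoints.tolist(),
            "visibility": self.visibility.astype(int).tolist(),
            "image_size": list(self.image_size),
            "label": self.label,
            "split": self.split,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoseInstance":
        return cls(
            sample_id=d["sample_id"],
            keypoints=np.asarray(d["keypoints"], dtype=float),
            visibility=np.asarray(d["visibility"], dtype=bool),
            image_size=tuple(d["image_size"]),
            label=d.get("label"),
            split=d.get("split"),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseInstance):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.keypoints, other.keypoints)
            and np.array_equal(self.visibility, other.visibility)
            and tuple(self.image_size) == tuple(other.image_size)
            and self.label == other.label
            and self.split == other.split
        )


def load_labelme(path: str | Path, schema: SkeletonSchema = COW16) -> PoseInstance:
    """Read one Labelme-dialect JSON annotation into a :class:`PoseInstance`.

    Point shapes are matched to schema keypoint names; names absent from the
    file become invisible keypoints at (0, 0). The behavior label, when
    present, is read from the Labelme ``flags`` dictionary (the flag set to
    true among ``stand`` / ``walk`` / ``lying``).
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed Labelme JSON ({exc})") from exc

    try:
        h = int(payload["imageHeight"])
        w = int(payload["imageWidth"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing image size field {exc}") from exc

    keypoints = np.zeros((schema.n_keypoints, 2), dtype=float)
    visibility = np.zeros(schema.n_keypoints, dtype=bool)
    seen: set[str] = set()
    for shape in payload.get("shapes", []):
        if shape.get("shape_type") != "point":
            continue
        name = shape.get("label")
        if name not in schema.keypoint_names:
            raise ValidationError(f"{path}: point label {name!r} not in schema {schema.name}")
        if name in seen:
            raise ValidationError(f"{path}: duplicate keypoint label {name!r}")
        seen.add(name)
        (x, y), = shape["points"]
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(
                f"{path}: keypoint {name!r} at ({x}, {y}) outside [0, {w}) x [0, {h})"
            )
        i = schema.index(name)
        keypoints[i] = (x, y)
        visibility[i] = True

    label = None
    flags = payload.get("flags") or {}
    active = [k for k, v in flags.items() if v and k in BEHAVIORS]
    if len(active) > 1:
        raise ValidationError(f"{path}: multiple behavior flags set: {active}")
    if active:
        label = active[0]

    return PoseInstance(
        sample_id=payload.get("sample_id", path.stem),
        keypoints=keypoints,
        visibility=visibility,
        image_size=(h, w),
        label=label,
    )


def write_labelme(instance: PoseInstance, path: str | Path, schema: SkeletonSchema = COW16) -> None:
    """Write a :class:`PoseInstance` as Labelme-dialect JSON (round-trips with
    :func:`load_labelme`; invisible keypoints are simply omitted)."""
    h, w = instance.image_size
    shapes = [
        {
            "label": schema.keypoint_names[i],
            "points": [[float(instance.keypoints[i, 0]), float(instance.keypoints[i, 1])]],
            "shape_type": "point",
        }
        for i in range(schema.n_keypoints)
        if instance.visibility[i]
    ]
    payload = {
        "version": "5.2.1",
        "sample_id": instance.sample_id,
        "flags": {b: (instance.label == b) for b in BEHAVIORS},
        "shapes": shapes,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class DatasetManifest:
    """An ordered collection of labeled samples with split assignment.

    Construction validates the partition invariant (no sample id appears
    twice); ``class_counts`` is always recomputed from the records.
    """

    records: list[PoseInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValidationError(
                    f"sample {rec.sample_id!r} assigned to both "
                    f"{seen[rec.sample_id]!r} and {rec.split!r}"
                )
            seen[rec.sample_id] = rec.split or ""

    @property
    def class_counts(self) -> dict[str, tuple[int, ...]]:
        """Per-split counts in canonical class order (stand, walk, lying)."""
        counts: dict[str, list[int]] = {}
        for rec in self.records:
            if rec.split is None or rec.label is None:
                continue
            row = counts.setdefault(rec.split, [0] * len(BEHAVIORS))
            row[BEHAVIORS.index(rec.label)] += 1
        return {split: tuple(row) for split, row in counts.items()}

    def subset(self, split: str) -> list[PoseInstance]:
        return [rec for rec in self.records if rec.split == split]

    def __len__(self) -> int:
        return len(self.records)


def write_manifest(records: Iterable[PoseInstance] | DatasetManifest, path: str | Path) -> None:
    """Write records as JSONL, one sample per line."""
    if isinstance(records, DatasetManifest):
        records = records.records
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a JSONL manifest, validating labels, splits and the partition."""
    path = Path(path)
    records: list[PoseInstance] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSONL ({exc})") from exc
            records.append(PoseInstance.from_dict(d))
    return DatasetManifest(records=records)


def class_counts_csv(manifest: DatasetManifest, path: str | Path) -> None:
    """Export per-split class counts as a small CSV table."""
    lines = ["split," + ",".join(BEHAVIORS) + ",total"]
    for split in ("train", "val", "test"):
        counts = manifest.class_counts.get(split)
        if counts is None:
            continue
        lines.append(f"{split}," + ",".join(map(str, counts)) + f",{sum(counts)}")
    Path(path).write_text("\n".join(lines) + "\n")
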