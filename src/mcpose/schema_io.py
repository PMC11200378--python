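"""Domain types and COCO-keypoints JSON I/O for multi-chicken pose data.

The toolkit works on a single animal category ("chicken") with a fixed
10-keypoint schema.  Annotations and predictions are persisted in the COCO
keypoints dialect: annotations as a ``{"images", "annotations", "categories"}``
document, predictions as a flat list of result records.  Coordinates are
continuous, 0-based, origin at the top-left corner, x rightward, y downward;
bounding boxes cover the half-open region ``[x, x+w) x [y, y+h)``.

Visibility is binary inside the toolkit: COCO's ``v=2`` (visible) and ``v=1``
(labeled but occluded) both collapse to ``v=1`` on read, since the similarity
metric only distinguishes scored vs. ignored keypoints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class McposeError(Exception):
    """Base class for toolkit errors."""


class ValidationError(McposeError, ValueError):
    """Input violates a documented invariant."""


class SchemaMismatchError(ValidationError):
    """Keypoint payload does not conform to the active keypoint schema."""


class UndefinedMetricError(McposeError, ValueError):
    """A metric was requested on input for which it is not defined."""


# ---------------------------------------------------------------------------
# Keypoint schema
# ---------------------------------------------------------------------------

#: The 10 chicken keypoints in canonical order.
CHICKEN_KEYPOINT_NAMES: tuple[str, ...] = (
    "body_center",
    "body_tail",
    "body_knee_left",
    "body_knee_right",
    "body_heel_left",
    "body_heel_right",
    "eye_left",
    "eye_right",
    "comb",
    "beak",
)

#: Per-keypoint normalization constants of the chicken keypoint similarity:
#: body_center is the hardest point to annotate consistently and gets the
#: largest beta; every other point uses the tight default.
BETA_BODY_CENTER = 0.107
BETA_DEFAULT = 0.025


@dataclass(frozen=True)
class KeypointSchema:
    """Names, CKS normalization factors, left/right pairs and skeleton edges.

    Parameters
    ----------
    names
        Ordered keypoint labels; length defines N.
    betas
        Per-keypoint normalization factor beta_i (dimensionless, > 0) used in
        the CKS Gaussian kernel.
    lr_pairs
        Index pairs (left, right) of laterally symmetric keypoints.
    skeleton
        Edge list (index, index) used for drawing; purely cosmetic.
    """

    names: tuple[str, ...]
    betas: tuple[float, ...]
    lr_pairs: tuple[tuple[int, int], ...] = ()
    skeleton: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != len(self.betas):
            raise ValidationError("names and betas must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate keypoint name in schema")
        if any(b <= 0 for b in self.betas):
            raise ValidationError("all betas must be > 0")
        n = len(self.names)
        used: set[int] = set()
        for left, right in self.lr_pairs:
            if not (0 <= left < n and 0 <= right < n) or left == right:
                raise ValidationError(f"invalid lr pair ({left}, {right})")
            if left in used or right in used:
                raise ValidationError("lr_pairs indices must be disjoint")
            used.update((left, right))
        for a, b in self.skeleton:
            if not (0 <= a < n and 0 <= b < n):
                raise ValidationError(f"skeleton edge ({a}, {b}) out of range")

    @property
    def n_keypoints(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def beta(self, name: str) -> float:
        return self.betas[self.index(name)]


def default_chicken_schema() -> KeypointSchema:
    """Canonical 10-keypoint chicken schema.

    beta is 0.107 for ``body_center`` and 0.025 for every other keypoint.
    The skeleton is a drawing convention of this toolkit (body axis, legs,
    head), configurable via :class:`KeypointSchema`.
    """
    names = CHICKEN_KEYPOINT_NAMES
    betas = tuple(
        BETA_BODY_CENTER if name == "body_center" else BETA_DEFAULT
        for name in names
    )
    idx = {name: i for i, name in enumerate(names)}
    lr_pairs = (
        (idx["body_knee_left"], idx["body_knee_right"]),
        (idx["body_heel_left"], idx["body_heel_right"]),
        (idx["eye_left"], idx["eye_right"]),
    )
    skeleton = (
        (idx["body_tail"], idx["body_center"]),
        (idx["body_center"], idx["body_knee_left"]),
        (idx["body_center"], idx["body_knee_right"]),
        (idx["body_knee_left"], idx["body_heel_left"]),
        (idx["body_knee_right"], idx["body_heel_right"]),
        (idx["body_center"], idx["comb"]),
        (idx["comb"], idx["eye_left"]),
        (idx["comb"], idx["eye_right"]),
        (idx["eye_left"], idx["beak"]),
        (idx["eye_right"], idx["beak"]),
    )
    return KeypointSchema(names=names, betas=betas, lr_pairs=lr_pairs,
                          skeleton=skeleton)


# ---------------------------------------------------------------------------
# Geometric / instance types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box (x, y, w, h) in pixels, top-left anchored."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"degenerate box w={self.w}, h={self.h}")

    def area(self) -> float:
        return self.w * self.h

    def diagonal(self) -> float:
        return math.hypot(self.w, self.h)

    def as_list(self) -> list[float]:
        return [self.x, self.y, self.w, self.h]


def normalize_visibility(v: int) -> int:
    """Collapse COCO visibility {0,1,2} to the binary flag {0,1}.

    Idempotent: values already in {0,1} are unchanged.
    """
    if v not in (0, 1, 2):
        raise ValidationError(f"visibility flag {v!r} not in {{0,1,2}}")
    return 1 if v >= 1 else 0


@dataclass(frozen=True)
class Keypoint:
    """One keypoint: continuous pixel coordinates plus binary visibility."""

    x: float
    y: float
    v: int = 1

    def __post_init__(self) -> None:
        if self.v not in (0, 1):
            raise ValidationError(f"visibility must be 0 or 1, got {self.v}")

    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class PoseInstance:
    """One animal: bounding box, keypoints and a confidence score.

    Ground-truth instances carry ``score = 1.0``.
    """

    box: BoundingBox
    keypoints: tuple[Keypoint, ...]
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")
        object.__setattr__(self, "keypoints", tuple(self.keypoints))

    def n_visible(self) -> int:
        return sum(k.v for k in self.keypoints)

    def check_schema(self, schema: KeypointSchema) -> None:
        if len(self.keypoints) != schema.n_keypoints:
            raise SchemaMismatchError(
                f"instance has {len(self.keypoints)} keypoints, "
                f"schema expects {schema.n_keypoints}"
            )


@dataclass(frozen=True)
class SceneAnnotation:
    """Ground truth for one image: size plus annotated instances."""

    image_id: int
    width: int
    height: int
    instances: tuple[PoseInstance, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("image dimensions must be positive")
        object.__setattr__(self, "instances", tuple(self.instances))
        for inst in self.instances:
            for kp in inst.keypoints:
                if kp.v == 1 and not (
                    0 <= kp.x < self.width and 0 <= kp.y < self.height
                ):
                    raise ValidationError(
                        f"visible keypoint ({kp.x}, {kp.y}) outside image "
                        f"{self.width}x{self.height} (image {self.image_id})"
                    )


@dataclass(frozen=True)
class ScenePrediction:
    """Predicted instances (with scores) for one image."""

    image_id: int
    instances: tuple[PoseInstance, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))


# ---------------------------------------------------------------------------
# COCO-dialect JSON I/O
# ---------------------------------------------------------------------------

CATEGORY_ID = 1
_JSON_KW = dict(indent=1, sort_keys=True)  # byte-stable serialization


def _keypoints_flat(inst: PoseInstance) -> list[float]:
    flat: list[float] = []
    for kp in inst.keypoints:
        flat.extend((kp.x, kp.y, kp.v))
    return flat


def _keypoints_from_flat(flat: Sequence[float],
                         schema: KeypointSchema) -> tuple[Keypoint, ...]:
    if len(flat) != 3 * schema.n_keypoints:
        raise SchemaMismatchError(
            f"keypoint array length {len(flat)} != 3*{schema.n_keypoints}"
        )
    kps = []
    for i in range(schema.n_keypoints):
        x, y, v = flat[3 * i], flat[3 * i + 1], flat[3 * i + 2]
        kps.append(Keypoint(float(x), float(y), normalize_visibility(int(v))))
    return tuple(kps)


def _category_block(schema: KeypointSchema) -> dict:
    return {
        "id": CATEGORY_ID,
        "name": "chicken",
        "supercategory": "animal",
        "keypoints": list(schema.names),
        "betas": list(schema.betas),
        "skeleton": [[a + 1, b + 1] for a, b in schema.skeleton],  # 1-based
    }


def _schema_from_category(cat: dict) -> KeypointSchema:
    names = tuple(cat["keypoints"])
    default = default_chicken_schema()
    if names == default.names and "betas" not in cat:
        return default
    betas = tuple(cat.get("betas", [BETA_DEFAULT] * len(names)))
    skeleton = tuple(
        (a - 1, b - 1) for a, b in cat.get("skeleton", [])
    )
    lr_pairs = default.lr_pairs if names == default.names else ()
    return KeypointSchema(names=names, betas=betas, lr_pairs=lr_pairs,
                          skeleton=skeleton)


def write_annotations(schema: KeypointSchema,
                      annotations: Sequence[SceneAnnotation],
                      path: str | Path,
                      info: dict | None = None) -> None:
    """Write a dataset as a COCO-keypoints JSON document.

    Output is byte-stable for fixed input: keys are sorted and floats are
    serialized with ``repr`` (exact round trip).
    """
    images = []
    ann_records = []
    ann_id = 1
    for scene in annotations:
        images.append({
            "id": scene.image_id,
            "width": scene.width,
            "height": scene.height,
            "file_name": f"img_{scene.image_id:06d}.png",
        })
        for inst in scene.instances:
            inst.check_schema(schema)
            ann_records.append({
                "id": ann_id,
                "image_id": scene.image_id,
                "category_id": CATEGORY_ID,
                "bbox": inst.box.as_list(),
                "area": inst.box.area(),
                "keypoints": _keypoints_flat(inst),
                "num_keypoints": inst.n_visible(),
                "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "info": info or {},
        "images": images,
        "annotations": ann_records,
        "categories": [_category_block(schema)],
    }
    Path(path).write_text(json.dumps(doc, **_JSON_KW), encoding="utf-8")


def read_annotations(path: str | Path
                     ) -> tuple[KeypointSchema, list[SceneAnnotation]]:
    """Read a COCO-keypoints JSON file into scene annotations.

    Raises
    ------
    SchemaMismatchError
        If a keypoint array length disagrees with the schema.
    ValidationError
        If an annotation references a missing image.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValidationError(f"missing top-level key {key!r}")
    schema = _schema_from_category(doc["categories"][0])

    by_image: dict[int, list[PoseInstance]] = {}
    meta: dict[int, tuple[int, int]] = {}
    for img in doc["images"]:
        image_id = int(img["id"])
        if image_id in meta:
            raise ValidationError(f"duplicate image id {image_id}")
        meta[image_id] = (int(img["width"]), int(img["height"]))
        by_image[image_id] = []
    for ann in doc["annotations"]:
        image_id = int(ann["image_id"])
        if image_id not in meta:
            raise ValidationError(
                f"annotation {ann.get('id')} references unknown image "
                f"{image_id}"
            )
        x, y, w, h = ann["bbox"]
        inst = PoseInstance(
            box=BoundingBox(float(x), float(y), float(w), float(h)),
            keypoints=_keypoints_from_flat(ann["keypoints"], schema),
            score=1.0,
        )
        by_image[image_id].append(inst)

    scenes = [
        SceneAnnotation(image_id=i, width=meta[i][0], height=meta[i][1],
                        instances=tuple(by_image[i]))
        for i in sorted(meta)
    ]
    return schema, scenes


def write_predictions(predictions: Sequence[ScenePrediction],
                      path: str | Path) -> None:
    """Write predictions in the COCO results dialect (flat record list)."""
    records = []
    for scene in predictions:
        for inst in scene.instances:
            records.append({
                "image_id": scene.image_id,
                "category_id": CATEGORY_ID,
                "bbox": inst.box.as_list(),
                "keypoints": _keypoints_flat(inst),
                "score": inst.score,
            })
    Path(path).write_text(json.dumps(records, **_JSON_KW), encoding="utf-8")


def read_predictions(path: str | Path,
                     schema: KeypointSchema) -> list[ScenePrediction]:
    """Read a COCO results JSON file, grouping records per image.

    Record order within an image is preserved (it breaks score ties
    deterministically downstream).
    """
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(records, list):
        raise ValidationError("predictions file must be a JSON array")
    by_image: dict[int, list[PoseInstance]] = {}
    order: list[int] = []
    for rec in records:
        image_id = int(rec["image_id"])
        score = float(rec["score"])
        if not (0.0 <= score <= 1.0):
            raise ValidationError(f"score {score} outside [0, 1]")
        x, y, w, h = rec["bbox"]
        inst = PoseInstance(
            box=BoundingBox(float(x), float(y), float(w), float(h)),
            keypoints=_keypoints_from_flat(rec["keypoints"], schema),
            score=score,
        )
        if image_id not in by_image:
            by_image[image_id] = []
            order.append(image_id)
        by_image[image_id].append(inst)
    return [ScenePrediction(image_id=i, instances=tuple(by_image[i]))
            for i in order]
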