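"""Top-down pose pipeline scaffold: detect, crop, infer heatmaps, decode.

The two-stage design detects each bird first, crops and resizes the box to a
fixed input (default 512x512), runs a pose backend that emits per-keypoint
heatmaps over the crop, decodes each heatmap to a keypoint, and maps the
keypoints back to image coordinates through the recorded inverse affine.

No neural network ships with the toolkit: detector and pose backends are
plain callables satisfying small contracts, and the reference backends are
deterministic oracles built from ground truth (see
:mod:`mcpose.synthetic_scenes` for scene generation).  The compound-scaling
helper (depth/width/resolution multipliers d = alpha^phi, w = beta^phi,
r = gamma^phi subject to alpha * beta^2 * gamma^2 ~= 2) is included as a
configuration utility for sizing such backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from skimage.transform import AffineTransform, warp

from .schema_io import (
    BoundingBox,
    Keypoint,
    KeypointSchema,
    PoseInstance,
    SceneAnnotation,
    ScenePrediction,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_CROP_SIZE: tuple[int, int] = (512, 512)  # (W, H)
DEFAULT_STRIDE: int = 4
DEFAULT_VISIBILITY_FLOOR: float = 0.05
DEFAULT_SCORE_FLOOR: float = 0.3


# ---------------------------------------------------------------------------
# Crop / resize
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropTransform:
    """Affine map between image coordinates and crop coordinates.

    Forward maps image (x, y) to crop (u, v) by anchoring the box corner at
    the crop origin with independent per-axis scales; inverse undoes it
    exactly (composition is identity to well below 1e-9 px).
    """

    box: BoundingBox
    target: tuple[int, int]  # (W, H)

    @property
    def scale(self) -> tuple[float, float]:
        return (self.target[0] / self.box.w, self.target[1] / self.box.h)

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Image coords (N, 2) -> crop coords (N, 2)."""
        pts = np.asarray(points, dtype=float)
        sx, sy = self.scale
        return np.column_stack(((pts[:, 0] - self.box.x) * sx,
                                (pts[:, 1] - self.box.y) * sy))

    def inverse(self, points: np.ndarray) -> np.ndarray:
        """Crop coords (N, 2) -> image coords (N, 2)."""
        pts = np.asarray(points, dtype=float)
        sx, sy = self.scale
        return np.column_stack((pts[:, 0] / sx + self.box.x,
                                pts[:, 1] / sy + self.box.y))


def crop_and_resize(image: np.ndarray, box: BoundingBox,
                    target: tuple[int, int] = DEFAULT_CROP_SIZE,
                    ) -> tuple[np.ndarray, CropTransform]:
    """Crop a box out of an image and resize it to ``target`` (W, H).

    The resize is a direct non-uniform scale of the box onto the target
    (scale_x = W/w, scale_y = H/h); regions outside the image are
    zero-padded.  Bilinear sampling.
    """
    if target[0] <= 0 or target[1] <= 0:
        raise ValidationError(f"target size {target} must be positive")
    if (box.x + box.w <= 0 or box.y + box.h <= 0
            or box.x >= image.shape[1] or box.y >= image.shape[0]):
        raise ValidationError("box does not intersect the image")
    transform = CropTransform(box=box, target=target)
    sx, sy = transform.scale
    # skimage's inverse_map: output (crop) coords -> input (image) coords
    affine = AffineTransform(scale=(1.0 / sx, 1.0 / sy),
                             translation=(box.x, box.y))
    crop = warp(
        image.astype(float), affine,
        output_shape=(target[1], target[0]) + image.shape[2:],
        order=1, cval=0.0, preserve_range=True,
    )
    return crop, transform


# ---------------------------------------------------------------------------
# Heatmaps and decoding
# ---------------------------------------------------------------------------

@dataclass
class HeatmapStack:
    """K per-keypoint score maps over the crop at a fixed stride.

    ``maps`` has shape (K, H', W'); a heatmap cell (r, c) covers the crop
    pixel block starting at (c * stride, r * stride).
    """

    maps: np.ndarray
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValidationError("heatmap stack must be (K, H', W')")
        if not np.isfinite(self.maps).all():
            raise ValidationError("heatmap scores must be finite")
        if self.stride <= 0:
            raise ValidationError("stride must be positive")

    def validate_for(self, schema: KeypointSchema,
                     crop_size: tuple[int, int]) -> None:
        k, hh, ww = self.maps.shape
        if k != schema.n_keypoints:
            raise ValidationError(f"{k} heatmaps for {schema.n_keypoints} "
                                  "keypoints")
        if (ww * self.stride, hh * self.stride) != crop_size:
            raise ValidationError(
                f"heatmap {ww}x{hh} at stride {self.stride} does not tile "
                f"crop {crop_size}"
            )


def decode_heatmaps(stack: HeatmapStack, schema: KeypointSchema,
                    refine: bool = True,
                    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
                    ) -> tuple[list[Keypoint], list[float]]:
    """Decode each heatmap to a crop-coordinate keypoint plus confidence.

    The argmax cell (row r, col c) maps to (x, y) = (c, r) * stride; with
    ``refine`` a quarter-stride shift is applied toward the larger of the
    two axial neighbors (standard simple-baselines refinement).  Ties pick
    the first cell in row-major order.  Peaks below ``visibility_floor``
    are emitted with v = 0.
    """
    if stack.maps.shape[0] != schema.n_keypoints:
        raise ValidationError("heatmap count does not match schema")
    keypoints: list[Keypoint] = []
    confidences: list[float] = []
    for k in range(stack.maps.shape[0]):
        heat = stack.maps[k]
        if heat.max() == heat.min():
            logger.warning("flat heatmap for keypoint %s; using first cell",
                           schema.names[k])
        r, c = np.unravel_index(int(np.argmax(heat)), heat.shape)
        x = float(c * stack.stride)
        y = float(r * stack.stride)
        if refine:
            if 0 < c < heat.shape[1] - 1:
                x += 0.25 * stack.stride * np.sign(heat[r, c + 1]
                                                   - heat[r, c - 1])
            if 0 < r < heat.shape[0] - 1:
                y += 0.25 * stack.stride * np.sign(heat[r + 1, c]
                                                   - heat[r - 1, c])
        peak = float(heat[r, c])
        v = 1 if peak >= visibility_floor else 0
        keypoints.append(Keypoint(x, y, v))
        confidences.append(peak)
    return keypoints, confidences


# ---------------------------------------------------------------------------
# Backend contracts and oracles
# ---------------------------------------------------------------------------

class DetectorBackend(Protocol):
    """image -> list of (BoundingBox, score) with scores in [0, 1]."""

    def __call__(self, image: np.ndarray
                 ) -> list[tuple[BoundingBox, float]]: ...


class PoseBackend(Protocol):
    """(crop, transform) -> HeatmapStack.

    The crop transform is provided so oracle backends can place peaks in
    the crop frame; model-driven backends may ignore it.
    """

    def __call__(self, crop: np.ndarray,
                 transform: CropTransform) -> HeatmapStack: ...


def oracle_detector(annotation: SceneAnnotation,
                    score: float = 0.99) -> DetectorBackend:
    """Detector that returns the ground-truth boxes of one scene."""

    def detect(image: np.ndarray) -> list[tuple[BoundingBox, float]]:
        h, w = image.shape[:2]
        out = []
        for inst in annotation.instances:
            b = inst.box
            x0 = min(max(b.x, 0.0), w - 1.0)
            y0 = min(max(b.y, 0.0), h - 1.0)
            x1 = min(b.x + b.w, float(w))
            y1 = min(b.y + b.h, float(h))
            out.append((BoundingBox(x0, y0, x1 - x0, y1 - y0), score))
        return out

    return detect


def oracle_pose_backend(annotation: SceneAnnotation, schema: KeypointSchema,
                        stride: int = DEFAULT_STRIDE,
                        peak_sigma_cells: float = 1.0) -> PoseBackend:
    """Pose backend that renders ideal Gaussian heatmaps from ground truth.

    For each detection crop it places, per visible GT keypoint of the
    instance whose box center is nearest to the crop's source box center, a
    unit-peak Gaussian at the keypoint's crop position.  Invisible
    keypoints leave their map at zero, so decoding emits v = 0.
    """

    def infer(crop: np.ndarray, transform: CropTransform) -> HeatmapStack:
        w, h = transform.target
        hh, ww = h // stride, w // stride
        maps = np.zeros((schema.n_keypoints, hh, ww))
        if annotation.instances:
            centers = np.array([
                (i.box.x + i.box.w / 2, i.box.y + i.box.h / 2)
                for i in annotation.instances
            ])
            src = np.array([transform.box.x + transform.box.w / 2,
                            transform.box.y + transform.box.h / 2])
            inst = annotation.instances[
                int(np.argmin(((centers - src) ** 2).sum(axis=1)))
            ]
            rows = np.arange(hh)[:, None]
            cols = np.arange(ww)[None, :]
            for k, kp in enumerate(inst.keypoints):
                if kp.v == 0:
                    continue
                u, v = transform.forward(np.array([[kp.x, kp.y]]))[0]
                cu, cv = u / stride, v / stride
                maps[k] = np.exp(
                    -((cols - cu) ** 2 + (rows - cv) ** 2)
                    / (2.0 * peak_sigma_cells ** 2)
                )
        return HeatmapStack(maps=maps, stride=stride)

    return infer


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(image: np.ndarray, image_id: int,
                 detector: DetectorBackend, pose: PoseBackend,
                 schema: KeypointSchema,
                 score_floor: float = DEFAULT_SCORE_FLOOR,
                 crop_size: tuple[int, int] = DEFAULT_CROP_SIZE,
                 refine: bool = True,
                 score_fusion: bool = False) -> ScenePrediction:
    """Detect, crop, infer and decode one image into a ScenePrediction.

    Instance score is the detection score; with ``score_fusion`` it is
    averaged with the mean decoded peak confidence.  A failing backend call
    skips that detection and continues (logged).
    """
    instances: list[PoseInstance] = []
    for box, det_score in detector(image):
        if det_score < score_floor:
            continue
        try:
            crop, transform = crop_and_resize(image, box, crop_size)
            stack = pose(crop, transform)
            stack.validate_for(schema, crop_size)
            kps_crop, confidences = decode_heatmaps(stack, schema,
                                                    refine=refine)
            crop_xy = np.array([kp.xy() for kp in kps_crop])
            image_xy = transform.inverse(crop_xy)
            keypoints = tuple(
                Keypoint(float(x), float(y), kp.v)
                for (x, y), kp in zip(image_xy, kps_crop)
            )
            score = det_score
            if score_fusion:
                score = float(np.clip(
                    0.5 * (det_score + float(np.mean(confidences))), 0, 1))
            instances.append(PoseInstance(box=box, keypoints=keypoints,
                                          score=score))
        except Exception:
            logger.exception("pose inference failed for box %s; skipping",
                             box)
    instances.sort(key=lambda i: -i.score)
    return ScenePrediction(image_id=image_id, instances=tuple(instances))


# ---------------------------------------------------------------------------
# Compound scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingParams:
    """Compound-scaling bases and coefficient (network sizing utility).

    alpha, beta, gamma scale depth, width and input resolution; phi is the
    compound coefficient.  Distinct from the CKS alpha (box area) and
    beta_i (keypoint normalizers).
    """

    phi: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1 or self.gamma < 1:
            raise ValidationError("alpha, beta, gamma must each be >= 1")


def compound_scaling(params: ScalingParams, tolerance: float = 0.1,
                     ) -> tuple[float, float, float, float]:
    """Multipliers (d, w, r) = (alpha, beta, gamma)^phi and the residual.

    residual = |alpha * beta^2 * gamma^2 - 2|; a residual above
    ``tolerance`` logs a warning (the FLOPs-doubling constraint is only
    approximate by design).
    """
    d = params.alpha ** params.phi
    w = params.beta ** params.phi
    r = params.gamma ** params.phi
    residual = abs(params.alpha * params.beta ** 2 * params.gamma ** 2 - 2.0)
    if residual > tolerance:
        logger.warning("compound-scaling constraint violated: residual %.4f "
                       "> %.4f", residual, tolerance)
    return d, w, r, residual
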