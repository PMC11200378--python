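"""Synthetic multi-chicken scene generator and prediction-noise model.

Real annotated chicken imagery is not publicly deposited, so the toolkit
carries its own scene simulator: ground truth is produced by scaling,
rotating and translating a canonical body template inside the image, and
predictions are derived from ground truth through a configurable noise
model that emulates the failure modes seen in practice — coordinate jitter,
keypoints dropped near box edges, left/right foot swaps, whole birds missed
by the detector, and spurious detections with lower scores.

Everything is driven by one seeded NumPy generator consumed in a fixed
documented order (per image: bird placements, then per-instance noise, then
spurious instances), so a given (config, seed) always yields byte-identical
JSON output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .schema_io import (
    BoundingBox,
    Keypoint,
    KeypointSchema,
    PoseInstance,
    SceneAnnotation,
    ScenePrediction,
    ValidationError,
    default_chicken_schema,
)

BOX_MARGIN_FRACTION = 0.10  # GT box inflation per side over the tight box


# ---------------------------------------------------------------------------
# Body template
# ---------------------------------------------------------------------------

#: Canonical unit-pose offsets (x, y) for the 10 chicken keypoints, bird
#: facing +x, y down.  A stylised side-view chicken: horizontal body axis,
#: two legs below, head (eyes, comb, beak) front-top.
_TEMPLATE_OFFSETS: dict[str, tuple[float, float]] = {
    "body_center": (0.00, 0.00),
    "body_tail": (-0.48, -0.08),
    "body_knee_left": (0.02, 0.28),
    "body_knee_right": (0.18, 0.26),
    "body_heel_left": (0.00, 0.48),
    "body_heel_right": (0.20, 0.46),
    "eye_left": (0.33, -0.30),
    "eye_right": (0.39, -0.28),
    "comb": (0.34, -0.44),
    "beak": (0.50, -0.26),
}


@dataclass(frozen=True)
class BodyTemplate:
    """Canonical keypoint offsets (unit pose) plus the left/right mirror map."""

    offsets: np.ndarray  # (N, 2)
    schema: KeypointSchema

    @classmethod
    def chicken(cls, schema: KeypointSchema | None = None) -> "BodyTemplate":
        schema = schema or default_chicken_schema()
        offsets = np.array([_TEMPLATE_OFFSETS[name] for name in schema.names])
        return cls(offsets=offsets, schema=schema)

    def max_radius(self) -> float:
        return float(np.linalg.norm(self.offsets, axis=1).max())

    def mirrored(self) -> np.ndarray:
        """Offsets with each left/right pair swapped (per the schema)."""
        out = self.offsets.copy()
        for left, right in self.schema.lr_pairs:
            out[[left, right]] = out[[right, left]]
        return out

    def posed(self, center: tuple[float, float], scale: float,
              theta: float) -> np.ndarray:
        """Scaled, rotated and translated keypoint coordinates (N, 2)."""
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        return scale * self.offsets @ rot.T + np.asarray(center)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Scene-generation and prediction-noise parameters.

    Defaults describe a mid-density pen scene: a few birds per 960x720
    frame, body spans of 80-160 px, mild localisation jitter (sigma 1.5 px)
    and low rates for the discrete failure modes.
    """

    n_images: int = 20
    birds_per_image: tuple[int, int] = (2, 5)
    image_size: tuple[int, int] = (960, 720)  # (W, H)
    body_scale_range: tuple[float, float] = (80.0, 160.0)
    orientation_range: tuple[float, float] = (-math.pi, math.pi)
    jitter_sigma: float = 1.5
    p_miss_keypoint: float = 0.05
    p_swap_lr: float = 0.03
    p_miss_detection: float = 0.05
    p_false_detection: float = 0.08
    box_noise: float = 3.0
    score_mean_true: float = 0.85
    score_sd_true: float = 0.08
    score_mean_false: float = 0.40
    score_sd_false: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss_keypoint", "p_swap_lr", "p_miss_detection",
                     "p_false_detection"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be >= 0")
        if self.n_images <= 0:
            raise ValidationError("n_images must be positive")
        if self.birds_per_image[0] < 0 or (
                self.birds_per_image[0] > self.birds_per_image[1]):
            raise ValidationError("invalid birds_per_image range")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _tight_box(points: np.ndarray) -> BoundingBox:
    """Tight keypoint bounding box inflated by 10% per side."""
    x0, y0 = points.min(axis=0)
    x1, y1 = points.max(axis=0)
    w = max(x1 - x0, 1.0)
    h = max(y1 - y0, 1.0)
    mx, my = BOX_MARGIN_FRACTION * w, BOX_MARGIN_FRACTION * h
    return BoundingBox(float(x0 - mx), float(y0 - my),
                       float(w + 2 * mx), float(h + 2 * my))


def _place_bird(rng: np.random.Generator, config: SynthConfig,
                template: BodyTemplate) -> np.ndarray:
    """Sample one GT pose fully inside the image bounds."""
    width, height = config.image_size
    scale = float(rng.uniform(*config.body_scale_range))
    theta = float(rng.uniform(*config.orientation_range))
    margin = scale * template.max_radius() * 1.05 + 1.0
    if 2 * margin >= width or 2 * margin >= height:
        raise ValidationError(
            f"body scale {scale:.0f} too large for image {config.image_size}"
        )
    cx = float(rng.uniform(margin, width - margin))
    cy = float(rng.uniform(margin, height - margin))
    return template.posed((cx, cy), scale, theta)


def _noisy_prediction(rng: np.random.Generator, config: SynthConfig,
                      gt_points: np.ndarray, gt_box: BoundingBox,
                      schema: KeypointSchema) -> PoseInstance:
    """Perturb one GT instance into a predicted instance.

    Draw order: jitter (2N normals), one uniform per left/right pair (swap),
    one uniform per keypoint (dropout), four uniforms (box), one normal
    (score).
    """
    pts = gt_points + rng.normal(0.0, config.jitter_sigma,
                                 size=gt_points.shape)
    for left, right in schema.lr_pairs:
        if rng.random() < config.p_swap_lr:
            pts[[left, right]] = pts[[right, left]]
    vis = (rng.random(len(pts)) >= config.p_miss_keypoint).astype(int)
    dx, dy, dw, dh = rng.uniform(-config.box_noise, config.box_noise, size=4)
    box = BoundingBox(gt_box.x + float(dx), gt_box.y + float(dy),
                      max(gt_box.w + float(dw), 1.0),
                      max(gt_box.h + float(dh), 1.0))
    score = float(np.clip(rng.normal(config.score_mean_true,
                                     config.score_sd_true), 0.05, 1.0))
    keypoints = tuple(Keypoint(float(x), float(y), int(v))
                      for (x, y), v in zip(pts, vis))
    return PoseInstance(box=box, keypoints=keypoints, score=score)


def generate_dataset(config: SynthConfig,
                     schema: KeypointSchema | None = None,
                     ) -> tuple[list[SceneAnnotation], list[ScenePrediction]]:
    """Generate ground-truth scenes and noise-perturbed predictions.

    Fully reproducible from ``config.seed``; with all noise parameters at
    zero the predictions are structurally equal to the ground truth.
    """
    schema = schema or default_chicken_schema()
    template = BodyTemplate.chicken(schema)
    rng = np.random.default_rng(config.seed)
    width, height = config.image_size

    annotations: list[SceneAnnotation] = []
    predictions: list[ScenePrediction] = []
    for image_index in range(config.n_images):
        image_id = image_index + 1
        lo, hi = config.birds_per_image
        n_birds = int(rng.integers(lo, hi + 1))
        gt_instances: list[PoseInstance] = []
        gt_points_list: list[np.ndarray] = []
        for _ in range(n_birds):
            pts = _place_bird(rng, config, template)
            gt_points_list.append(pts)
            gt_instances.append(PoseInstance(
                box=_tight_box(pts),
                keypoints=tuple(Keypoint(float(x), float(y), 1)
                                for x, y in pts),
                score=1.0,
            ))

        pred_instances: list[PoseInstance] = []
        for pts, inst in zip(gt_points_list, gt_instances):
            if rng.random() < config.p_miss_detection:
                continue
            pred_instances.append(_noisy_prediction(rng, config, pts,
                                                    inst.box, schema))
        # spurious instances: one Bernoulli trial per true bird
        for _ in range(n_birds):
            if rng.random() < config.p_false_detection:
                pts = _place_bird(rng, config, template)
                score = float(np.clip(
                    rng.normal(config.score_mean_false,
                               config.score_sd_false), 0.01, 0.95))
                pred_instances.append(PoseInstance(
                    box=_tight_box(pts),
                    keypoints=tuple(Keypoint(float(x), float(y), 1)
                                    for x, y in pts),
                    score=score,
                ))

        annotations.append(SceneAnnotation(
            image_id=image_id, width=width, height=height,
            instances=tuple(gt_instances)))
        predictions.append(ScenePrediction(
            image_id=image_id, instances=tuple(pred_instances)))
    return annotations, predictions


# ---------------------------------------------------------------------------
# Analytic companion
# ---------------------------------------------------------------------------

def expected_mean_cks(config: SynthConfig, schema: KeypointSchema,
                      area: float) -> float:
    """Closed-form expected CKS under jitter-only noise.

    With isotropic Gaussian jitter of standard deviation sigma per axis,
    d^2 ~ sigma^2 * chi^2_2, so each per-keypoint Gaussian term has
    expectation v*/(v* + sigma^2) with v* = area * beta_i^2; the expected
    CKS is the mean of these over the (all-visible) keypoints.

    Raises
    ------
    ValidationError
        If any discrete noise probability is nonzero (no closed form then).
    """
    for name in ("p_miss_keypoint", "p_swap_lr", "p_miss_detection",
                 "p_false_detection"):
        if getattr(config, name) != 0.0:
            raise ValidationError(
                f"expected_mean_cks requires jitter-only noise; {name} != 0"
            )
    if area <= 0:
        raise ValidationError("area must be > 0")
    sigma2 = config.jitter_sigma ** 2
    vstar = area * np.asarray(schema.betas) ** 2
    return float(np.mean(vstar / (vstar + sigma2)))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

BODY_VALUE = 120
KEYPOINT_VALUE = 255


def render_scene(annotation: SceneAnnotation,
                 size: tuple[int, int] | None = None) -> np.ndarray:
    """Deterministically rasterise a scene as a grayscale uint8 image.

    Draws each bird as a filled body ellipse plus bright keypoint disks —
    enough structure for pipeline tests, with no pretence of realism.
    """
    from skimage.draw import disk, ellipse

    width, height = size or (annotation.width, annotation.height)
    image = np.zeros((height, width), dtype=np.uint8)
    for inst in annotation.instances:
        pts = np.array([kp.xy() for kp in inst.keypoints])
        center = pts.mean(axis=0)
        spread = pts.std(axis=0)
        tail = pts[1]  # body_tail in canonical order
        angle = math.atan2(center[1] - tail[1], center[0] - tail[0])
        rr, cc = ellipse(
            center[1], center[0],
            max(float(spread[1]), 2.0), max(float(spread[0]), 2.0),
            shape=image.shape, rotation=-angle,
        )
        image[rr, cc] = BODY_VALUE
        for kp in inst.keypoints:
            if kp.v == 1:
                rr, cc = disk((kp.y, kp.x), 3.0, shape=image.shape)
                image[rr, cc] = KEYPOINT_VALUE
    return image
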