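"""Keypoint-level metrics: CKS, pixel error, per-keypoint RMSE and PCK.

The chicken keypoint similarity (CKS) adapts COCO's object keypoint
similarity to the 10-point chicken schema.  For a ground-truth instance
``BT`` and a prediction ``BP`` with visibilities ``v_i``::

    CKS = sum_i exp(-d_i^2 / (2 * alpha * beta_i^2)) * v_i  /  sum_i v_i

where ``d_i`` is the Euclidean pixel distance between the i-th keypoints,
``alpha`` is the instance scale (ground-truth box area in px^2) and
``beta_i`` the per-keypoint normalization constant.  CKS lies in [0, 1]:
1 means identical poses, 0 completely dissimilar.  Only keypoints with
ground-truth visibility 1 contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .schema_io import (
    KeypointSchema,
    PoseInstance,
    UndefinedMetricError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# CKS
# ---------------------------------------------------------------------------

def cks(gt: PoseInstance, pred: PoseInstance, area: float,
        schema: KeypointSchema) -> float:
    """Chicken keypoint similarity between a GT instance and a prediction.

    Parameters
    ----------
    gt, pred
        Instances conforming to ``schema``.  Only the GT visibility gates
        inclusion; predicted visibility is ignored.
    area
        Scale factor alpha: the ground-truth bounding-box area in px^2.

    Returns
    -------
    float in [0, 1].

    Raises
    ------
    ValidationError
        If ``area <= 0``.
    UndefinedMetricError
        If no GT keypoint is visible.
    """
    if area <= 0:
        raise ValidationError(f"area must be > 0, got {area}")
    gt.check_schema(schema)
    pred.check_schema(schema)
    v = np.array([kp.v for kp in gt.keypoints], dtype=float)
    if v.sum() == 0:
        raise UndefinedMetricError("CKS undefined: no visible GT keypoint")
    gxy = np.array([kp.xy() for kp in gt.keypoints], dtype=float)
    pxy = np.array([kp.xy() for kp in pred.keypoints], dtype=float)
    d2 = ((gxy - pxy) ** 2).sum(axis=1)
    betas = np.asarray(schema.betas, dtype=float)
    kernel = np.exp(-d2 / (2.0 * area * betas ** 2))
    return float((kernel * v).sum() / v.sum())


# ---------------------------------------------------------------------------
# Pixel error and RMSE
# ---------------------------------------------------------------------------

def pixel_error(gt: tuple[float, float], pred: tuple[float, float]) -> float:
    """Euclidean distance in pixels between a true and a predicted point."""
    return math.hypot(gt[0] - pred[0], gt[1] - pred[1])


@dataclass(frozen=True)
class MatchedKeypointPair:
    """A GT/predicted keypoint pair from one matched instance.

    Created only for keypoints whose ground-truth visibility is 1.
    ``norm_length`` optionally carries the matched GT box diagonal for
    instance-level PCK normalization.
    """

    keypoint_index: int
    gt: tuple[float, float]
    pred: tuple[float, float]
    image_id: int
    norm_length: float | None = None

    def error(self) -> float:
        return pixel_error(self.gt, self.pred)


def rmse_per_keypoint(pairs: Sequence[MatchedKeypointPair],
                      schema: KeypointSchema,
                      pooled_rule: str = "pooled_rms",
                      ) -> tuple[dict[str, float], float | None]:
    """Per-keypoint RMSE table plus one pooled summary value.

    RMSE_k = sqrt(mean of squared pixel errors over the pairs of keypoint k).
    Keypoints with no pairs are absent from the table (not reported as 0).

    ``pooled_rule`` selects the aggregation of the summary value:
    ``"pooled_rms"`` pools all squared errors before the root (each pair
    weighted equally), ``"keypoint_mean"`` averages the per-keypoint RMSEs
    (each keypoint weighted equally).

    Returns ``(table, pooled)``; pooled is None on empty input.
    """
    if pooled_rule not in ("pooled_rms", "keypoint_mean"):
        raise ValidationError(f"unknown pooled_rule {pooled_rule!r}")
    sq: dict[int, list[float]] = {}
    for p in pairs:
        if not 0 <= p.keypoint_index < schema.n_keypoints:
            raise ValidationError(f"keypoint index {p.keypoint_index} invalid")
        sq.setdefault(p.keypoint_index, []).append(p.error() ** 2)
    table = {
        schema.names[i]: float(np.sqrt(np.mean(errs)))
        for i, errs in sorted(sq.items())
    }
    if not table:
        return {}, None
    if pooled_rule == "pooled_rms":
        all_sq = [e for errs in sq.values() for e in errs]
        pooled = float(np.sqrt(np.mean(all_sq)))
    else:
        pooled = float(np.mean(list(table.values())))
    return table, pooled


# ---------------------------------------------------------------------------
# PCK
# ---------------------------------------------------------------------------

class PckNormalizer(str, Enum):
    BBOX_DIAGONAL = "bbox_diagonal"
    BBOX_MAX_SIDE = "bbox_max_side"
    REFERENCE_SEGMENT = "reference_segment"


@dataclass(frozen=True)
class PckConfig:
    """PCK convention: which reference length, and the threshold fraction.

    The default normalizer is the GT bounding-box diagonal with tau = 0.05.
    There is no established chicken analog of the human head length used by
    PCKh, so this is a declared toolkit convention.
    """

    normalizer: PckNormalizer = PckNormalizer.BBOX_DIAGONAL
    tau: float = 0.05
    reference_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError(f"tau must be > 0, got {self.tau}")


def pck(pairs: Sequence[MatchedKeypointPair],
        normalizers: Mapping[int, float] | float,
        config: PckConfig = PckConfig()) -> float:
    """Percentage of correct keypoints.

    A pair counts as correct when its pixel error is strictly less than
    ``tau * L`` with reference length ``L``.  ``L`` is the pair's own
    ``norm_length`` when set; otherwise it is looked up per image in
    ``normalizers`` (a single float applies everywhere).

    Raises
    ------
    UndefinedMetricError
        On empty ``pairs``.
    ValidationError
        On a non-positive reference length.
    """
    if not pairs:
        raise UndefinedMetricError("PCK undefined on zero keypoint pairs")
    correct = 0
    for p in pairs:
        if p.norm_length is not None:
            length = p.norm_length
        elif isinstance(normalizers, Mapping):
            length = normalizers[p.image_id]
        else:
            length = float(normalizers)
        if length <= 0:
            raise ValidationError(f"normalizer {length} must be > 0")
        if p.error() < config.tau * length:
            correct += 1
    return correct / len(pairs)


def instance_keypoint_pairs(gt: PoseInstance, pred: PoseInstance,
                            image_id: int,
                            schema: KeypointSchema,
                            ) -> list[MatchedKeypointPair]:
    """Expand one matched GT/prediction instance into keypoint pairs.

    One pair per GT-visible keypoint; ``norm_length`` is the GT box diagonal.
    """
    gt.check_schema(schema)
    pred.check_schema(schema)
    diag = gt.box.diagonal()
    return [
        MatchedKeypointPair(
            keypoint_index=i,
            gt=gkp.xy(),
            pred=pkp.xy(),
            image_id=image_id,
            norm_length=diag,
        )
        for i, (gkp, pkp) in enumerate(zip(gt.keypoints, pred.keypoints))
        if gkp.v == 1
    ]
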