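"""Instance-level evaluation: CKS matching, precision/recall, mAP, mAR.

The matcher is the COCO greedy convention, stated explicitly because the
choice matters: within one image, predictions are processed in descending
score order and each is assigned to the not-yet-matched ground-truth
instance with the highest CKS.  The prediction is a true positive iff that
best CKS reaches the similarity threshold; otherwise it is a false positive
and does not consume a ground truth.  Unmatched ground truths are false
negatives.  Score ties among predictions and CKS ties among ground truths
break by input order, so evaluation is fully deterministic.

AP at one threshold is the 101-point interpolated average precision: the
mean over the recall grid {0.00, 0.01, ..., 1.00} of the best precision
achieved at any rank whose recall reaches that level.  AR at one threshold
is the maximum attainable recall (all predictions admitted).  mAP and mAR
average over the 10 CKS thresholds {0.50, 0.55, ..., 0.95}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .schema_io import (
    KeypointSchema,
    SceneAnnotation,
    ScenePrediction,
    UndefinedMetricError,
    ValidationError,
)
from .similarity_metrics import (
    MatchedKeypointPair,
    PckConfig,
    cks,
    instance_keypoint_pairs,
    pck,
    rmse_per_keypoint,
)

logger = logging.getLogger(__name__)

DEFAULT_CKS_THRESHOLDS: tuple[float, ...] = tuple(
    round(0.50 + 0.05 * i, 2) for i in range(10)
)
DEFAULT_RECALL_GRID: tuple[float, ...] = tuple(
    round(0.01 * i, 2) for i in range(101)
)
DEFAULT_HISTOGRAM_BINS: tuple[float, ...] = tuple(
    round(0.1 * i, 1) for i in range(11)
)


@dataclass(frozen=True)
class EvalConfig:
    """Thresholds, recall grid and histogram binning for evaluation."""

    cks_thresholds: tuple[float, ...] = DEFAULT_CKS_THRESHOLDS
    recall_grid: tuple[float, ...] = DEFAULT_RECALL_GRID
    histogram_bins: tuple[float, ...] = DEFAULT_HISTOGRAM_BINS

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.cks_thresholds[1:],
                                      self.cks_thresholds)):
            raise ValidationError("cks_thresholds must be strictly increasing")


@dataclass(frozen=True)
class PredictionRecord:
    """Evaluation outcome for one prediction at one threshold."""

    image_id: int
    score: float
    is_tp: bool
    matched_gt: int | None  # GT index within its image, or None
    cks: float | None       # CKS against the matched/best GT, None if no GT


@dataclass
class MatchResult:
    """All prediction records and FN counts at one similarity threshold."""

    threshold: float
    records: list[PredictionRecord] = field(default_factory=list)
    fn_per_image: dict[int, int] = field(default_factory=dict)
    n_gt: int = 0

    def n_tp(self) -> int:
        return sum(r.is_tp for r in self.records)


def _cks_matrix(gt: SceneAnnotation, pred: ScenePrediction,
                schema: KeypointSchema) -> tuple[np.ndarray, list[int]]:
    """CKS of every prediction against every evaluable GT instance.

    GT instances with zero visible keypoints are excluded (logged); returns
    the matrix (n_pred x n_gt_kept) and the kept GT indices.
    """
    kept = [i for i, g in enumerate(gt.instances) if g.n_visible() > 0]
    skipped = len(gt.instances) - len(kept)
    if skipped:
        logger.info("image %s: skipped %d GT instance(s) with no visible "
                    "keypoints", gt.image_id, skipped)
    mat = np.zeros((len(pred.instances), len(kept)))
    for pi, p in enumerate(pred.instances):
        for column, gi in enumerate(kept):
            g = gt.instances[gi]
            mat[pi, column] = cks(g, p, g.box.area(), schema)
    return mat, kept


def match_scene(gt: SceneAnnotation, pred: ScenePrediction, threshold: float,
                schema: KeypointSchema) -> MatchResult:
    """Greedy CKS matching of one image's predictions at one threshold."""
    if gt.image_id != pred.image_id:
        raise ValidationError(
            f"image id mismatch: GT {gt.image_id} vs pred {pred.image_id}"
        )
    result = MatchResult(threshold=threshold)
    mat, kept = _cks_matrix(gt, pred, schema)
    result.n_gt = len(kept)

    # descending score, stable => ties by input order
    order = sorted(range(len(pred.instances)),
                   key=lambda i: -pred.instances[i].score)
    taken: set[int] = set()
    records: dict[int, PredictionRecord] = {}
    for pi in order:
        best_col, best_cks = None, -1.0
        for column in range(len(kept)):
            if column in taken:
                continue
            if mat[pi, column] > best_cks:  # strict > keeps first on ties
                best_col, best_cks = column, mat[pi, column]
        if best_col is not None and best_cks >= threshold:
            taken.add(best_col)
            records[pi] = PredictionRecord(
                image_id=gt.image_id, score=pred.instances[pi].score,
                is_tp=True, matched_gt=kept[best_col], cks=best_cks,
            )
        else:
            records[pi] = PredictionRecord(
                image_id=gt.image_id, score=pred.instances[pi].score,
                is_tp=False, matched_gt=None,
                cks=best_cks if best_col is not None else None,
            )
    # records kept in score-processing order for deterministic pooling
    result.records = [records[pi] for pi in order]
    result.fn_per_image[gt.image_id] = len(kept) - len(taken)
    return result


def match_dataset(annotations: Sequence[SceneAnnotation],
                  predictions: Sequence[ScenePrediction],
                  threshold: float,
                  schema: KeypointSchema) -> MatchResult:
    """Pool :func:`match_scene` over all images at one threshold."""
    pred_by_image = {p.image_id: p for p in predictions}
    if len(pred_by_image) != len(predictions):
        raise ValidationError("duplicate ScenePrediction for one image")
    pooled = MatchResult(threshold=threshold)
    for scene in annotations:
        pred = pred_by_image.get(scene.image_id,
                                 ScenePrediction(scene.image_id, ()))
        part = match_scene(scene, pred, threshold, schema)
        pooled.records.extend(part.records)
        pooled.fn_per_image.update(part.fn_per_image)
        pooled.n_gt += part.n_gt
    return pooled


def precision_recall_points(result: MatchResult
                            ) -> list[tuple[float, float]]:
    """Cumulative (recall, precision) at each rank, pooled over images.

    Predictions are sorted by descending score (stable across the pooled
    image order).  Raises on a dataset with zero ground truths.
    """
    if result.n_gt == 0:
        raise UndefinedMetricError("PR curve undefined with zero GT")
    ranked = sorted(result.records, key=lambda r: -r.score)
    points = []
    tp = fp = 0
    for rec in ranked:
        if rec.is_tp:
            tp += 1
        else:
            fp += 1
        points.append((tp / result.n_gt, tp / (tp + fp)))
    return points


def average_precision(pr_points: Sequence[tuple[float, float]],
                      recall_grid: Sequence[float] = DEFAULT_RECALL_GRID,
                      ) -> float:
    """101-point interpolated AP: grid mean of max precision at recall >= r."""
    if not pr_points:
        return 0.0
    recalls = np.array([r for r, _ in pr_points])
    precisions = np.array([p for _, p in pr_points])
    total = 0.0
    for level in recall_grid:
        mask = recalls >= level
        total += float(precisions[mask].max()) if mask.any() else 0.0
    return total / len(recall_grid)


def ar_at_threshold(result: MatchResult) -> float:
    """Maximum attainable recall at one threshold (all predictions in)."""
    if result.n_gt == 0:
        raise UndefinedMetricError("AR undefined with zero GT")
    return result.n_tp() / result.n_gt


def mean_ap(aps: Mapping[float, float],
            thresholds: Sequence[float] = DEFAULT_CKS_THRESHOLDS) -> float:
    """Unweighted mean AP over the configured CKS thresholds."""
    missing = [t for t in thresholds if t not in aps]
    if missing:
        raise ValidationError(f"missing AP at thresholds {missing}")
    return float(np.mean([aps[t] for t in thresholds]))


def mean_ar(ars: Mapping[float, float],
            thresholds: Sequence[float] = DEFAULT_CKS_THRESHOLDS) -> float:
    """Unweighted mean AR over the configured CKS thresholds."""
    missing = [t for t in thresholds if t not in ars]
    if missing:
        raise ValidationError(f"missing AR at thresholds {missing}")
    return float(np.mean([ars[t] for t in thresholds]))


def cks_histogram(values: Sequence[float],
                  bins: Sequence[float] = DEFAULT_HISTOGRAM_BINS,
                  ) -> np.ndarray:
    """Histogram of matched-instance CKS values on [0, 1].

    The last bin is right-closed so a perfect similarity of 1.0 is counted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValidationError("CKS values must lie in [0, 1]")
    counts, _ = np.histogram(arr, bins=np.asarray(bins, dtype=float))
    return counts


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Combined evaluation output.

    All similarity-derived quantities are in [0, 1]; RMSE and pixel-error
    fields are in pixels.  ``rmse_pooled_rms`` pools squared errors over all
    pairs; ``rmse_keypoint_mean`` averages the per-keypoint RMSE column —
    two defensible summary conventions, both reported.
    """

    ap_per_threshold: dict[float, float]
    ar_per_threshold: dict[float, float]
    map: float
    mar: float
    pck: float | None
    rmse_per_keypoint: dict[str, float]
    rmse_pooled_rms: float | None
    rmse_keypoint_mean: float | None
    pe_mean_per_keypoint: dict[str, float]
    cks_histogram_counts: list[int]
    cks_histogram_bins: list[float]
    n_images: int
    n_gt_instances: int
    n_pred_instances: int
    n_skipped_gt: int

    def to_dict(self) -> dict:
        return {
            "map": self.map,
            "mar": self.mar,
            "pck": self.pck,
            "ap_per_threshold": {f"{t:.2f}": v
                                 for t, v in self.ap_per_threshold.items()},
            "ar_per_threshold": {f"{t:.2f}": v
                                 for t, v in self.ar_per_threshold.items()},
            "rmse_per_keypoint": self.rmse_per_keypoint,
            "rmse_pooled_rms": self.rmse_pooled_rms,
            "rmse_keypoint_mean": self.rmse_keypoint_mean,
            "pe_mean_per_keypoint": self.pe_mean_per_keypoint,
            "cks_histogram": {
                "bins": self.cks_histogram_bins,
                "counts": self.cks_histogram_counts,
            },
            "counts": {
                "images": self.n_images,
                "gt_instances": self.n_gt_instances,
                "pred_instances": self.n_pred_instances,
                "skipped_gt_instances": self.n_skipped_gt,
            },
        }


def _pair_instances(annotations: Sequence[SceneAnnotation],
                    predictions: Sequence[ScenePrediction],
                    schema: KeypointSchema,
                    ) -> tuple[list[MatchedKeypointPair], list[float]]:
    """Instance pairing for keypoint-level metrics and the CKS histogram.

    Greedy by score with best-CKS assignment, no similarity threshold: every
    prediction that can claim an unmatched GT yields keypoint pairs and one
    histogram value.
    """
    pred_by_image = {p.image_id: p for p in predictions}
    pairs: list[MatchedKeypointPair] = []
    cks_values: list[float] = []
    for scene in annotations:
        pred = pred_by_image.get(scene.image_id)
        if pred is None or not pred.instances:
            continue
        mat, kept = _cks_matrix(scene, pred, schema)
        order = sorted(range(len(pred.instances)),
                       key=lambda i: -pred.instances[i].score)
        taken: set[int] = set()
        for pi in order:
            best_col, best_cks = None, -1.0
            for column in range(len(kept)):
                if column in taken:
                    continue
                if mat[pi, column] > best_cks:
                    best_col, best_cks = column, mat[pi, column]
            if best_col is None:
                continue
            taken.add(best_col)
            g = scene.instances[kept[best_col]]
            pairs.extend(instance_keypoint_pairs(
                g, pred.instances[pi], scene.image_id, schema))
            cks_values.append(best_cks)
    return pairs, cks_values


def evaluate(annotations: Sequence[SceneAnnotation],
             predictions: Sequence[ScenePrediction],
             config: EvalConfig = EvalConfig(),
             pck_config: PckConfig = PckConfig(),
             schema: KeypointSchema | None = None) -> MetricsReport:
    """Run the complete evaluation and return a :class:`MetricsReport`.

    Every prediction's ``image_id`` must exist in the annotation set.
    Deterministic for fixed inputs.
    """
    if schema is None:
        from .schema_io import default_chicken_schema
        schema = default_chicken_schema()
    gt_ids = {a.image_id for a in annotations}
    pred_ids = {p.image_id for p in predictions}
    unknown = pred_ids - gt_ids
    if unknown:
        raise ValidationError(f"predictions reference unknown images "
                              f"{sorted(unknown)}")

    n_gt = sum(len(a.instances) for a in annotations)
    n_evaluable = sum(
        sum(1 for g in a.instances if g.n_visible() > 0) for a in annotations
    )
    n_pred = sum(len(p.instances) for p in predictions)

    aps: dict[float, float] = {}
    ars: dict[float, float] = {}
    for threshold in config.cks_thresholds:
        result = match_dataset(annotations, predictions, threshold, schema)
        if result.n_gt == 0:
            raise UndefinedMetricError("evaluation undefined with zero GT")
        if result.records:
            aps[threshold] = average_precision(
                precision_recall_points(result), config.recall_grid)
        else:
            aps[threshold] = 0.0
        ars[threshold] = ar_at_threshold(result)

    pairs, cks_values = _pair_instances(annotations, predictions, schema)
    if pairs:
        pck_value = pck(pairs, {}, pck_config)
        rmse_table, pooled_rms = rmse_per_keypoint(pairs, schema,
                                                   "pooled_rms")
        _, kp_mean = rmse_per_keypoint(pairs, schema, "keypoint_mean")
        pe_sums: dict[int, list[float]] = {}
        for p in pairs:
            pe_sums.setdefault(p.keypoint_index, []).append(p.error())
        pe_mean = {schema.names[i]: float(np.mean(v))
                   for i, v in sorted(pe_sums.items())}
    else:
        pck_value, rmse_table, pooled_rms, kp_mean = None, {}, None, None
        pe_mean = {}
    counts = cks_histogram(cks_values, config.histogram_bins)

    return MetricsReport(
        ap_per_threshold=aps,
        ar_per_threshold=ars,
        map=mean_ap(aps, config.cks_thresholds),
        mar=mean_ar(ars, config.cks_thresholds),
        pck=pck_value,
        rmse_per_keypoint=rmse_table,
        rmse_pooled_rms=pooled_rms,
        rmse_keypoint_mean=kp_mean,
        pe_mean_per_keypoint=pe_mean,
        cks_histogram_counts=[int(c) for c in counts],
        cks_histogram_bins=[float(b) for b in config.histogram_bins],
        n_images=len(annotations),
        n_gt_instances=n_gt,
        n_pred_instances=n_pred,
        n_skipped_gt=n_gt - n_evaluable,
    )
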