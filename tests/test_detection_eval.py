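import numpy as np
import pytest

from mcpose import (
    BoundingBox,
    EvalConfig,
    Keypoint,
    PoseInstance,
    SceneAnnotation,
    ScenePrediction,
    UndefinedMetricError,
    ValidationError,
    average_precision,
    ar_at_threshold,
    cks,
    cks_histogram,
    evaluate,
    match_dataset,
    match_scene,
    mean_ap,
    mean_ar,
    precision_recall_points,
)
from mcpose.detection_eval import DEFAULT_RECALL_GRID

from conftest import make_instance, random_scene
from oracle_utils import oracle_evaluate


def shifted(inst, dx, score):
    xy = np.array([kp.xy() for kp in inst.keypoints]) + [dx, 0]
    return make_instance(xy, box=inst.box, score=score)


class TestMatchScene:
    def test_exact_prediction_is_tp_at_highest_threshold(self, schema):
        gt, _ = random_scene(np.random.default_rng(0), schema, 1, 1, 0)
        pred = ScenePrediction(1, (make_instance(
            [kp.xy() for kp in gt.instances[0].keypoints],
            box=gt.instances[0].box, score=0.9),))
        result = match_scene(gt, pred, 0.95, schema)
        assert result.n_tp() == 1
        assert result.fn_per_image[1] == 0
        assert result.records[0].cks == 1.0

    def test_higher_score_matches_first_even_with_lower_cks(self, schema):
        """The greedy rule processes by score: the 0.9-score prediction
        claims the single GT even though the 0.8-score one fits better."""
        gt, _ = random_scene(np.random.default_rng(1), schema, 1, 1, 0)
        g = gt.instances[0]
        near = shifted(g, 0.5, score=0.8)    # higher CKS
        far = shifted(g, 2.0, score=0.9)     # lower CKS, higher score
        area = g.box.area()
        assert cks(g, far, area, schema) > 0.1
        assert cks(g, near, area, schema) > cks(g, far, area, schema)
        result = match_scene(gt, ScenePrediction(1, (near, far)), 0.1,
                             schema)
        by_score = {r.score: r.is_tp for r in result.records}
        assert by_score[0.9] is True
        assert by_score[0.8] is False

    def test_no_predictions_all_fn(self, schema):
        gt, _ = random_scene(np.random.default_rng(2), schema, 1, 2, 0)
        result = match_scene(gt, ScenePrediction(1, ()), 0.5, schema)
        assert result.n_tp() == 0
        assert result.fn_per_image[1] == 2

    def test_duplicate_detections_yield_one_tp(self, schema):
        gt, _ = random_scene(np.random.default_rng(3), schema, 1, 1, 0)
        g = gt.instances[0]
        dupes = tuple(shifted(g, 0.0, score=s) for s in (0.9, 0.8, 0.7))
        result = match_scene(gt, ScenePrediction(1, dupes), 0.5, schema)
        assert result.n_tp() == 1
        assert sum(not r.is_tp for r in result.records) == 2

    def test_below_threshold_prediction_does_not_consume_gt(self, schema):
        gt, _ = random_scene(np.random.default_rng(4), schema, 1, 1, 0)
        g = gt.instances[0]
        poor = shifted(g, 500.0, score=0.95)
        good = shifted(g, 0.0, score=0.5)
        result = match_scene(gt, ScenePrediction(1, (poor, good)), 0.9,
                             schema)
        by_score = {r.score: r for r in result.records}
        assert by_score[0.95].is_tp is False
        assert by_score[0.5].is_tp is True

    def test_mismatched_image_ids_rejected(self, schema):
        gt, _ = random_scene(np.random.default_rng(5), schema, 1, 1, 0)
        with pytest.raises(ValidationError):
            match_scene(gt, ScenePrediction(2, ()), 0.5, schema)


class TestPrCurveAndAp:
    def test_single_tp_gives_perfect_point(self, schema):
        gt, _ = random_scene(np.random.default_rng(6), schema, 1, 1, 0)
        pred = ScenePrediction(1, (shifted(gt.instances[0], 0.0, 0.9),))
        result = match_dataset([gt], [pred], 0.5, schema)
        assert precision_recall_points(result) == [(1.0, 1.0)]
        assert average_precision([(1.0, 1.0)]) == 1.0

    def test_one_tp_of_two_gt(self, schema):
        gt, _ = random_scene(np.random.default_rng(7), schema, 1, 2, 0)
        pred = ScenePrediction(1, (shifted(gt.instances[0], 0.0, 0.9),))
        result = match_dataset([gt], [pred], 0.5, schema)
        assert precision_recall_points(result) == [(0.5, 1.0)]

    def test_tp_then_fp_curve(self, schema):
        gt, _ = random_scene(np.random.default_rng(8), schema, 1, 1, 0)
        g = gt.instances[0]
        pred = ScenePrediction(1, (shifted(g, 0.0, 0.9),
                                   shifted(g, 900.0, 0.8)))
        result = match_dataset([gt], [pred], 0.5, schema)
        assert precision_recall_points(result) == [(1.0, 1.0), (1.0, 0.5)]

    def test_ap_of_half_recall_plateau(self):
        # precision 1 visible at the 51 grid levels <= 0.5, zero beyond
        assert average_precision([(0.5, 1.0)]) == pytest.approx(51 / 101)

    def test_ap_empty_curve(self):
        assert average_precision([]) == 0.0

    def test_zero_gt_is_undefined(self, schema):
        gt = SceneAnnotation(1, 640, 480, ())
        result = match_dataset([gt], [], 0.5, schema)
        with pytest.raises(UndefinedMetricError):
            precision_recall_points(result)


class TestMeanApAr:
    def test_mean_over_thresholds(self):
        thresholds = EvalConfig().cks_thresholds
        aps = {t: (1.0 if i < 5 else 0.0)
               for i, t in enumerate(thresholds)}
        assert mean_ap(aps, thresholds) == 0.5
        assert mean_ar(aps, thresholds) == 0.5

    def test_missing_threshold_rejected(self):
        thresholds = EvalConfig().cks_thresholds
        aps = {t: 1.0 for t in thresholds[:-1]}
        with pytest.raises(ValidationError):
            mean_ap(aps, thresholds)

    def test_ar_is_max_recall(self, schema):
        gt, _ = random_scene(np.random.default_rng(9), schema, 1, 2, 0)
        pred = ScenePrediction(1, (shifted(gt.instances[0], 0.0, 0.2),))
        result = match_dataset([gt], [pred], 0.5, schema)
        assert ar_at_threshold(result) == 0.5


class TestHistogram:
    def test_one_is_counted_in_last_bin(self):
        counts = cks_histogram([1.0, 1.0, 0.5])
        assert counts[-1] == 2
        assert counts[5] == 1  # 0.5 falls in [0.5, 0.6)

    def test_empty_input(self):
        assert cks_histogram([]).sum() == 0

    def test_conservation(self):
        rng = np.random.default_rng(10)
        values = rng.uniform(0, 1, size=1000)
        assert cks_histogram(values).sum() == 1000

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            cks_histogram([1.2])


class TestEvaluate:
    def test_perfect_predictions(self, schema):
        rng = np.random.default_rng(11)
        annotations, predictions = [], []
        for i in range(4):
            gt, _ = random_scene(rng, schema, i + 1, 2, 0)
            annotations.append(gt)
            predictions.append(ScenePrediction(
                i + 1, tuple(shifted(g, 0.0, 0.9) for g in gt.instances)))
        report = evaluate(annotations, predictions, schema=schema)
        assert report.map == 1.0
        assert report.mar == 1.0
        assert report.pck == 1.0
        assert all(v == 0.0 for v in report.rmse_per_keypoint.values())
        assert report.cks_histogram_counts[-1] == 8

    def test_empty_predictions(self, schema):
        rng = np.random.default_rng(12)
        gt, _ = random_scene(rng, schema, 1, 2, 0)
        report = evaluate([gt], [], schema=schema)
        assert report.map == 0.0
        assert report.mar == 0.0
        assert report.pck is None
        assert report.rmse_per_keypoint == {}

    def test_unknown_image_id_rejected(self, schema):
        rng = np.random.default_rng(13)
        gt, pred = random_scene(rng, schema, 1, 1, 1)
        bad = ScenePrediction(99, pred.instances)
        with pytest.raises(ValidationError):
            evaluate([gt], [bad], schema=schema)

    def test_planted_tp_fp_pattern(self, schema):
        """2 GT, one exact match + one far FP: hand-computed report."""
        rng = np.random.default_rng(14)
        gt, _ = random_scene(rng, schema, 1, 2, 0)
        pred = ScenePrediction(1, (
            shifted(gt.instances[0], 0.0, 0.9),
            shifted(gt.instances[1], 5000.0, 0.8),
        ))
        report = evaluate([gt], [pred], schema=schema)
        # at every threshold: ranked [TP, FP] with 2 GT
        # -> PR [(0.5, 1.0), (0.5, 0.5)], AP = 51/101, AR = 0.5
        assert report.map == pytest.approx(51 / 101)
        assert report.mar == 0.5

    def test_matches_brute_force_oracle_on_random_scenes(self, schema):
        rng = np.random.default_rng(77)
        config = EvalConfig()
        for _ in range(40):
            annotations, predictions = [], []
            for i in range(rng.integers(1, 4)):
                n_gt = int(rng.integers(1, 4))
                n_pred = int(rng.integers(0, 5))
                gt, pred = random_scene(rng, schema, i + 1, n_gt, n_pred)
                annotations.append(gt)
                predictions.append(pred)
            report = evaluate(annotations, predictions, config,
                              schema=schema)
            expected = oracle_evaluate(annotations, predictions,
                                       config.cks_thresholds,
                                       DEFAULT_RECALL_GRID, schema.betas)
            assert report.map == pytest.approx(expected["map"], abs=1e-12)
            assert report.mar == pytest.approx(expected["mar"], abs=1e-12)
            for t, ap in zip(config.cks_thresholds, expected["ap"]):
                assert report.ap_per_threshold[t] == pytest.approx(
                    ap, abs=1e-12)


class TestInvariants:
    def test_tp_fp_fn_counting(self, schema):
        rng = np.random.default_rng(21)
        thresholds = EvalConfig().cks_thresholds
        for _ in range(20):
            gt, pred = random_scene(rng, schema, 1,
                                    int(rng.integers(1, 4)),
                                    int(rng.integers(0, 5)))
            for threshold in thresholds:
                result = match_scene(gt, pred, threshold, schema)
                tp = result.n_tp()
                fp = len(result.records) - tp
                assert tp + fp == len(pred.instances)
                assert tp + result.fn_per_image[1] == len(gt.instances)

    def test_ap_ar_non_increasing_in_threshold(self, schema):
        rng = np.random.default_rng(22)
        for _ in range(10):
            annotations, predictions = [], []
            for i in range(3):
                gt, pred = random_scene(rng, schema, i + 1,
                                        int(rng.integers(1, 4)),
                                        int(rng.integers(1, 5)))
                annotations.append(gt)
                # mix in near-misses so mid thresholds are informative
                noisy = tuple(
                    shifted(g, float(rng.uniform(0, 15)),
                            float(rng.uniform(0.1, 1.0)))
                    for g in gt.instances
                ) + pred.instances
                predictions.append(ScenePrediction(i + 1, noisy))
            report = evaluate(annotations, predictions, schema=schema)
            thresholds = EvalConfig().cks_thresholds
            aps = [report.ap_per_threshold[t] for t in thresholds]
            ars = [report.ar_per_threshold[t] for t in thresholds]
            assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(ars, ars[1:]))

    def test_ap_bounded_by_max_recall(self, schema):
        rng = np.random.default_rng(23)
        gt, pred = random_scene(rng, schema, 1, 3, 4)
        report = evaluate([gt], [pred], schema=schema)
        for t in EvalConfig().cks_thresholds:
            assert report.ap_per_threshold[t] <= \
                report.ar_per_threshold[t] + 1e-12
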