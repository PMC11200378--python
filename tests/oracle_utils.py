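"""Independent brute-force re-derivations of the evaluation mathematics.

Everything here is deliberately written as plain-Python loops with no reuse
of the library's vectorised code paths, so it can serve as an oracle for
the implementation.
"""

import math


def oracle_cks(gt, pred, area, betas):
    """Per-point loop evaluation of the CKS Gaussian-kernel similarity."""
    num = 0.0
    den = 0.0
    for g, p, beta in zip(gt.keypoints, pred.keypoints, betas):
        if g.v != 1:
            continue
        d2 = (g.x - p.x) ** 2 + (g.y - p.y) ** 2
        num += math.exp(-d2 / (2.0 * area * beta * beta))
        den += 1.0
    return num / den


def oracle_match_image(gt_instances, pred_instances, threshold, betas):
    """Trace the greedy matching rule by hand.

    Predictions in descending score order (ties by input order); each takes
    the unmatched GT with the highest CKS (ties by GT order); TP iff that
    CKS reaches the threshold.  Returns records in processing order as
    (score, is_tp) plus the FN count.
    """
    order = sorted(range(len(pred_instances)),
                   key=lambda i: -pred_instances[i].score)
    evaluable = [g for g in gt_instances
                 if any(k.v == 1 for k in g.keypoints)]
    matched = [False] * len(evaluable)
    records = []
    for pi in order:
        best, best_cks = None, -1.0
        for gi, g in enumerate(evaluable):
            if matched[gi]:
                continue
            value = oracle_cks(g, pred_instances[pi], g.box.area(), betas)
            if value > best_cks:
                best, best_cks = gi, value
        is_tp = best is not None and best_cks >= threshold
        if is_tp:
            matched[best] = True
        records.append((pred_instances[pi].score, is_tp))
    fn = matched.count(False)
    return records, fn, len(evaluable)


def oracle_ap(records, n_gt, recall_grid):
    """Cumulative PR from pooled ranked records, then the grid-max AP."""
    ranked = sorted(records, key=lambda r: -r[0])
    tp = fp = 0
    points = []
    for _, is_tp in ranked:
        if is_tp:
            tp += 1
        else:
            fp += 1
        points.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for level in recall_grid:
        best = 0.0
        for recall, precision in points:
            if recall >= level and precision > best:
                best = precision
        total += best
    return total / len(recall_grid)


def oracle_evaluate(annotations, predictions, thresholds, recall_grid,
                    betas):
    """Full mAP/mAR re-derivation by direct enumeration."""
    pred_by_image = {p.image_id: p for p in predictions}
    aps, ars = [], []
    for threshold in thresholds:
        records = []
        n_gt = 0
        tp_total = 0
        for scene in annotations:
            pred = pred_by_image.get(scene.image_id)
            insts = pred.instances if pred is not None else ()
            recs, _, n_eval = oracle_match_image(
                scene.instances, insts, threshold, betas)
            records.extend(recs)
            n_gt += n_eval
            tp_total += sum(1 for _, is_tp in recs if is_tp)
        aps.append(oracle_ap(records, n_gt, recall_grid) if records else 0.0)
        ars.append(tp_total / n_gt)
    return {
        "ap": aps,
        "ar": ars,
        "map": sum(aps) / len(aps),
        "mar": sum(ars) / len(ars),
    }
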