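# Methods

This note documents the models, conventions and numerical choices behind
`mcpose`, and what the synthetic-data tests do and do not establish about
real data.

## Similarity model

CKS is an object-keypoint-similarity kernel specialised to the 10-point
chicken schema.  For keypoint *i* with ground-truth visibility $v_i$ the
per-point term is $\exp(-d_i^2 / (2\alpha\beta_i^2))$, averaged over the
visible points.  Conventions:

- **Scale $\alpha$** is the *ground-truth* box area (px²).  Using the GT
  box rather than the predicted box makes the metric independent of detector
  output, matching standard OKS practice.
- **Visibility gating** uses the GT flag alone; predicted visibility never
  affects CKS (there is a single $v_i$ in the definition).
- $\beta_{\text{body\_center}} = 0.107$, all other $\beta_i = 0.025$.  A
  larger $\beta$ encodes higher annotation ambiguity: the kernel tolerance
  scales as $\beta_i\sqrt{\alpha}$, so on a 100×100 px box the body-center
  kernel has a standard deviation of ~10.7 px versus 2.5 px elsewhere.
- An instance whose GT keypoints are all invisible has no defined CKS; such
  instances are excluded from keypoint-level metrics and counted in the
  report's `skipped_gt_instances` diagnostic.

A useful closed form (used by tests and `expected_mean_cks`): under i.i.d.
isotropic Gaussian jitter with per-axis standard deviation $\sigma$,
$d_i^2 \sim \sigma^2\chi^2_2$, so each per-point term has expectation
$v_i^*/(v_i^* + \sigma^2)$ with $v_i^* = \alpha\beta_i^2$.

## Matching and ranking conventions

The similarity definition alone does not determine an evaluation; the
following conventions are deliberate choices, stated prominently because a
different matcher yields different mAP:

- **Greedy matching** per image: predictions in descending score order, each
  assigned to the unmatched GT with the highest CKS; TP iff that CKS
  reaches the threshold.  A below-threshold prediction is an FP and does
  *not* consume a GT.  Score ties break by input order; CKS ties by GT
  order.  This is the COCO matcher and guarantees determinism.
- **AP** is the plain 101-point grid maximum (`max` precision over ranks
  with recall ≥ the grid level, empty max = 0); no extra smoothing.
- **AR** admits all predictions (no max-detections cap): it is the maximum
  attainable recall at the threshold, i.e. final recall of the ranked list.
- **Keypoint-level pairing** (for PCK, RMSE, pixel error and the CKS
  histogram) reuses the greedy score/CKS assignment but without a threshold
  gate, so every prediction that can claim a GT contributes pairs.  Only
  GT-visible keypoints form pairs.
- **PCK** uses a strict `<` comparison against $\tau L$.  $L$ defaults to
  the matched GT box diagonal, $\tau = 0.05$; both are configurable
  (`bbox_max_side` and a reference-segment mode are available).  There is
  no established chicken analog of the head-length reference of PCKh, so
  this is a toolkit convention, not a community standard.
- **RMSE aggregation**: the per-keypoint table is unambiguous, but a single
  "average" row is not — pooling all squared errors (`pooled_rms`) and
  averaging the per-keypoint RMSEs (`keypoint_mean`) both appear in the
  literature and differ when keypoint counts are unbalanced.  Published
  summary rows for this kind of table are not always reconstructible from
  the printed columns, so the report carries both values and claims neither
  as canonical.
- **Histogram**: bins partition [0, 1]; the last bin is right-closed so a
  perfect CKS of 1.0 is counted.

## Top-down pipeline

The pipeline contract is detector → crop/resize → pose backend → heatmap
decode → back-projection:

- **Crop**: the box is mapped onto the fixed input (default 512×512) by a
  direct non-uniform affine (scale $W/w$, $H/h$), the most literal reading
  of "resize every box to the same size"; out-of-image regions are
  zero-padded and sampling is bilinear.  The forward/inverse affine pair is
  recorded and composes to identity well below 1e-9 px.
- **Decoding**: per-keypoint argmax (row-major first index on ties), cell
  (r, c) → crop pixel (c·stride, r·stride), then an optional quarter-stride
  shift toward the larger axial neighbour — the standard simple-baselines
  refinement, which bounds the quantization error by stride/4 for a
  symmetric unimodal peak (stride/2 without refinement or at map borders).
  Peaks below the visibility floor (default 0.05) are emitted with v = 0.
  The heatmap stride is a parameter (default 4) since deconvolution-head
  resolutions vary between architectures.
- **Scores**: the instance score is the detection score; a mean-peak fusion
  mode exists behind a flag.  The detector score floor defaults to 0.3.
- **Backends** are plain callables.  The pose-backend signature is
  `(crop, transform) → HeatmapStack`: the crop transform is passed along so
  the bundled *oracle* backend can project ground truth into the crop frame
  and emit ideal Gaussian heatmaps; a model-driven backend simply ignores
  the second argument.  No network weights ship with the toolkit — training
  and GPU inference are out of scope by design.
- `compound_scaling` implements the EfficientNet-style sizing rule
  $d = \alpha^\phi$, $w = \beta^\phi$, $r = \gamma^\phi$ with the FLOPs
  constraint residual $|\alpha\beta^2\gamma^2 - 2|$ reported and checked
  against a configurable tolerance (default 0.1, since the constraint is
  approximate by construction).

## Synthetic scenes and the noise model

`generate_dataset` places a stylised 10-keypoint body template (scaled,
rotated, translated) inside the image; the GT box is the tight keypoint box
inflated by 10% per side.  Predictions derive from GT by, in fixed draw
order per instance: Gaussian jitter (σ, px), left/right pair swap
(probability per pair), keypoint dropout (→ v = 0), box perturbation, and a
truncated-normal score; whole instances are dropped with `p_miss_detection`
and spurious template poses are added with `p_false_detection` per true
bird, with scores drawn from a lower-mean distribution (0.40 ± 0.10 vs
0.85 ± 0.08) so ranking is informative but imperfect.  One seeded generator
consumed in a documented order makes the whole stream byte-reproducible.

Default magnitudes (20 images, 2–5 birds of 80–160 px span per 960×720
frame, σ = 1.5 px, dropout 0.05, swap 0.03, missed detection 0.05, spurious
0.08) were chosen once as plausible for a mid-density pen with a
well-trained network; no quantitative noise measurements exist for the
emulated failure modes, so these are coverage-oriented, not calibrated.
Test problem sizes (e.g. 2000 jitter pairs per keypoint, 200 oracle-checked
scenes, 10⁴ Monte-Carlo draws) were likewise fixed as the package's own
choice of statistically sufficient desk-scale runs.

What the simulator does **not** model: photorealistic appearance, geometry-
driven occlusion (visibility is i.i.d. dropout), inter-bird contact,
perspective scaling, video correlation.  Passing tests therefore establish
the correctness of the *mathematics* (metrics, matching, transforms) and
the *plumbing*, not the accuracy of any real detector or pose network; in
particular, benchmark values published for real flocks (mAP ≈ 0.65-level
numbers) require the original dataset and trained weights and are format
targets only.

## Numerical and degenerate-input choices

- Exact identities are honoured where mathematically exact: CKS of
  identical poses is exactly 1.0 (exp(0) carries no rounding).
- JSON serialization uses sorted keys and `repr`-based floats: byte-stable
  and exact on round trip.
- COCO visibility {0, 1, 2} collapses to {0, 1} on read (idempotent).
- Flat heatmaps decode to the first cell with a logged warning; degenerate
  boxes, non-positive areas/normalizers, out-of-range scores and keypoint
  arrays of the wrong length raise validation errors rather than being
  silently coerced.
- Empty inputs: an empty prediction set evaluates to mAP = mAR = 0 with an
  empty keypoint table; PCK/RMSE on zero pairs are undefined (`None` in the
  report) rather than 0.

## Known limitations

- Single category; no identity tracking or video metrics.
- The keypoint-pairing rule for PCK/RMSE (threshold-free greedy match) is a
  convention; papers rarely state theirs, and a different pairing changes
  the keypoint-level numbers on noisy data.
- The skeleton edge set is a drawing convention of this toolkit.
- Bottom-up grouping is out of scope.
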