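# Methods

## The curation problem

Camera traps fire in bursts: one animal visit produces many frames
differing only by a small shift, sensor noise, or an exposure change.
Training an object detector on such data inflates apparent sample size
while teaching the model site-specific backgrounds, which is the main
cause of poor transfer to new camera locations. The workflow implemented
here curates detector datasets around two similarity thresholds and a
deterministic split calculus, and scores detector output with the
PASCAL-VOC protocol. The detector itself is out of scope.

## Structural similarity

Two images are compared by first converting to single-channel grayscale
(Pillow's luma conversion, ITU-R 601 weights) and bilinearly resizing
both to a common `comparison_size` (default 256×256) so differently
sized inputs are commensurable. The score is the windowed SSIM mean

    SSIM(a,b) = mean_w [ (2 μₐμᵦ + C₁)(2 σₐᵦ + C₂)
                        / ((μₐ² + μᵦ² + C₁)(σₐ² + σᵦ² + C₂)) ]

with C₁ = (k₁L)², C₂ = (k₂L)². Defaults follow the SSIM literature:
k₁ = 0.01, k₂ = 0.03, dynamic range L = 255, a 7×7 *uniform* window,
sample (N/(N−1)) normalization for variances/covariance, and the
half-window border excluded from the mean. With these conventions the
implementation agrees with `skimage.metrics.structural_similarity`
(uniform window) to 1e-12, which the test suite asserts as an
independent cross-check; the in-package implementation is built on
`scipy.ndimage.uniform_filter` only. All parameters are configurable
through `SsimParams`.

Two thresholds drive curation, both configurable:

* **0.8, strict `>` — duplicates.** Applied to web-scraped pools.
  Deleting *every* image of a duplicate pair would erase exact
  duplicates entirely, so within each connected component of the
  `> 0.8` graph one seeded-random representative is kept.
* **0.4, inclusive `≥` — capture events.** Frames linked at `≥ 0.4` are
  grouped by connected components (single linkage): a star of pairwise
  comparisons against a test frame generalizes transitively, so frames
  chained through intermediates count as one event even when their
  direct score dips below 0.4. Complete linkage would split such chains;
  the single-linkage choice is deliberate and changes cluster
  boundaries, so it is stated here rather than hidden.

Component finding is delegated to `scipy.sparse.csgraph`; the tests
check it against a brute-force reachability oracle on 500 random
matrices up to n = 12.

## Split calculus

All published split tables reproduce under one rule: **round half up**,
computed in exact decimal arithmetic (never float banker's rounding).

* Base split: train = round-half-up(0.9 · N), validation the remainder,
  membership by seeded shuffle of the sorted id list.
* Infusion: k = round-half-up(p · N_base) camera-trap images join the
  pool *before* splitting, so validation receives its share — the
  published validation counts (e.g. 175 = validation of 1,748 combined,
  not 166 + 9) confirm this ordering.
* Negatives: appended after the split arithmetic (800 train / 200 test
  by default) and never counted in N.

Infusion images are selected one-per-cluster from the capture-event
clustering, visiting clusters in ascending size order (ties by smallest
member id) and wrapping when k exceeds the cluster count; without a
clustering the selection is a plain seeded sample. Whether the original
"SSIM sorted" selection ordered clusters by size or by score is not
recorded anywhere authoritative; small-first maximizes the variability
of the first few picks and is the package's choice.

Two boundary decisions:

* At exact .5 boundaries the published tables are internally
  inconsistent (one 1,915-image pool is printed as train 1723 although
  0.9 · 1915 = 1723.5, while 0.9 · 1665 = 1498.5 is printed as 1499).
  Round-half-up reproduces 20 of the 21 published rows; the one
  conflicting row is excluded from the acceptance checks and the
  rounding rule is exposed for callers who need the other convention.
* On degenerate pools the rounded train count is clamped into
  [1, N−1] so both sets are non-empty (e.g. N = 2 at 0.9 would round to
  2/0). No published row is affected.

Every split is a pure function of (sorted id pool, fraction, seed):
fixed seeds give byte-identical split files across runs and platforms.

## Evaluation

Boxes use a 0-based half-open convention internally; VOC XML files are
1-based inclusive and converted only at the I/O boundary, making IoU
arithmetic offset-free. Per class, detections are ranked by descending
score — ties broken by image id then box coordinates, a total order, so
evaluation is invariant to detection file row order — and greedily
matched to the unmatched same-image ground-truth box of highest IoU.
TP iff IoU ≥ 0.5 (the VOC default; configurable). Detections on negative
images are false positives by construction, which is the point of
supplementing evaluation sets with explicit negatives.

AP is the area under the monotone precision envelope. The default
`all_points` mode integrates the envelope over every recall change
point (the convention of the reference evaluator shipped with the
detector family the workflow targets); `eleven_point` averages the
envelope at recalls 0.0, 0.1, …, 1.0 for strict VOC2007 comparability.
With no ground truth and no detections AP is defined as 0 with a
warning. mAP is the unweighted class mean. Confidence-threshold sweeps
re-match after discarding detections below each threshold; truncating a
ranked list cannot raise the envelope integral, so mAP is non-increasing
in the threshold — the property the sweep is meant to expose.

VOC `difficult`/`truncated` flags are read and preserved on round-trip
but ignored by evaluation.

## Synthetic data

The fixture generator states a small world with known truth:

* **Scenes**: 256×256 8-bit grayscale; background = Gaussian-smoothed
  white noise (σ = 4 px) scaled to [40, 200] plus a random linear
  illumination gradient (±40); 0–3 "animals" as filled ellipses
  (axes 10–35 px) at near-black (15) or near-white (235), with tight
  bounding boxes. Negatives are blob-free scenes.
* **Bursts**: n = 4 frames; integer jitter ≤ 2 px, sensor noise
  σ = 2, global exposure shift uniform in ±10.
* **Simulated detections**: planted TP count = round(recall · n_gt)
  with recall 0.8, box jitter σ = 1 px, TP scores uniform in
  [0.5, 1.0], 10 false positives with scores in [0.05, 0.29] — so a
  0.30 threshold removes every FP by construction.

The background texture scale matters: at very smooth settings two
*independent* scenes score SSIM ≈ 0.6 because low local variance lets
the luminance term dominate. σ = 4 px keeps ample structure inside the
7×7 window; on the frozen defaults intra-burst SSIM measures 0.54–0.92
(≥ 0.4) and cross-scene/cross-burst 0.24–0.36 (< 0.4), which the tests
assert with the similarity module itself. These margins were fixed
before any expected values were frozen.

What a green fixture-based test does **not** establish: real camera-trap
imagery has infrared frames, motion blur, occlusion, and animals whose
appearance varies continuously — the 0.4/0.8 thresholds are inherited
operating points, not values validated on synthetic blobs. The fixtures
validate the *machinery* (graph clustering, split arithmetic, AP
computation), not the thresholds' ecological calibration.

## Pipeline

`run_pipeline` executes dedup (web/base-source positives) → capture-event
clustering (camera-trap/infusion-source positives) → representative
selection → one infusion plan per requested percentage → negative
supplementation → optional evaluation of a supplied detections CSV. One
global seed hashes (SHA-256) into per-stage seeds, so stages rerun
standalone reproduce the pipeline's outputs, and a rerun with identical
config and inputs is byte-identical (the resolved config written next to
the outputs embeds the output path and is the one file excluded from
byte comparison in the tests).

## Known limitations

* SSIM is O(n²) in pool size with full matrices held dense; pools beyond
  a few thousand images need blocking or a candidate pre-filter, which
  is out of scope.
* Single-linkage clustering chains: one intermediate frame can merge two
  visually distinct events.
* The splitter does no stratification by site, time, or class — the
  protocol it reproduces specifies a plain random shuffle.
* COCO-style mAP@[.5:.95], segmentation, and abundance estimation are
  non-goals.
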