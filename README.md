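# trapcurate

Dataset curation and evaluation tooling for camera-trap object detection.

Ecologists increasingly train deep-learning detectors to find animals in
motion-triggered camera-trap images, but such models generalize poorly to
camera sites unseen during training, and camera-trap archives are choked
with near-duplicate frames from each capture event. A practical recipe is
to train on highly varied public web imagery and then *infuse* the
training pool with a small percentage of camera-trap frames chosen for
maximum variability. `trapcurate` implements every dataset-side step of
that recipe — the detector itself is a pluggable external stage; this
package prepares its training/validation/test sets and scores its output.

## What it does

* **SSIM scoring** — windowed structural similarity between grayscale,
  size-normalized images:
  `SSIM = mean over windows of (2 μₐ μᵦ + C₁)(2 σₐᵦ + C₂) / ((μₐ² + μᵦ² + C₁)(σₐ² + σᵦ² + C₂))`
  with C₁ = (k₁ L)², C₂ = (k₂ L)², defaults k₁ = 0.01, k₂ = 0.03, L = 255,
  7×7 uniform window, 256×256 comparison size.
* **Near-duplicate removal** — pairs scoring strictly above 0.8 are
  duplicates; one seeded-random representative per connected duplicate
  group is kept.
* **Capture-event clustering** — pairs scoring at/above 0.4 are linked;
  connected components are the clusters, and one random frame per cluster
  gives a maximally varied subset.
* **Split planning** — seeded 90/10 train/validation splits with exact
  round-half-up arithmetic; infusion plans that add
  k = round-half-up(p · N) camera-trap images (p = 5–20 %) to a base pool
  of N web images *before* splitting; explicit negative samples (800
  train / 200 test by default) appended after the split arithmetic.
* **Evaluation** — PASCAL-VOC detection scoring: IoU, greedy
  highest-IoU matching at IoU ≥ 0.5, all-points (or 11-point) average
  precision, mAP, and sweeps over confidence thresholds
  (0.05 / 0.30 / 0.50 by default).
* **Synthetic fixtures** — seeded scene/burst/detection generators with
  recorded ground truth, so the whole pipeline is testable offline.

## Worked example

Plan a 5 % infusion of a 333-image camera-trap pool into a 1,665-image
web pool:

```python
from trapcurate import (InfusionSpec, SplitSpec, build_infusion_split,
                        infusion_count)

base = [f"fin_rhino_{k:04d}" for k in range(1665)]   # web-image pool
trap = [f"wcs_rhino_{k:04d}" for k in range(333)]    # camera-trap pool

k = infusion_count(len(base), 0.05)
split = build_infusion_split(base, trap,
                             InfusionSpec(percent=0.05, source_tag="wcs", seed=1),
                             SplitSpec(train_fraction=0.9, seed=1),
                             base_source_tag="fin")
print(f"infusion images: {k}")
print(f"combined pool:   {len(split.train_ids | split.val_ids)}")
print(f"train/val:       {len(split.train_ids)}/{len(split.val_ids)}")
print(f"infused in val:  {len(split.infused_ids & split.val_ids)}")
```

prints

```
infusion images: 83
combined pool:   1748
train/val:       1573/175
infused in val:  10
```

83 = round-half-up(0.05 · 1665) camera-trap images join the pool; the
combined 1,748 images split into 1,573 training and 175 validation
(round-half-up(0.9 · 1748) = 1573), and because infusion happens before
splitting, 10 of the 83 infused frames land in validation.

The same workflow runs end to end from the shell:

```sh
trapcurate simulate --out demo/data --seed 7          # synthetic dataset
trapcurate run --config demo/config.yaml              # dedup→cluster→split→evaluate
```

which reports, for the default 37-image synthetic dataset, 3 recovered
capture-event clusters, 0 duplicates among the 5 distinct web scenes, one
split per infusion level, and a detector evaluation such as
`mAP 0.794, TP 27 / FP 10 / FN 7` at threshold 0.05 rising to
`FP 0` at 0.30 (the simulated detector's false positives all score low).
Subcommands `dedup`, `cluster`, `split`, `infuse`, and `evaluate` expose
each stage individually.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the published single-class experiment pools at their recorded
sizes, runs the infusion planner and 90/10 splitter on them, and writes
the measured infusion counts and train/validation sizes as JSON.

## Layout

| module | contents |
| --- | --- |
| `trapcurate.annotations` | PASCAL-VOC XML read/write, manifest CSV, box types |
| `trapcurate.similarity` | SSIM, pairwise matrices, dedup, clustering |
| `trapcurate.splits` | 90/10 splits, infusion planning, negatives |
| `trapcurate.evaluation` | IoU, matching, AP/mAP, threshold sweeps |
| `trapcurate.fixtures` | synthetic scenes, bursts, simulated detections |
| `trapcurate.pipeline` / `trapcurate.cli` | orchestration and the `trapcurate` command |

See `docs/methods.md` for the modelling choices, parameter defaults, and
known limitations.
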