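"""Synthetic camera-trap data with known ground truth.

Every other module is exercised against data produced here, so no image
downloads are needed: scenes are seeded textured backgrounds (smoothed
noise plus an illumination gradient) carrying 0-3 high-contrast elliptical
"animal" blobs with tight bounding boxes; *bursts* emulate a capture
event by perturbing one scene with small translations, sensor noise, and
a global exposure shift; and :func:`simulate_detections` plants detector
output with controllable recall, localization error, false-positive count
and score distributions, recording the planted truth for oracle checks.

The blobs are geometric, not rendered wildlife — similarity scoring,
clustering, split planning and mAP arithmetic are agnostic to semantic
content, so realism buys nothing for correctness.  Images are 256x256
8-bit grayscale PNGs, matching the similarity module's default comparison
size, and everything is reproducible bit for bit from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .annotations import (AnnotationSet, BoundingBox, DatasetManifest,
                          ImageRecord, VocObject, save_manifest,
                          write_voc_xml)
from .evaluation import Detection

IMAGE_SIZE = 256
CLASS_LABEL = "animal"


@dataclass(frozen=True)
class BurstSpec:
    """Perturbations applied to one scene to emulate a capture event.

    Defaults (2 px jitter, sigma-2 sensor noise, up to ±10 intensity
    exposure shift) keep intra-burst SSIM well above the 0.4 clustering
    cutoff while independently seeded scenes stay well below it.
    """

    n_frames: int = 4
    jitter: int = 2
    noise_sigma: float = 2.0
    brightness_delta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("a burst needs at least one frame")
        if self.jitter < 0 or self.noise_sigma < 0 or self.brightness_delta < 0:
            raise ValueError("burst perturbation magnitudes must be >= 0")


@dataclass(frozen=True)
class DetectionSimSpec:
    """Knobs for the simulated detector output.

    The planted true-positive count is round(recall * n_gt) and is
    recorded in the returned metadata so tests can compare measured
    against planted quantities exactly.  Scores are drawn uniformly from
    the given (low, high) ranges; the defaults separate TP and FP scores
    so a 0.30 confidence threshold removes every false positive.
    """

    recall: float = 0.8
    n_false_positives: int = 10
    loc_noise: float = 1.0
    tp_score_range: tuple[float, float] = (0.5, 1.0)
    fp_score_range: tuple[float, float] = (0.05, 0.29)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.recall <= 1.0:
            raise ValueError("recall must lie in [0, 1]")
        if self.n_false_positives < 0:
            raise ValueError("n_false_positives must be >= 0")


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Textured background: band-passed noise over a soft gradient.

    The smoothing scale (sigma 4 px) keeps plenty of structure inside a
    7x7 SSIM window: independently seeded backgrounds then decorrelate to
    scores near 0, while a 2 px shifted copy stays highly similar.
    """
    noise = gaussian_filter(rng.normal(size=(size, size)), sigma=4.0)
    noise = (noise - noise.min()) / (noise.max() - noise.min() + 1e-12)
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    a, b = rng.uniform(-1, 1, 2)
    gradient = (a * xx + b * yy - min(a + b, 0)) / (abs(a) + abs(b) + 1e-12)
    return 40.0 + 160.0 * noise + 40.0 * gradient


def _add_blob(img: np.ndarray, rng: np.random.Generator) -> BoundingBox:
    """Draw one filled ellipse of contrasting intensity; return its box."""
    size = img.shape[0]
    ax = int(rng.integers(10, 36))
    ay = int(rng.integers(10, 36))
    margin = 5
    cx = int(rng.integers(ax + margin, size - ax - margin))
    cy = int(rng.integers(ay + margin, size - ay - margin))
    yy, xx = np.mgrid[0:size, 0:size]
    mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    intensity = float(rng.choice([15.0, 235.0]))  # dark or bright animal
    img[mask] = intensity
    ys, xs = np.nonzero(mask)
    return BoundingBox(int(xs.min()), int(ys.min()),
                       int(xs.max()) + 1, int(ys.max()) + 1)


def _save(img: np.ndarray, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.clip(img, 0, 255).astype(np.uint8), mode="L").save(path)


def generate_scene(seed: int, out_dir: str | Path,
                   image_id: str | None = None,
                   n_blobs: int | None = None,
                   source_tag: str = "synthetic",
                   size: int = IMAGE_SIZE,
                   ) -> tuple[ImageRecord, AnnotationSet]:
    """Generate one scene image plus its ground-truth annotation.

    ``n_blobs`` forces the object count (0 makes an explicit negative);
    by default 1-3 blobs are drawn.  Output is a PNG under ``out_dir``
    and is byte-identical across runs for a fixed (seed, size).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    image_id = image_id or f"scene_{seed:08d}"

    img = _background(rng, size)
    count = int(rng.integers(1, 4)) if n_blobs is None else n_blobs
    objects = tuple(VocObject(CLASS_LABEL, _add_blob(img, rng))
                    for _ in range(count))

    path = out_dir / f"{image_id}.png"
    _save(img, path)
    record = ImageRecord(image_id=image_id, path=path, source_tag=source_tag,
                         is_negative=(count == 0))
    ann = AnnotationSet(image_id=image_id, width=size, height=size,
                        objects=objects)
    return record, ann


def generate_burst(base: ImageRecord, base_ann: AnnotationSet,
                   spec: BurstSpec, out_dir: str | Path,
                   ) -> list[tuple[ImageRecord, AnnotationSet]]:
    """Perturbed copies of one scene, annotations translated to match.

    Each frame gets an integer translation of at most ``jitter`` pixels,
    Gaussian sensor noise, and a global brightness shift.  Should the
    jitter push a box entirely out of frame (possible only with extreme
    jitter), the frame is regenerated with the jitter halved.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    with Image.open(base.path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64)
    h, w = arr.shape

    frames: list[tuple[ImageRecord, AnnotationSet]] = []
    for k in range(spec.n_frames):
        jitter = spec.jitter
        while True:
            dx = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            dy = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            try:
                boxes = tuple(
                    replace(o, box=o.box.shifted(dx, dy).clipped(w, h))
                    for o in base_ann.objects)
            except ValueError:
                jitter //= 2  # box left the frame: retry gentler
                continue
            break
        frame = nd_shift(arr, (dy, dx), order=1, mode="nearest")
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        if spec.brightness_delta > 0:
            frame = frame + rng.uniform(-spec.brightness_delta,
                                        spec.brightness_delta)
        image_id = f"{base.image_id}_f{k}"
        path = out_dir / f"{image_id}.png"
        _save(frame, path)
        rec = ImageRecord(image_id=image_id, path=path,
                          source_tag=base.source_tag,
                          is_negative=base.is_negative)
        frames.append((rec, AnnotationSet(image_id, w, h, boxes)))
    return frames


def simulate_detections(gts: Mapping[str, AnnotationSet],
                        spec: DetectionSimSpec,
                        ) -> tuple[list[Detection], dict]:
    """Plant a detector output with known recall and false-positive load.

    Returns the detections plus a metadata dict holding the planted TP
    count and the (image_id, object index) pairs detected — the oracle
    against which measured evaluation results are compared.
    """
    rng = np.random.default_rng(spec.seed)
    all_gt = [(img, j, ann.objects[j].box, ann.objects[j].class_label,
               ann.width, ann.height)
              for img, ann in sorted(gts.items())
              for j in range(len(ann.objects))]
    n_gt = len(all_gt)
    n_tp = int(round(spec.recall * n_gt))
    chosen = sorted(rng.choice(n_gt, size=n_tp, replace=False).tolist()) \
        if n_tp else []

    dets: list[Detection] = []
    planted: list[tuple[str, int]] = []
    for idx in chosen:
        img, j, box, cls, w, h = all_gt[idx]
        if spec.loc_noise > 0:
            d = rng.normal(0.0, spec.loc_noise, 4).round().astype(int)
            jittered = BoundingBox(box.xmin + d[0], box.ymin + d[1],
                                   max(box.xmax + d[2], box.xmin + d[0] + 1),
                                   max(box.ymax + d[3], box.ymin + d[1] + 1))
            box = jittered.clipped(w, h)
        score = float(rng.uniform(*spec.tp_score_range))
        dets.append(Detection(img, cls, box, score))
        planted.append((img, j))

    images = sorted(gts)
    classes = sorted({o.class_label for a in gts.values()
                      for o in a.objects}) or [CLASS_LABEL]
    for _ in range(spec.n_false_positives):
        img = images[int(rng.integers(len(images)))]
        ann = gts[img]
        w, h = max(ann.width, 16), max(ann.height, 16)
        bw = int(rng.integers(8, max(w // 2, 9)))
        bh = int(rng.integers(8, max(h // 2, 9)))
        x0 = int(rng.integers(0, w - bw))
        y0 = int(rng.integers(0, h - bh))
        cls = classes[int(rng.integers(len(classes)))]
        score = float(rng.uniform(*spec.fp_score_range))
        dets.append(Detection(img, cls, BoundingBox(x0, y0, x0 + bw, y0 + bh),
                              score))

    meta = {
        "n_gt": n_gt,
        "n_planted_tp": n_tp,
        "planted_tp": planted,
        "n_false_positives": spec.n_false_positives,
        "recall": spec.recall,
    }
    return dets, meta


def generate_dataset(out_dir: str | Path, seed: int = 0,
                     n_bursts: int = 3, frames_per_burst: int = 4,
                     n_scenes: int = 5, n_negatives: int = 20,
                     burst_source: str = "trap", scene_source: str = "web",
                     negative_source: str = "neg",
                     ) -> tuple[DatasetManifest, dict[str, AnnotationSet], dict]:
    """Assemble a full synthetic dataset on disk.

    Layout under ``out_dir``: ``images/`` (PNGs), ``annotations/`` (VOC
    XML for every positive), ``manifest.csv``.  Bursts carry the
    camera-trap source tag (the infusion pool), distinct scenes the web
    source tag (the base pool), and blob-free scenes the negative tag.
    Returns the manifest, all annotations, and truth metadata naming each
    burst's frame ids (the planted capture-event clusters).
    """
    out_dir = Path(out_dir)
    images = out_dir / "images"
    xml_dir = out_dir / "annotations"
    rng = np.random.default_rng(seed)
    # independent sub-seeds kept below 2**31 for portability
    sub = lambda: int(rng.integers(1, 2**31 - 1))  # noqa: E731

    records: list[ImageRecord] = []
    anns: dict[str, AnnotationSet] = {}
    burst_truth: dict[str, list[str]] = {}

    for b in range(n_bursts):
        base_rec, base_ann = generate_scene(
            sub(), images, image_id=f"burst{b:02d}", source_tag=burst_source)
        spec = BurstSpec(n_frames=frames_per_burst, seed=sub())
        frames = generate_burst(base_rec, base_ann, spec, images)
        base_rec.path.unlink()  # only the perturbed frames enter the dataset
        burst_truth[f"burst{b:02d}"] = [r.image_id for r, _ in frames]
        for rec, ann in frames:
            records.append(rec)
            anns[rec.image_id] = ann

    for s in range(n_scenes):
        rec, ann = generate_scene(sub(), images, image_id=f"scene{s:02d}",
                                  source_tag=scene_source)
        records.append(rec)
        anns[rec.image_id] = ann

    for s in range(n_negatives):
        rec, ann = generate_scene(sub(), images, image_id=f"neg{s:03d}",
                                  n_blobs=0, source_tag=negative_source)
        records.append(rec)
        anns[rec.image_id] = ann

    for ann in anns.values():
        write_voc_xml(ann, xml_dir / f"{ann.image_id}.xml")

    manifest = DatasetManifest(records=records, class_names=[CLASS_LABEL])
    save_manifest(manifest, out_dir / "manifest.csv")
    truth = {"bursts": burst_truth,
             "scene_ids": [f"scene{s:02d}" for s in range(n_scenes)],
             "negative_ids": [f"neg{s:03d}" for s in range(n_negatives)]}
    return manifest, anns, truth
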