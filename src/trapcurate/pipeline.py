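"""End-to-end curation pipeline: dedup -> cluster -> select -> split/infuse
-> (optional) evaluate.

The pipeline mirrors the experimental workflow around a pluggable
detector: web-sourced positives are deduplicated (SSIM > 0.8), the
camera-trap positives are clustered into capture events (SSIM >= 0.4),
infusion plans are built for each requested percentage using
one-frame-per-cluster selection, training/test sets are supplemented
with explicit negatives, and, if a detections file is supplied, the
detector's output is scored at the configured confidence thresholds.

Determinism: one global seed deterministically derives a per-stage seed
by hashing the stage name, so a stage run standalone with its derived
seed reproduces exactly what the pipeline produced, and two runs with
identical config and inputs write byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import evaluation, similarity, splits
from .annotations import DatasetManifest, load_annotations, load_manifest
from .evaluation import read_detections_csv
from .similarity import SsimParams

log = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending item."""


@dataclass
class PipelineConfig:
    """Everything a run needs, serializable to/from YAML."""

    manifest: str
    annotations_dir: str
    output_dir: str
    base_source: str = "web"
    infusion_source: str = "trap"
    negative_source: str = "neg"
    ssim: SsimParams = field(default_factory=SsimParams)
    dedup_threshold: float = similarity.DEDUP_THRESHOLD
    cluster_threshold: float = similarity.CLUSTER_THRESHOLD
    train_fraction: float = 0.9
    infusion_percents: tuple[float, ...] = splits.DEFAULT_INFUSION_PERCENTS
    negatives_train: int = 800
    negatives_test: int = 200
    detections: str | None = None
    confidence_thresholds: tuple[float, ...] = \
        evaluation.DEFAULT_CONFIDENCE_THRESHOLDS
    iou_threshold: float = evaluation.DEFAULT_IOU_THRESHOLD
    ap_mode: str = "all_points"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ssim"]["comparison_size"] = list(self.ssim.comparison_size)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ssim_raw = raw.pop("ssim", {})
        if "comparison_size" in ssim_raw:
            ssim_raw["comparison_size"] = tuple(ssim_raw["comparison_size"])
        raw.pop("keywords", None)  # illustrative download metadata only
        cfg = cls(ssim=SsimParams(**ssim_raw), **raw)
        cfg.infusion_percents = tuple(cfg.infusion_percents)
        cfg.confidence_thresholds = tuple(cfg.confidence_thresholds)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


@dataclass
class RunSummary:
    """Per-stage counts sufficient to audit the split arithmetic."""

    n_images: int = 0
    n_base: int = 0
    n_infusion: int = 0
    n_negatives: int = 0
    duplicates_removed: int = 0
    n_clusters: int = 0
    splits: dict = field(default_factory=dict)   # name -> count summary
    evaluation: dict = field(default_factory=dict)  # name -> list of reports
    seeds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True)
                        + "\n")
        return path


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the full curation workflow; returns the audit summary.

    All intermediate artifacts (similarity matrices, removal lists,
    cluster tables, split CSVs, evaluation JSON) are written under
    ``config.output_dir`` together with the resolved config, and a rerun
    with the same config and inputs reproduces them byte for byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    summary = RunSummary()
    seeds = {s: derive_seed(config.seed, s)
             for s in ("dedup", "cluster", "split", "infusion", "negatives")}
    summary.seeds = dict(seeds)

    manifest = _stage("load")(load_manifest)(
        config.manifest, annotations_dir=config.annotations_dir)
    base = [r for r in manifest.positives()
            if r.source_tag == config.base_source]
    infusion = [r for r in manifest.positives()
                if r.source_tag == config.infusion_source]
    negatives = [r for r in manifest.negatives()]
    summary.n_images = len(manifest)
    summary.n_base = len(base)
    summary.n_infusion = len(infusion)
    summary.n_negatives = len(negatives)
    log.info("loaded %d images: %d base, %d infusion, %d negative",
             len(manifest), len(base), len(infusion), len(negatives))

    # --- dedup the web-sourced base pool -------------------------------
    if base:
        base_matrix = _stage("dedup")(similarity.pairwise_matrix)(
            base, config.ssim)
        base_matrix.to_csv(out / "similarity_base.csv")
        kept, removed = similarity.dedup(base_matrix, config.dedup_threshold,
                                         seed=seeds["dedup"])
        (out / "dedup_removed.csv").write_text(
            "image_id\n" + "".join(f"{i}\n" for i in sorted(removed)))
        base_ids = sorted(kept)
    else:
        base_ids, removed = [], frozenset()
    summary.duplicates_removed = len(removed)
    log.info("dedup: kept %d, removed %d (threshold %.2f)",
             len(base_ids), len(removed), config.dedup_threshold)

    # --- cluster the camera-trap infusion pool -------------------------
    clusters = None
    if infusion:
        inf_matrix = _stage("cluster")(similarity.pairwise_matrix)(
            infusion, config.ssim)
        inf_matrix.to_csv(out / "similarity_infusion.csv")
        clusters = similarity.cluster(inf_matrix, config.cluster_threshold)
        clusters.to_csv(out / "clusters.csv")
        reps = similarity.select_representatives(clusters,
                                                 seed=seeds["cluster"])
        (out / "representatives.csv").write_text(
            "image_id\n" + "".join(f"{i}\n" for i in sorted(reps)))
        summary.n_clusters = clusters.n_clusters
        log.info("clustering: %d capture-event clusters from %d images "
                 "(threshold %.2f)", clusters.n_clusters, len(infusion),
                 config.cluster_threshold)

    # --- base split and infusion plans ---------------------------------
    neg_ids = [r.image_id for r in negatives]
    nspec = splits.NegativeSampleSpec(n_train=config.negatives_train,
                                     n_test=config.negatives_test)

    def finish(split: splits.DatasetSplit, name: str) -> None:
        if neg_ids and (nspec.n_train or nspec.n_test):
            split = splits.supplement_negatives(
                split, neg_ids, nspec, seed=seeds["negatives"],
                source_tag=config.negative_source)
        split.to_csv(out / f"split_{name}.csv")
        summary.splits[name] = split.summary()
        log.info("split %s: %s", name, summary.splits[name])

    sspec = splits.SplitSpec(train_fraction=config.train_fraction,
                             seed=seeds["split"])
    if len(base_ids) >= 2:
        finish(_stage("split")(splits.base_split)(
            base_ids, sspec, source_tag=config.base_source), "base")
        for p in config.infusion_percents:
            ispec = splits.InfusionSpec(percent=p,
                                        source_tag=config.infusion_source,
                                        seed=seeds["infusion"])
            split = _stage("infuse")(splits.build_infusion_split)(
                base_ids, [r.image_id for r in infusion], ispec, sspec,
                cluster_ranking=clusters,
                base_source_tag=config.base_source)
            finish(split, f"inf_{int(round(p * 100)):02d}")

    # --- optional evaluation of provided detector output ----------------
    if config.detections:
        dets = _stage("evaluate")(read_detections_csv)(config.detections)
        anns = load_annotations(manifest, config.annotations_dir)
        reports = _stage("evaluate")(evaluation.evaluate_at_thresholds)(
            dets, anns, thresholds=config.confidence_thresholds,
            iou_threshold=config.iou_threshold, mode=config.ap_mode)
        summary.evaluation = {"all": [r.to_dict() for r in reports]}
        (out / "evaluation.json").write_text(
            json.dumps(summary.evaluation, indent=2, sort_keys=True) + "\n")
        for r in reports:
            evaluation.write_pr_curves(r, out / "pr_curves")
        for r in reports:
            log.info("threshold %.2f: mAP %.4f", r.confidence_threshold, r.map)

    summary.write(out / "summary.json")
    return summary
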