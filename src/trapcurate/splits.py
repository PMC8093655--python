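"""Deterministic train/validation/test planning with infusion.

The curation protocol implemented here:

* a positive image pool is split 90/10 into training and validation by a
  seeded shuffle, with the training share rounded half-up;
* *infusion* adds a small percentage p of camera-trap images (counted
  against the size of the base web-image pool, k = round-half-up(p * N))
  to the pool *before* splitting, so both training and validation receive
  infusion images — e.g. a base pool of 1,665 at p = 0.05 adds 83 images,
  and the combined 1,748 split 90/10 gives 1,573 train / 175 validation;
* infusion images are preferentially drawn one-per-cluster from an SSIM
  capture-event clustering (small clusters first) to maximize variability;
* explicit negative samples (default 800 train / 200 test) are appended
  *after* the split arithmetic and are never counted in the pool size N.

All rounding is exact decimal round-half-up, not float banker's rounding,
so printed split tables can be reproduced digit for digit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import ClusterSet

DEFAULT_INFUSION_PERCENTS = (0.05, 0.10, 0.15, 0.20)


class SplitError(ValueError):
    """Raised for infeasible or inconsistent split requests."""


def round_half_up(x: float | Decimal) -> int:
    """Round to the nearest integer, halves away from zero (upward)."""
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _decimal_product(p: float, n: int) -> Decimal:
    # str() keeps 0.9 * 1665 == 1498.5 exact instead of 1498.499999...
    return Decimal(str(p)) * Decimal(n)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation proportions and the shuffle seed."""

    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise SplitError("train_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class InfusionSpec:
    """Infusion percentage (of the *base* pool size) and its source."""

    percent: float
    source_tag: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.percent <= 1.0:
            raise SplitError("infusion percent must lie in (0, 1]")


@dataclass(frozen=True)
class NegativeSampleSpec:
    """How many explicit negatives supplement training and test sets."""

    n_train: int = 800
    n_test: int = 200

    def __post_init__(self) -> None:
        if self.n_train < 0 or self.n_test < 0:
            raise SplitError("negative sample counts must be non-negative")


@dataclass(frozen=True)
class Provenance:
    source_tag: str = ""
    infused: bool = False
    negative: bool = False


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test id sets with per-id provenance."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str] = frozenset()
    provenance: Mapping[str, Provenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_ids & self.val_ids:
            raise SplitError("train and validation sets overlap")
        if self.test_ids & (self.train_ids | self.val_ids):
            raise SplitError("test ids appear in train or validation")

    def _positives(self, ids: frozenset[str]) -> frozenset[str]:
        return frozenset(i for i in ids
                         if not self.provenance.get(i, Provenance()).negative)

    @property
    def n_train_positives(self) -> int:
        return len(self._positives(self.train_ids))

    @property
    def n_val_positives(self) -> int:
        return len(self._positives(self.val_ids))

    @property
    def infused_ids(self) -> frozenset[str]:
        return frozenset(i for i, p in self.provenance.items() if p.infused)

    def with_test(self, test_ids: Iterable[str],
                  source_tag: str = "") -> "DatasetSplit":
        """Attach an out-of-sample test set; refuses any overlap."""
        test = frozenset(test_ids)
        prov = dict(self.provenance)
        for i in test:
            prov.setdefault(i, Provenance(source_tag=source_tag))
        return DatasetSplit(self.train_ids, self.val_ids,
                            self.test_ids | test, prov)

    def summary(self) -> dict:
        return {
            "train": len(self.train_ids),
            "val": len(self.val_ids),
            "test": len(self.test_ids),
            "train_positives": self.n_train_positives,
            "val_positives": self.n_val_positives,
            "infused": len(self.infused_ids),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, ids in (("train", self.train_ids), ("val", self.val_ids),
                            ("test", self.test_ids)):
            for i in sorted(ids):
                p = self.provenance.get(i, Provenance())
                rows.append((i, subset, p.source_tag, p.infused))
        return pd.DataFrame(rows, columns=["image_id", "subset",
                                           "source_tag", "infused"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetSplit":
        df = pd.read_csv(path, dtype={"image_id": str, "subset": str,
                                      "source_tag": str},
                         keep_default_na=False)
        sets = {"train": set(), "val": set(), "test": set()}
        prov = {}
        for row in df.itertuples(index=False):
            sets[row.subset].add(row.image_id)
            infused = str(row.infused).strip().lower() in ("1", "true")
            prov[row.image_id] = Provenance(row.source_tag, infused)
        return cls(frozenset(sets["train"]), frozenset(sets["val"]),
                   frozenset(sets["test"]), prov)


def infusion_count(n_base: int, p: float) -> int:
    """Number of infusion images for a base pool of ``n_base`` at level ``p``.

    Round-half-up of p * n_base: 5% of 1,665 -> 83; 20% of 472 -> 94.
    """
    if n_base < 1:
        raise SplitError("base pool must hold at least one image")
    if not 0.0 < p <= 1.0:
        raise SplitError("infusion percent must lie in (0, 1]")
    return round_half_up(_decimal_product(p, n_base))


def _shuffled(ids: Iterable[str], seed: int) -> list[str]:
    ordered = sorted(ids)
    rng = np.random.default_rng(seed)
    return [ordered[i] for i in rng.permutation(len(ordered))]


def base_split(pool: Iterable[str], spec: SplitSpec,
               source_tag: str = "",
               provenance: Mapping[str, Provenance] | None = None,
               ) -> DatasetSplit:
    """Randomly split a positive pool into train and validation sets.

    Train size is round-half-up(train_fraction * |pool|); membership comes
    from a seeded shuffle of the sorted id list, so a fixed seed gives a
    byte-identical split everywhere.
    """
    ids = sorted(set(pool))
    if len(ids) < 2:
        raise SplitError("pool must hold at least 2 images to form both sets")
    n_train = round_half_up(_decimal_product(spec.train_fraction, len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both sets non-empty
    order = _shuffled(ids, spec.seed)
    train = frozenset(order[:n_train])
    val = frozenset(order[n_train:])
    prov = dict(provenance) if provenance else {}
    for i in ids:
        prov.setdefault(i, Provenance(source_tag=source_tag))
    return DatasetSplit(train_ids=train, val_ids=val, provenance=prov)


def select_infusion_images(infusion_pool: Iterable[str], k: int, seed: int,
                           cluster_ranking: ClusterSet | None = None,
                           ) -> list[str]:
    """Pick ``k`` infusion images from a camera-trap pool.

    With a capture-event clustering, one seeded-random frame is drawn per
    cluster, visiting clusters in ascending size order (ties by smallest
    id); if k exceeds the number of clusters the sweep repeats over the
    remaining frames.  Small-cluster-first maximizes the variability of
    the selected subset.  Without a clustering the choice is a plain
    seeded-random sample.
    """
    pool = sorted(set(infusion_pool))
    if k > len(pool):
        raise SplitError(
            f"infusion pool holds {len(pool)} images but {k} are required")
    rng = np.random.default_rng(seed)
    if k == 0:
        return []
    if cluster_ranking is None:
        order = _shuffled(pool, seed)
        return sorted(order[:k])

    if cluster_ranking.all_ids() != frozenset(pool):
        raise SplitError("cluster_ranking must partition the infusion pool")
    remaining = [sorted(c) for c in
                 sorted(cluster_ranking.clusters, key=lambda c: (len(c), min(c)))]
    chosen: list[str] = []
    while len(chosen) < k:
        progressed = False
        for members in remaining:
            if not members or len(chosen) >= k:
                continue
            pick = members.pop(int(rng.integers(len(members))))
            chosen.append(pick)
            progressed = True
        if not progressed:  # pragma: no cover - guarded by k <= |pool|
            raise SplitError("infusion pool exhausted")
    return sorted(chosen)


def build_infusion_split(base_pool: Iterable[str],
                         infusion_pool: Iterable[str],
                         ispec: InfusionSpec,
                         sspec: SplitSpec,
                         cluster_ranking: ClusterSet | None = None,
                         base_source_tag: str = "",
                         ) -> DatasetSplit:
    """Build a train/validation split of a base pool plus infusion images.

    k = infusion_count(|base|, p) camera-trap images are selected (one
    per capture-event cluster when a clustering is supplied), merged into
    the base pool, and the *combined* pool is split train/validation —
    so validation also contains its share of infusion images, matching
    the published split arithmetic.
    """
    base = sorted(set(base_pool))
    infusion = sorted(set(infusion_pool))
    if set(base) & set(infusion):
        raise SplitError("base and infusion pools overlap")
    k = infusion_count(len(base), ispec.percent)
    selected = select_infusion_images(infusion, k, ispec.seed, cluster_ranking)
    prov: dict[str, Provenance] = {
        i: Provenance(source_tag=base_source_tag) for i in base}
    prov.update({i: Provenance(source_tag=ispec.source_tag, infused=True)
                 for i in selected})
    return base_split(base + selected, sspec, provenance=prov)


def supplement_negatives(split: DatasetSplit, negatives: Iterable[str],
                         spec: NegativeSampleSpec, seed: int = 0,
                         source_tag: str = "") -> DatasetSplit:
    """Append explicit negative samples to the train and test sets.

    Negatives improve discrimination during training and give the test
    set false-positive opportunities; they are never counted in the
    positive split arithmetic.  ``n_train`` negatives go to train and
    ``n_test`` to test, disjointly, by seeded shuffle.
    """
    negs = sorted(set(negatives))
    used = split.train_ids | split.val_ids | split.test_ids
    clash = used & set(negs)
    if clash:
        raise SplitError(f"negatives overlap split ids: {sorted(clash)[:5]}")
    need = spec.n_train + spec.n_test
    if len(negs) < need:
        raise SplitError(
            f"need {need} negatives ({spec.n_train} train + {spec.n_test} "
            f"test) but only {len(negs)} available")
    order = _shuffled(negs, seed)
    to_train = frozenset(order[:spec.n_train])
    to_test = frozenset(order[spec.n_train:need])
    prov = dict(split.provenance)
    for i in to_train | to_test:
        prov[i] = Provenance(source_tag=source_tag, negative=True)
    return DatasetSplit(split.train_ids | to_train, split.val_ids,
                        split.test_ids | to_test, prov)


def write_summary(split: DatasetSplit, path: str | Path) -> Path:
    """JSON audit record of the split counts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(split.summary(), indent=2, sort_keys=True)
                    + "\n")
    return path
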