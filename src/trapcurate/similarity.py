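"""Structural-similarity scoring, near-duplicate removal, and capture-event
clustering.

Camera traps fire in bursts, so a single animal visit ("capture event")
yields many frames that differ only by a small shift, sensor noise, or an
exposure change.  Web-scraped datasets likewise contain exact and near
duplicates.  Both inflate apparent dataset size without adding variability,
which hurts detector generalization.

The workflow implemented here:

1. score every image pair with SSIM (Wang et al.'s windowed
   luminance/contrast/structure index, in [-1, 1], 1 = identical);
2. *dedup*: treat pairs scoring strictly above 0.8 as duplicates, and keep
   exactly one seeded-random representative per duplicate group;
3. *cluster*: treat pairs scoring at or above 0.4 as the same capture
   event and partition the pool into connected components;
4. *select_representatives*: draw one random frame per cluster, which is
   how low-redundancy "infusion" subsets are assembled.

Grouping is single linkage (connected components of the thresholded
similarity graph): a star of pairwise comparisons against a test frame
generalizes transitively, so two frames chained through intermediates are
one event even if their direct score dips below the cutoff.  Note that
complete linkage would split such chains; the choice is deliberate and
documented here because it changes cluster boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import sparse
from scipy.ndimage import uniform_filter
from scipy.sparse.csgraph import connected_components

from .annotations import ImageRecord

DEDUP_THRESHOLD = 0.8   # pairs scoring strictly above are duplicates
CLUSTER_THRESHOLD = 0.4  # pairs scoring at/above belong to one capture event


@dataclass(frozen=True)
class SsimParams:
    """SSIM stabilization constants and preprocessing geometry.

    ``k1``/``k2`` and the dynamic range ``L`` form the usual stabilizers
    C1=(k1*L)^2 and C2=(k2*L)^2.  Images are converted to single-channel
    grayscale and resized to ``comparison_size`` before scoring so that
    differently sized inputs are comparable; the window is uniform (not
    Gaussian-weighted), ``window_size`` pixels square.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0
    window_size: int = 7
    comparison_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        w, h = self.comparison_size
        if min(w, h) < self.window_size:
            raise ValueError("comparison_size smaller than the SSIM window")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise SSIM scores over an ordered id list."""

    image_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        n = len(self.image_ids)
        if scores.shape != (n, n):
            raise ValueError(f"scores shape {scores.shape} != ({n},{n})")
        if not np.allclose(scores, scores.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.diag(scores) == 1.0):
            raise ValueError("diagonal of a similarity matrix must be exactly 1.0")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.image_ids)

    def score(self, a: str, b: str) -> float:
        i = self.image_ids.index(a)
        j = self.image_ids.index(b)
        return float(self.scores[i, j])

    def submatrix(self, ids: Iterable[str]) -> "SimilarityMatrix":
        keep = [i for i, x in enumerate(self.image_ids) if x in set(ids)]
        return SimilarityMatrix(
            image_ids=tuple(self.image_ids[i] for i in keep),
            scores=self.scores[np.ix_(keep, keep)],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.scores, index=list(self.image_ids),
                          columns=list(self.image_ids))
        df.index.name = "image_id"
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, float_format="%.10f")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        m = df.to_numpy(dtype=float)
        # symmetrize away the round-trip rounding and pin the diagonal
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
        return cls(image_ids=tuple(df.columns), scores=m)


@dataclass(frozen=True)
class ClusterSet:
    """Partition of an id set into capture-event clusters."""

    clusters: tuple[frozenset[str], ...]
    threshold: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters must be disjoint")
            seen |= c

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def all_ids(self) -> frozenset[str]:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def membership(self) -> dict[str, int]:
        return {i: k for k, c in enumerate(self.clusters) for i in c}

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [(i, k) for k, c in enumerate(self.clusters) for i in sorted(c)]
        df = pd.DataFrame(rows, columns=["image_id", "cluster_id"])
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, threshold: float) -> "ClusterSet":
        df = pd.read_csv(path, dtype={"image_id": str, "cluster_id": int})
        groups = df.groupby("cluster_id")["image_id"].apply(frozenset)
        return cls(clusters=_canonical(groups.tolist()), threshold=threshold)


def _canonical(clusters: Iterable[frozenset[str]]) -> tuple[frozenset[str], ...]:
    """Order clusters by their smallest member so output is reproducible."""
    return tuple(sorted((frozenset(c) for c in clusters), key=min))


def load_grayscale(source: ImageRecord | str | Path,
                   params: SsimParams | None = None) -> np.ndarray:
    """Decode an image, convert to 8-bit grayscale (luma weights), and
    bilinearly resize to the comparison size.  Returns float64."""
    params = params or SsimParams()
    path = Path(source.path if isinstance(source, ImageRecord) else source)
    try:
        with Image.open(path) as img:
            gray = img.convert("L").resize(params.comparison_size,
                                           Image.Resampling.BILINEAR)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    return np.asarray(gray, dtype=np.float64)


def ssim_arrays(a: np.ndarray, b: np.ndarray,
                params: SsimParams | None = None) -> float:
    """Mean SSIM between two equal-shaped grayscale arrays.

    Uniform ``window_size`` x ``window_size`` windows; variances and the
    covariance use the unbiased (sample) normalization N/(N-1); the border
    of half a window, where the filter response is padded, is excluded
    from the mean.
    """
    params = params or SsimParams()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    win = params.window_size
    if min(a.shape) < win:
        raise ValueError("image smaller than the SSIM window")

    c1 = (params.k1 * params.dynamic_range) ** 2
    c2 = (params.k2 * params.dynamic_range) ** 2
    n = win * win
    cov_norm = n / (n - 1)

    mu_a = uniform_filter(a, win)
    mu_b = uniform_filter(b, win)
    var_a = cov_norm * (uniform_filter(a * a, win) - mu_a * mu_a)
    var_b = cov_norm * (uniform_filter(b * b, win) - mu_b * mu_b)
    cov = cov_norm * (uniform_filter(a * b, win) - mu_a * mu_b)

    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    ssim_map = num / den

    pad = (win - 1) // 2
    core = ssim_map[pad:ssim_map.shape[0] - pad, pad:ssim_map.shape[1] - pad]
    return float(np.mean(core))


def ssim(image_a: ImageRecord | str | Path, image_b: ImageRecord | str | Path,
         params: SsimParams | None = None) -> float:
    """SSIM between two images on disk (1.0 = identical)."""
    params = params or SsimParams()
    return ssim_arrays(load_grayscale(image_a, params),
                       load_grayscale(image_b, params), params)


def pairwise_matrix(records: Sequence[ImageRecord],
                    params: SsimParams | None = None) -> SimilarityMatrix:
    """Full symmetric SSIM matrix over a set of images.

    Ids are sorted and pairs visited row-major, so the matrix is
    reproducible regardless of manifest order.  Each image is decoded
    once; n(n-1)/2 SSIM evaluations.
    """
    if not records:
        raise ValueError("pairwise_matrix needs at least one record")
    params = params or SsimParams()
    recs = sorted(records, key=lambda r: r.image_id)
    ids = tuple(r.image_id for r in recs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image_ids in records")

    arrays = []
    for r in recs:
        try:
            arrays.append(load_grayscale(r, params))
        except IOError as exc:
            raise IOError(f"while loading {r.image_id}: {exc}") from exc

    n = len(recs)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = ssim_arrays(arrays[i], arrays[j], params)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            m[i, j] = m[j, i] = s
    return SimilarityMatrix(image_ids=ids, scores=m)


def _components(matrix: SimilarityMatrix, threshold: float,
                strict: bool) -> tuple[frozenset[str], ...]:
    """Connected components of the thresholded similarity graph."""
    s = matrix.scores.copy()
    np.fill_diagonal(s, -np.inf)
    adj = (s > threshold) if strict else (s >= threshold)
    _, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    groups: dict[int, set[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(matrix.image_ids[i])
    return _canonical(frozenset(g) for g in groups.values())


def dedup(matrix: SimilarityMatrix, threshold: float = DEDUP_THRESHOLD,
          seed: int = 0) -> tuple[frozenset[str], frozenset[str]]:
    """Remove near-duplicates scoring strictly above ``threshold``.

    Within each connected component of the duplicate graph, one image is
    kept (seeded-random choice) and the rest are removed; singletons are
    always kept.  Read literally, "delete everything above the threshold"
    would erase both members of every duplicate pair, so one
    representative is retained instead.  Returns ``(kept, removed)``,
    disjoint sets covering all ids.
    """
    rng = np.random.default_rng(seed)
    kept: set[str] = set()
    removed: set[str] = set()
    for comp in _components(matrix, threshold, strict=True):
        members = sorted(comp)
        if len(members) == 1:
            kept.add(members[0])
        else:
            keep = members[int(rng.integers(len(members)))]
            kept.add(keep)
            removed.update(m for m in members if m != keep)
    return frozenset(kept), frozenset(removed)


def cluster(matrix: SimilarityMatrix,
            threshold: float = CLUSTER_THRESHOLD) -> ClusterSet:
    """Partition images into capture-event clusters.

    Clusters are the connected components of the graph whose edges join
    pairs scoring at or above ``threshold``.
    """
    return ClusterSet(clusters=_components(matrix, threshold, strict=False),
                      threshold=threshold)


def select_representatives(clusters: ClusterSet, seed: int = 0) -> frozenset[str]:
    """One uniformly random frame per cluster (seeded, reproducible).

    Clusters are visited in canonical order (by smallest member id) so a
    fixed seed gives an identical selection across runs and platforms.
    """
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for comp in _canonical(clusters.clusters):
        members = sorted(comp)
        chosen.add(members[int(rng.integers(len(members)))])
    return frozenset(chosen)
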