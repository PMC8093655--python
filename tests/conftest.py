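import numpy as np
import pytest

from trapcurate import fixtures as fx
from trapcurate.annotations import (AnnotationSet, BoundingBox, VocObject)


def random_annotation_set(rng: np.random.Generator,
                          image_id: str = "img") -> AnnotationSet:
    """A random but valid annotation set for round-trip testing."""
    width = int(rng.integers(16, 512))
    height = int(rng.integers(16, 512))
    objects = []
    for _ in range(int(rng.integers(0, 5))):
        xmin = int(rng.integers(0, width - 1))
        ymin = int(rng.integers(0, height - 1))
        xmax = int(rng.integers(xmin + 1, width + 1))
        ymax = int(rng.integers(ymin + 1, height + 1))
        objects.append(VocObject(
            class_label=str(rng.choice(["animal", "rhino", "pig"])),
            box=BoundingBox(xmin, ymin, xmax, ymax),
            difficult=bool(rng.integers(2)),
            truncated=bool(rng.integers(2)),
        ))
    return AnnotationSet(image_id=image_id, width=width, height=height,
                         objects=tuple(objects))


def random_similarity_matrix(rng: np.random.Generator, n: int):
    """Random symmetric matrix in [-1, 1] with unit diagonal."""
    from trapcurate.similarity import SimilarityMatrix
    raw = rng.uniform(-1.0, 1.0, size=(n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    ids = tuple(f"im{k:02d}" for k in range(n))
    return SimilarityMatrix(image_ids=ids, scores=sym)


def brute_force_components(matrix, threshold: float, strict: bool):
    """Reachability oracle: exhaustive DFS over the thresholded graph."""
    n = len(matrix.image_ids)
    s = matrix.scores
    adj = {
        i: [j for j in range(n) if j != i
            and (s[i, j] > threshold if strict else s[i, j] >= threshold)]
        for i in range(n)
    }
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v])
        seen |= comp
        comps.append(frozenset(matrix.image_ids[v] for v in comp))
    return set(comps)


@pytest.fixture(scope="session")
def burst_dataset(tmp_path_factory):
    """Small synthetic dataset: 2 bursts x 3 frames, 2 scenes, 4 negatives."""
    root = tmp_path_factory.mktemp("burstdata")
    manifest, anns, truth = fx.generate_dataset(
        root, seed=7, n_bursts=2, frames_per_burst=3, n_scenes=2,
        n_negatives=4)
    return root, manifest, anns, truth
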