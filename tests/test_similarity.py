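"""SSIM scoring, duplicate removal, and capture-event clustering."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from conftest import brute_force_components, random_similarity_matrix
from trapcurate import fixtures as fx
from trapcurate.annotations import ImageRecord
from trapcurate.similarity import (ClusterSet, SimilarityMatrix, SsimParams,
                                   cluster, dedup, load_grayscale,
                                   pairwise_matrix, select_representatives,
                                   ssim, ssim_arrays)


@pytest.fixture(scope="module")
def scenes(tmp_path_factory):
    """Two frozen independent scenes and a 3-frame burst of the first."""
    root = tmp_path_factory.mktemp("scenes")
    rec_a, ann_a = fx.generate_scene(11, root, image_id="sceneA")
    rec_b, _ = fx.generate_scene(22, root, image_id="sceneB")
    burst = fx.generate_burst(rec_a, ann_a,
                              fx.BurstSpec(n_frames=3, seed=5), root)
    return rec_a, rec_b, [r for r, _ in burst]


class TestSsim:
    def test_self_similarity_is_one(self, scenes):
        rec_a, _, _ = scenes
        assert ssim(rec_a, rec_a) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, scenes):
        rec_a, rec_b, burst = scenes
        for x, y in [(rec_a, rec_b), (rec_a, burst[0]), (burst[0], burst[1])]:
            assert ssim(x, y) == ssim(y, x)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_implementation(self, seed):
        """Windowed-mean SSIM agrees with scikit-image's evaluator."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 255, (64, 64))
        b = np.clip(a + rng.normal(0, 20, a.shape), 0, 255)
        params = SsimParams()
        ref = sk_ssim(a, b, win_size=params.window_size,
                      gaussian_weights=False,
                      data_range=params.dynamic_range)
        assert ssim_arrays(a, b, params) == pytest.approx(ref, abs=1e-12)

    def test_matches_reference_on_fixture_images(self, scenes):
        rec_a, rec_b, _ = scenes
        params = SsimParams()
        a = load_grayscale(rec_a, params)
        b = load_grayscale(rec_b, params)
        ref = sk_ssim(a, b, win_size=7, gaussian_weights=False,
                      data_range=255.0)
        assert ssim(rec_a, rec_b) == pytest.approx(ref, abs=1e-12)

    def test_inverted_image_scores_low(self, scenes):
        rec_a, _, _ = scenes
        a = load_grayscale(rec_a)
        assert ssim_arrays(a, 255.0 - a) < 0.4

    def test_burst_above_scene_threshold(self, scenes):
        """Capture-event frames score >= 0.4; independent scenes < 0.4."""
        rec_a, rec_b, burst = scenes
        assert ssim(rec_a, burst[0]) > 0.4
        assert ssim(burst[0], burst[1]) > 0.4
        assert ssim(rec_a, rec_b) < 0.4
        assert ssim(burst[0], rec_b) < 0.4

    def test_undecodable_image_raises(self, tmp_path):
        bad = tmp_path / "corrupt.png"
        bad.write_bytes(b"not an image")
        good = tmp_path / "ok.png"
        fx.generate_scene(1, tmp_path, image_id="ok")
        with pytest.raises(IOError, match="corrupt.png"):
            ssim(bad, good)

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            SsimParams(window_size=6)


class TestPairwiseMatrix:
    def test_single_image(self, scenes):
        rec_a, _, _ = scenes
        m = pairwise_matrix([rec_a])
        assert m.scores.shape == (1, 1) and m.scores[0, 0] == 1.0

    def test_identical_files_score_one(self, scenes, tmp_path):
        rec_a, _, _ = scenes
        twin_path = tmp_path / "twin.png"
        twin_path.write_bytes(rec_a.path.read_bytes())
        twin = ImageRecord("twin", twin_path)
        m = pairwise_matrix([rec_a, twin])
        assert np.allclose(m.scores, 1.0)

    def test_burst_and_distinct_scene_structure(self, scenes):
        """Intra-burst pairs clear 0.4; cross pairs with the distinct
        scene fall below — matching per-pair brute force."""
        rec_a, rec_b, burst = scenes
        records = burst + [rec_b]
        m = pairwise_matrix(records)
        ids = m.image_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                expected = ssim(records[[r.image_id for r in records]
                                        .index(ids[i])],
                                records[[r.image_id for r in records]
                                        .index(ids[j])])
                assert m.scores[i, j] == pytest.approx(expected, abs=1e-12)
                both_burst = ids[i].startswith("sceneA_") and \
                    ids[j].startswith("sceneA_")
                assert (m.scores[i, j] >= 0.4) == both_burst

    def test_diagonal_and_symmetry_enforced(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(("a", "b"),
                             np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            SimilarityMatrix(("a", "b"),
                             np.array([[0.9, 0.5], [0.5, 1.0]]))

    def test_csv_round_trip(self, scenes, tmp_path):
        rec_a, rec_b, burst = scenes
        m = pairwise_matrix([rec_a, rec_b] + burst[:1])
        path = m.to_csv(tmp_path / "m.csv")
        back = SimilarityMatrix.from_csv(path)
        assert back.image_ids == m.image_ids
        assert np.allclose(back.scores, m.scores, atol=1e-9)


class TestDedup:
    def test_nothing_above_threshold_removes_nothing(self):
        rng = np.random.default_rng(0)
        m = random_similarity_matrix(rng, 6)
        m.scores[m.scores > 0.8] = 0.5
        np.fill_diagonal(m.scores, 1.0)
        kept, removed = dedup(m, 0.8, seed=0)
        assert removed == frozenset() and kept == frozenset(m.image_ids)

    def test_triple_duplicate_keeps_exactly_one(self):
        scores = np.full((3, 3), 0.95)
        np.fill_diagonal(scores, 1.0)
        m = SimilarityMatrix(("a", "b", "c"), scores)
        kept, removed = dedup(m, 0.8, seed=1)
        assert len(kept) == 1 and len(removed) == 2
        assert kept | removed == {"a", "b", "c"}

    def test_threshold_is_strict(self):
        scores = np.array([[1.0, 0.8], [0.8, 1.0]])
        m = SimilarityMatrix(("a", "b"), scores)
        kept, removed = dedup(m, 0.8, seed=0)
        assert removed == frozenset()  # exactly 0.8 is not "above 0.8"

    @pytest.mark.parametrize("trial", range(500))
    def test_idempotent_and_one_per_component(self, trial):
        """Dedup keeps exactly one id per duplicate component and a second
        pass over the survivors removes nothing."""
        rng = np.random.default_rng(1_000 + trial)
        m = random_similarity_matrix(rng, int(rng.integers(2, 13)))
        kept, removed = dedup(m, 0.8, seed=trial)
        assert kept | removed == set(m.image_ids)
        assert not kept & removed
        comps = brute_force_components(m, 0.8, strict=True)
        for comp in comps:
            assert len(comp & kept) == 1
        kept2, removed2 = dedup(m.submatrix(kept), 0.8, seed=trial + 1)
        assert removed2 == frozenset() and kept2 == kept

    def test_removal_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        m = random_similarity_matrix(rng, 10)
        counts = [len(dedup(m, t, seed=0)[1])
                  for t in (0.2, 0.4, 0.6, 0.8, 0.95)]
        assert counts == sorted(counts, reverse=True)


class TestCluster:
    def test_all_dissimilar_gives_singletons(self):
        rng = np.random.default_rng(0)
        m = random_similarity_matrix(rng, 5)
        m.scores[~np.eye(5, dtype=bool)] = 0.1
        cs = cluster(m, 0.4)
        assert cs.n_clusters == 5
        assert all(len(c) == 1 for c in cs.clusters)

    def test_three_block_matrix_gives_three_clusters(self):
        """Three groups of mutually similar images form three clusters."""
        n = 9
        scores = np.full((n, n), 0.1)
        for block in (slice(0, 3), slice(3, 6), slice(6, 9)):
            scores[block, block] = 0.9
        np.fill_diagonal(scores, 1.0)
        m = SimilarityMatrix(tuple(f"i{k}" for k in range(n)), scores)
        cs = cluster(m, 0.4)
        assert cs.n_clusters == 3
        assert sorted(len(c) for c in cs.clusters) == [3, 3, 3]

    def test_threshold_is_inclusive(self):
        scores = np.array([[1.0, 0.4], [0.4, 1.0]])
        m = SimilarityMatrix(("a", "b"), scores)
        assert cluster(m, 0.4).n_clusters == 1  # 0.4 itself clusters

    @pytest.mark.parametrize("trial", range(500))
    def test_agrees_with_reachability_oracle(self, trial):
        """Connected components equal exhaustive transitive closure."""
        rng = np.random.default_rng(2_000 + trial)
        n = int(rng.integers(1, 13))
        m = random_similarity_matrix(rng, n)
        t = float(rng.uniform(-0.5, 0.9))
        cs = cluster(m, t)
        assert set(cs.clusters) == brute_force_components(m, t, strict=False)

    def test_cluster_count_non_decreasing_in_threshold(self):
        rng = np.random.default_rng(4)
        m = random_similarity_matrix(rng, 12)
        counts = [cluster(m, t).n_clusters
                  for t in (-0.5, 0.0, 0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        cs = cluster(random_similarity_matrix(rng, 8), 0.4)
        path = cs.to_csv(tmp_path / "c.csv")
        assert ClusterSet.from_csv(path, 0.4).clusters == cs.clusters


class TestSelectRepresentatives:
    def test_singletons_select_everything(self):
        cs = ClusterSet(tuple(frozenset([f"i{k}"]) for k in range(5)), 0.4)
        assert select_representatives(cs, seed=0) == \
            frozenset(f"i{k}" for k in range(5))

    def test_deterministic_for_fixed_seed(self):
        cs = ClusterSet((frozenset("abc"), frozenset("xy")), 0.4)
        picks = {select_representatives(cs, seed=42) for _ in range(5)}
        assert len(picks) == 1

    def test_one_per_cluster(self):
        cs = ClusterSet((frozenset("abc"), frozenset("xy"),
                         frozenset(["z"])), 0.4)
        sel = select_representatives(cs, seed=3)
        assert len(sel) == 3
        for c in cs.clusters:
            assert len(sel & c) == 1

    def test_uniform_selection_frequency(self):
        """Over 1,000 seeds, each frame of a 3-cluster is chosen about a
        third of the time (within 5 binomial standard deviations)."""
        cs = ClusterSet((frozenset(["a", "b", "c"]), frozenset(["z"])), 0.4)
        counts = {"a": 0, "b": 0, "c": 0}
        for seed in range(1_000):
            pick = select_representatives(cs, seed=seed) - {"z"}
            counts[next(iter(pick))] += 1
        expected = 1_000 / 3
        sd = np.sqrt(1_000 * (1 / 3) * (2 / 3))
        for frame, n in counts.items():
            assert abs(n - expected) < 5 * sd, (frame, n)
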