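import numpy as np
import pytest

from infantmotion import clustering
from infantmotion.clustering import (
    ActivityLabel,
    ClusterModel,
    DegenerateInputError,
    assign,
    fit_kmeans,
    map_clusters_to_activities,
    select_cluster_count,
    silhouette_curve,
)


def brute_force_silhouette(x, labels):
    """O(n^2) per-point silhouette from first principles."""
    n = x.shape[0]
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        a = d[i, own & (np.arange(n) != i)].mean() if own.sum() > 1 else 0.0
        b = min(d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        scores[i] = 0.0 if own.sum() == 1 else (b - a) / max(a, b)
    return scores


def blobs(rng, centers, n_per, scale=0.1):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, scale, size=(n_per, len(c))))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


class TestKMeans:
    def test_two_separated_pairs_exact_centroids(self):
        x = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        cents, asg = fit_kmeans(x, 2, seed=0)
        got = sorted(cents.tolist())
        assert np.allclose(got, [[0, 0.5], [10, 0.5]])
        assert asg[0] == asg[1] and asg[2] == asg[3] and asg[0] != asg[2]

    def test_k_equals_points_zero_variance(self, rng):
        x = rng.normal(size=(5, 3))
        cents, asg = fit_kmeans(x, 5, seed=0)
        assert np.allclose(np.sort(cents, axis=0), np.sort(x, axis=0))

    def test_deterministic_given_seed(self, rng):
        x, _ = blobs(rng, [[0, 0], [5, 5], [0, 5]], 30, scale=0.5)
        _, a1 = fit_kmeans(x, 3, seed=7)
        _, a2 = fit_kmeans(x, 3, seed=7)
        assert (a1 == a2).all()

    def test_invalid_k(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_kmeans(x, 1)
        with pytest.raises(ValueError):
            fit_kmeans(x, 11)


class TestSilhouette:
    def test_three_tight_blobs_score_high(self, rng):
        x, _ = blobs(rng, [[0, 0], [20, 0], [0, 20]], 40)
        curve = silhouette_curve(x, [3], seed=0)
        assert curve[0][1] > 0.9

    def test_single_blob_at_k2_scores_low(self, rng):
        x = rng.normal(size=(120, 4))
        curve = silhouette_curve(x, [2], seed=0)
        assert curve[0][1] < 0.6

    def test_matches_bruteforce_oracle(self, rng):
        x, _ = blobs(rng, [[0, 0], [4, 1], [1, 5]], 40, scale=1.0)
        for k in (2, 3, 4):
            _, labels = fit_kmeans(x, k, seed=0)
            expected = brute_force_silhouette(x, labels).mean()
            got = dict(silhouette_curve(x, [k], seed=0))[k]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_values_within_definitional_bounds(self, rng):
        x = rng.normal(size=(60, 5))
        for k, s in silhouette_curve(x, range(2, 7), seed=0):
            assert -1.0 <= s <= 1.0

    def test_degenerate_identical_vectors(self):
        with pytest.raises(DegenerateInputError):
            silhouette_curve(np.ones((10, 3)), [2])


class TestSelection:
    def test_spec_example_selects_largest_qualifying_k(self):
        curve = [(2, 0.8), (3, 0.7), (4, 0.62), (5, 0.45)]
        assert select_cluster_count(curve, threshold=0.6) == (4, True)

    def test_fallback_to_argmax_with_warning_flag(self):
        assert select_cluster_count([(2, 0.5), (3, 0.4)]) == (2, False)

    def test_k_max_caps_selection(self):
        curve = [(k, 0.9) for k in range(2, 12)]
        assert select_cluster_count(curve, k_max=8) == (8, True)

    def test_empty_curve_raises(self):
        with pytest.raises(ValueError):
            select_cluster_count([])


class TestActivityNaming:
    def test_intensity_and_step_ranking(self):
        cents = np.zeros((4, 64))
        intensity = np.array([600.0, 2000.0, 5500.0, 5000.0])
        steps = np.array([10.0, 30.0, 100.0, 400.0])
        mapping = map_clusters_to_activities(cents, intensity, steps)
        assert mapping == {
            0: ActivityLabel.SLEEPING,
            1: ActivityLabel.WEAK_MOVEMENT,
            2: ActivityLabel.STRONG_MOVEMENT,
            3: ActivityLabel.EXTERNAL_FORCE,
        }

    def test_override_is_echoed(self):
        override = {0: ActivityLabel.EXTERNAL_FORCE, 1: ActivityLabel.SLEEPING}
        got = map_clusters_to_activities(np.zeros((4, 64)), np.zeros(4), None, override)
        assert got == override

    def test_wrong_k_warns_and_identity_maps(self):
        with pytest.warns(UserWarning):
            mapping = map_clusters_to_activities(np.zeros((3, 64)), np.zeros(3))
        assert mapping == {0: ActivityLabel(0), 1: ActivityLabel(1), 2: ActivityLabel(2)}


class TestAssign:
    def make_model(self):
        cents = np.array([[0.0] * 64, [10.0] * 64, [20.0] * 64, [-10.0] * 64])
        amap = {i: ActivityLabel(i) for i in range(4)}
        return ClusterModel(k=4, centroids=cents, activity_map=amap)

    def test_centroid_maps_to_its_label(self):
        model = self.make_model()
        assert assign(model, model.centroids[2])[0] == 2

    def test_midpoint_tie_breaks_to_lowest_index(self):
        model = self.make_model()
        midpoint = np.full(64, 5.0)  # equidistant from centroids 0 and 1
        assert assign(model, midpoint)[0] == 0

    def test_matches_bruteforce_distance_table(self, rng):
        model = self.make_model()
        latents = rng.normal(0, 15, size=(100, 64))
        got = assign(model, latents)
        d = np.linalg.norm(latents[:, None] - model.centroids[None], axis=2)
        assert (got == d.argmin(axis=1)).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            assign(self.make_model(), np.zeros(32))
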