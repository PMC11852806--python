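"""Feature construction, the k-means implementation, magnitude sorting."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from hphabitat.clustering import (
    FeatureMatrix,
    build_features,
    cluster_habitats,
    kmeans,
    sort_clusters,
)
from hphabitat.maps import DegenerateInputError, ParameterMap, TumourROI


@lru_cache(maxsize=None)
def _all_assignments(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int8)


def brute_force_min_wss(X: np.ndarray, k: int) -> float:
    """Global minimum within-cluster SS by exhaustive label enumeration."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    A = _all_assignments(n, k)
    sq = (X**2).sum(axis=1)
    best = np.inf
    for c in range(k):
        pass  # vectorised below
    total = np.zeros(len(A))
    for c in range(k):
        mask = A == c
        counts = mask.sum(axis=1)
        sums = mask @ X
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = mask @ sq - (sums**2).sum(axis=1) / counts
        total += np.where(counts > 0, contrib, 0.0)
    return float(total.min())


def _features_from(X, n_intensity=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X,
        [f"ch{i}" for i in range(X.shape[1])],
        np.arange(X.shape[0]),
        (1, X.shape[0]),
        n_intensity if n_intensity is not None else X.shape[1],
    )


class TestBuildFeatures:
    def _maps(self, small_roi, values_a, values_b=None):
        a = ParameterMap(values_a, "SNR_Pyr")
        maps = [a] if values_b is None else [a, ParameterMap(values_b, "k_PL")]
        return maps

    def test_two_channel_normalization_contract(self, small_roi):
        rng = np.random.default_rng(0)
        maps = self._maps(small_roi, rng.uniform(10, 50, (8, 8)),
                          rng.uniform(0.0, 0.05, (8, 8)))
        fm = build_features(maps, small_roi, snr_floor=0.0)
        assert fm.X.shape == (small_roi.n_pixels, 2)
        assert np.allclose(fm.X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(fm.X.std(axis=0), 1.0, atol=1e-12)

    def test_constant_channel_is_degenerate(self, small_roi):
        maps = self._maps(small_roi, np.full((8, 8), 7.0))
        with pytest.raises(DegenerateInputError, match="constant"):
            build_features(maps, small_roi, snr_floor=0.0)

    def test_snr_floor_above_max_leaves_no_pixels(self, small_roi):
        rng = np.random.default_rng(1)
        maps = self._maps(small_roi, rng.uniform(10, 20, (8, 8)))
        with pytest.raises(DegenerateInputError, match="survive"):
            build_features(maps, small_roi, snr_floor=100.0)

    def test_snr_floor_marks_low_snr_pixels_background(self, small_roi):
        vals = np.full((8, 8), 30.0)
        vals[2, 2] = 1.0  # below floor
        vals[3, :] = 50.0
        fm = build_features(self._maps(small_roi, vals), small_roi, snr_floor=5.0)
        assert 2 * 8 + 2 not in fm.pixel_index
        assert fm.X.shape[0] == small_roi.n_pixels - 1

    def test_spatial_weight_appends_scaled_coordinates(self, small_roi):
        rng = np.random.default_rng(2)
        fm = build_features(
            self._maps(small_roi, rng.uniform(10, 50, (8, 8))),
            small_roi, snr_floor=0.0, spatial_weight=0.5,
        )
        assert fm.channel_names == ["SNR_Pyr", "row", "col"]
        rows, cols = np.divmod(fm.pixel_index, 8)
        assert np.allclose(fm.X[:, 1], rows * 0.5)
        assert np.allclose(fm.X[:, 2], cols * 0.5)


class TestKMeans:
    def test_three_well_separated_1d_groups(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [10.0], [10.1]])
        res = kmeans(X, k=3, n_restarts=20, seed=0)
        groups = {tuple(sorted(np.flatnonzero(res.labels == j))) for j in range(3)}
        assert groups == {(0, 1), (2, 3), (4, 5)}
        assert sorted(np.round(res.centroids.ravel(), 6)) == [0.05, 5.05, 10.05]

    def test_k_equals_one_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(17, 2))
        res = kmeans(X, k=1, n_restarts=5, seed=0)
        assert np.allclose(res.centroids[0], X.mean(axis=0))
        assert res.wss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    @pytest.mark.parametrize("trial", range(25))
    def test_reaches_brute_force_global_optimum(self, trial):
        """On tiny instances the best-of-20-restarts objective equals the
        exhaustive-enumeration global minimum of within-cluster SS."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 11))
        d = int(rng.integers(1, 4))
        k = int(rng.integers(1, min(3, n) + 1))
        X = rng.normal(size=(n, d))
        res = kmeans(X, k=k, n_restarts=20, seed=trial)
        assert res.wss == pytest.approx(brute_force_min_wss(X, k), rel=1e-9, abs=1e-12)

    def test_objective_non_increasing_across_iterations(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        res = kmeans(X, k=3, n_restarts=1, seed=5)
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 2))
        a = kmeans(X, k=3, seed=11)
        b = kmeans(X, k=3, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    def test_matches_sklearn_objective_on_moderate_instance(self):
        """Independent library cross-check on the attained objective."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(7)
        X = np.concatenate(
            [rng.normal(m, 0.3, size=(60, 2)) for m in (0.0, 3.0, 6.0)]
        )
        ours = kmeans(X, k=3, n_restarts=20, seed=0)
        ref = sklearn_cluster.KMeans(n_clusters=3, n_init=20, random_state=0).fit(X)
        assert ours.wss == pytest.approx(ref.inertia_, rel=1e-6)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans(np.zeros((2, 1)), k=3)


class TestSortClusters:
    def test_labels_ascend_with_cluster_magnitude(self):
        # three clusters with magnitudes 3.2, 1.1, 2.0 -> relabelled 3, 1, 2
        X = np.array([[3.2], [3.2], [1.1], [1.1], [2.0], [2.0]])
        raw = np.array([0, 0, 1, 1, 2, 2])
        hm = sort_clusters(raw, _features_from(X))
        grid = hm.labels.ravel()
        assert grid.tolist() == [3, 3, 1, 1, 2, 2]
        assert np.all(np.diff(hm.ordering_stat) > 0)

    def test_already_sorted_input_unchanged(self):
        X = np.array([[1.0], [2.0], [3.0]])
        raw = np.array([0, 1, 2])
        hm = sort_clusters(raw, _features_from(X))
        assert hm.labels.ravel().tolist() == [1, 2, 3]

    def test_pure_relabelling_preserves_partition(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 2))
        raw = rng.integers(0, 3, size=100)
        hm = sort_clusters(raw, _features_from(X))
        new = hm.labels.ravel()
        # multiset of cluster sizes unchanged and pixel co-membership preserved
        assert sorted(np.bincount(raw).tolist()) == sorted(
            np.bincount(new)[1:].tolist()
        )
        for u in np.unique(raw):
            assert len(np.unique(new[raw == u])) == 1

    def test_tie_breaks_on_smaller_original_label(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        raw = np.array([1, 1, 0, 0])
        hm = sort_clusters(raw, _features_from(X))
        # equal magnitudes: original label 0 -> habitat 1, label 1 -> habitat 2
        assert hm.labels.ravel().tolist() == [2, 2, 1, 1]

    def test_spatial_columns_excluded_from_magnitude(self):
        # intensity says cluster 0 < cluster 1 even though spatial says opposite
        X = np.array([[0.0, 100.0], [0.0, 100.0], [5.0, 0.0], [5.0, 0.0]])
        raw = np.array([0, 0, 1, 1])
        hm = sort_clusters(raw, _features_from(X, n_intensity=1))
        assert hm.labels.ravel().tolist() == [1, 1, 2, 2]


def test_zero_noise_phantom_recovered_exactly(recovery_phantom_noiseless):
    """Combined [SNR_Pyr + k_PL] clustering reproduces the planted habitats
    up to relabelling on a noiseless phantom (ARI = 1)."""
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    ph = recovery_phantom_noiseless
    hm = cluster_habitats([ph.maps["SNR_Pyr"], ph.maps["k_PL"]], ph.roi, seed=2)
    sel = hm.labels > 0
    ari = sklearn_metrics.adjusted_rand_score(ph.truth_labels[sel], hm.labels[sel])
    assert ari == 1.0


def test_identical_seed_gives_identical_habitat_map(noisy_phantom):
    ph = noisy_phantom
    maps = [ph.maps["SNR_Pyr"], ph.maps["k_PL"]]
    a = cluster_habitats(maps, ph.roi, seed=13)
    b = cluster_habitats(maps, ph.roi, seed=13)
    assert np.array_equal(a.labels, b.labels)
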