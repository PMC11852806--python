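"""Normalized habitat means, mismatch ratio, cross-habitat statistics."""

import numpy as np
import pytest

from hphabitat.clustering import HabitatMap, cluster_habitats
from hphabitat.maps import ParameterMap
from hphabitat.mismatch import (
    cluster_summaries,
    compare_across_clusters,
    normalize_map,
)


def _habitats(labels, k=None):
    labels = np.asarray(labels)
    k = k if k is not None else int(labels.max())
    return HabitatMap(labels, k=k, ordering_stat=np.arange(k, dtype=float))


class TestNormalizeMap:
    def test_constant_map_becomes_ones(self):
        pm = ParameterMap(np.full((4, 4), 7.0), "SNR_Pyr")
        hm = _habitats(np.ones((4, 4), dtype=int))
        assert np.allclose(normalize_map(pm, hm).values, 1.0)

    def test_two_values_equally_weighted(self):
        vals = np.array([[1.0, 3.0], [1.0, 3.0]])
        pm = ParameterMap(vals, "k_PL")
        hm = _habitats(np.ones((2, 2), dtype=int))
        out = normalize_map(pm, hm).values
        assert np.allclose(np.unique(out), [0.5, 1.5])

    def test_clustered_mean_is_one_to_machine_precision(self):
        rng = np.random.default_rng(0)
        pm = ParameterMap(rng.uniform(1, 9, (16, 16)), "SNR_Pyr")
        labels = rng.integers(0, 4, (16, 16))
        hm = _habitats(labels, k=3)
        out = normalize_map(pm, hm).values
        assert out[labels > 0].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        pm = ParameterMap(np.full((3, 3), -1.0), "PNG")
        hm = _habitats(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="non-positive"):
            normalize_map(pm, hm)


class TestClusterSummaries:
    def test_uniform_maps_all_ratios_one(self):
        snr = ParameterMap(np.full((6, 6), 20.0), "SNR_Pyr")
        kpl = ParameterMap(np.full((6, 6), 0.02), "k_PL")
        labels = np.zeros((6, 6), dtype=int)
        labels[0:2] = 1
        labels[2:4] = 2
        labels[4:6] = 3
        out = cluster_summaries(_habitats(labels), snr, kpl)
        assert [s.label for s in out] == [1, 2, 3]
        for s in out:
            assert s.mismatch_ratio == pytest.approx(1.0)

    def test_pixel_weighted_norm_means_average_to_one(self):
        rng = np.random.default_rng(1)
        snr = ParameterMap(rng.uniform(5, 50, (12, 12)), "SNR_Pyr")
        kpl = ParameterMap(rng.uniform(0.005, 0.05, (12, 12)), "k_PL")
        labels = rng.integers(0, 4, (12, 12))
        out = cluster_summaries(_habitats(labels, k=3), snr, kpl)
        n_total = sum(s.n_pixels for s in out)
        for attr in ("norm_mean_snr", "norm_mean_kpl", "norm_mean_combined"):
            weighted = sum(getattr(s, attr) * s.n_pixels for s in out) / n_total
            assert weighted == pytest.approx(1.0, abs=1e-12)

    def test_mismatch_ratio_invariant_to_map_rescaling(self):
        rng = np.random.default_rng(2)
        snr_vals = rng.uniform(5, 50, (8, 8))
        kpl_vals = rng.uniform(0.005, 0.05, (8, 8))
        labels = rng.integers(1, 4, (8, 8))
        base = cluster_summaries(
            _habitats(labels), ParameterMap(snr_vals, "SNR_Pyr"),
            ParameterMap(kpl_vals, "k_PL"),
        )
        scaled = cluster_summaries(
            _habitats(labels), ParameterMap(13.7 * snr_vals, "SNR_Pyr"),
            ParameterMap(0.03 * kpl_vals, "k_PL"),
        )
        for a, b in zip(base, scaled):
            assert a.mismatch_ratio == pytest.approx(b.mismatch_ratio, rel=1e-12)

    def test_empty_habitat_omitted_with_warning(self):
        snr = ParameterMap(np.full((4, 4), 20.0), "SNR_Pyr")
        kpl = ParameterMap(np.full((4, 4), 0.02), "k_PL")
        labels = np.ones((4, 4), dtype=int)  # habitat 2 and 3 empty
        with pytest.warns(UserWarning, match="no pixels"):
            out = cluster_summaries(_habitats(labels, k=3), snr, kpl)
        assert [s.label for s in out] == [1]

    def test_planted_mismatch_habitat_attains_maximal_ratio(self, noisy_phantom):
        ph = noisy_phantom
        hm = cluster_habitats([ph.maps["SNR_Pyr"], ph.maps["k_PL"]], ph.roi, seed=3)
        out = cluster_summaries(hm, ph.maps["SNR_Pyr"], ph.maps["k_PL"])
        medium = next(s for s in out if s.label == 2)
        assert medium.mismatch_ratio == max(s.mismatch_ratio for s in out)
        assert medium.mismatch_ratio > 1.0


class TestCompareAcrossClusters:
    def test_identical_groups_show_no_difference(self):
        g = [np.array([2.0, 2.0, 2.0])] * 3
        res = compare_across_clusters(g)
        assert res.omnibus_p == pytest.approx(1.0)
        assert all(p["p_adj"] > 0.9 for p in res.pairwise)

    def test_separated_groups_detected(self):
        g = [np.array([1.0, 2, 3]), np.array([11.0, 12, 13]), np.array([21.0, 22, 23])]
        res = compare_across_clusters(g)
        assert res.omnibus_p < 0.05

    def test_dunn_pairwise_matches_rank_arithmetic(self):
        """Frozen oracle from first-principles rank computation: groups
        (1,2,3), (4,5,6), (7,8,9) give Dunn-adjusted p-values
        0.539137, 0.021871, 0.539137 (KW H = 7.2, p = 0.027324)."""
        g = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        res = compare_across_clusters(g, route="nonparametric")
        assert res.method == "kruskal+dunn"
        assert res.omnibus_stat == pytest.approx(7.2)
        assert res.omnibus_p == pytest.approx(0.02732372, abs=1e-6)
        padj = {tuple(p["groups"]): p["p_adj"] for p in res.pairwise}
        assert padj[(0, 1)] == pytest.approx(0.53913748, abs=1e-6)
        assert padj[(0, 2)] == pytest.approx(0.02187107, abs=1e-6)
        assert padj[(1, 2)] == pytest.approx(0.53913748, abs=1e-6)

    def test_dunn_tie_correction(self):
        """Frozen oracle with ties: groups (1,1,2), (2,3,3), (5,5,6)."""
        g = [np.array([1.0, 1, 2]), np.array([2.0, 3, 3]), np.array([5.0, 5, 6])]
        res = compare_across_clusters(g, route="nonparametric")
        padj = {tuple(p["groups"]): p["p_adj"] for p in res.pairwise}
        assert padj[(0, 1)] == pytest.approx(0.67543893, abs=1e-6)
        assert padj[(0, 2)] == pytest.approx(0.02390964, abs=1e-6)
        assert padj[(1, 2)] == pytest.approx(0.44927443, abs=1e-6)

    def test_normal_data_takes_anova_route(self):
        rng = np.random.default_rng(3)
        g = [rng.normal(m, 1.0, 40) for m in (0.0, 0.2, 3.0)]
        res = compare_across_clusters(g)
        assert res.method == "anova+holm-sidak"
        assert res.omnibus_p < 0.05

    def test_two_groups_degrade_to_binary_test(self):
        rng = np.random.default_rng(4)
        res_n = compare_across_clusters([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        assert res_n.method == "t-test"
        res_r = compare_across_clusters(
            [np.array([1.0, 1, 1, 2, 100.0]), np.array([5.0, 6, 7, 8, 9])]
        )
        assert res_r.method == "mann-whitney"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_across_clusters([np.array([1.0]), np.array([1.0, 2.0])])

    def test_adjusted_pvalues_within_unit_interval(self):
        rng = np.random.default_rng(5)
        for rep in range(5):
            g = [rng.exponential(1.0, 12) for _ in range(3)]
            res = compare_across_clusters(g)
            assert 0.0 <= res.omnibus_p <= 1.0
            assert all(0.0 <= p["p_adj"] <= 1.0 for p in res.pairwise)
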