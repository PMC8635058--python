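"""Cluster-permutation unit and property tests.

The independent oracle implemented here (``brute_force_max_masses``) uses
scipy's paired t-test and a plain breadth-first flood fill over an
explicit neighbor list — deliberately none of the package's vectorized
machinery — so that the exhaustive sign-flip null can be checked
end-to-end against a second implementation.
"""

import numpy as np
import pytest
from scipy import stats

from ambitopo.clusterstats import (Cluster, ClusterSettings, cluster_p_values,
                                   cluster_permutation_test, extract_bounds,
                                   paired_t_map, permutation_null, t_threshold,
                                   threshold_and_cluster)
from ambitopo.synthetic import generate_null_subject_ersp


# ---------------------------------------------------------------------------
# independent oracle


def brute_force_clusters(t_map, thr, edge_set, min_nbrs, nbr_lists):
    """Flood-fill clustering over an explicit voxel graph (oracle)."""
    C, F, T = t_map.shape
    out = []
    for sign in (1, -1):
        sup = {(c, f, t) for c in range(C) for f in range(F) for t in range(T)
               if sign * t_map[c, f, t] >= thr}
        if min_nbrs > 0:
            sup = {v for v in sup
                   if sum((n, v[1], v[2]) in sup for n in nbr_lists[v[0]]) >= min_nbrs}
        seen = set()
        for v in sorted(sup):
            if v in seen:
                continue
            comp, queue = [], [v]
            seen.add(v)
            while queue:
                c, f, t = queue.pop()
                comp.append((c, f, t))
                nxt = ([(n, f, t) for n in nbr_lists[c]]
                       + [(c, f + df, t) for df in (-1, 1)]
                       + [(c, f, t + dt) for dt in (-1, 1)])
                for w in nxt:
                    if w in sup and w not in seen:
                        seen.add(w)
                        queue.append(w)
            out.append((sign, sum(abs(t_map[c, f, t]) for c, f, t in comp), comp))
    return out


def brute_force_max_masses(ha, la, thr, nbr_lists, min_nbrs=0):
    """Exhaustive sign-flip null of the per-polarity max cluster mass."""
    n = ha.shape[0]
    d = ha - la
    pos, neg = [], []
    for bits in range(2 ** n):
        signs = np.array([1 - 2 * ((bits >> b) & 1) for b in range(n)])
        flipped = d * signs[:, None, None, None]
        t_map = stats.ttest_rel(flipped, np.zeros_like(flipped), axis=0).statistic
        t_map = np.nan_to_num(t_map)
        comps = brute_force_clusters(t_map, thr, None, min_nbrs, nbr_lists)
        pos.append(max([m for s, m, _ in comps if s == 1], default=0.0))
        neg.append(max([m for s, m, _ in comps if s == -1], default=0.0))
    return np.array(pos), np.array(neg)


# ---------------------------------------------------------------------------
# elementwise t


class TestPairedT:
    def test_hand_computed_example(self):
        """Differences [2, 0, 1, 1]: t = 1 / (0.8165/2) ~ 2.449."""
        ha = np.array([2.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1, 1)
        la = np.zeros_like(ha)
        t = paired_t_map(ha, la)
        assert t[0, 0, 0] == pytest.approx(2.449489742783178, abs=1e-12)
        ref = stats.ttest_rel(ha[:, 0, 0, 0], la[:, 0, 0, 0]).statistic
        assert t[0, 0, 0] == pytest.approx(ref)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(0)
        ha = rng.standard_normal((6, 2, 3, 4))
        la = rng.standard_normal((6, 2, 3, 4))
        np.testing.assert_allclose(paired_t_map(ha, la), -paired_t_map(la, ha))

    def test_null_symmetric_noise_mean_near_zero(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((40, 2, 3, 4))
        ha = base + rng.standard_normal((40, 2, 3, 4))
        la = base + rng.standard_normal((40, 2, 3, 4))
        t = paired_t_map(ha, la)
        assert abs(t.mean()) < 3.0 / np.sqrt(t.size)

    def test_zero_variance_triplet_set_to_zero(self, caplog):
        ha = np.ones((4, 1, 1, 1))
        la = np.zeros((4, 1, 1, 1)) + np.array([0.1, 0.2, 0.3, 0.4]).reshape(4, 1, 1, 1)
        ha2 = np.concatenate([ha, ha], axis=1)  # ch0: constant diff
        la2 = np.concatenate([np.zeros((4, 1, 1, 1)), la], axis=1)
        with caplog.at_level("WARNING"):
            t = paired_t_map(ha2, la2)
        assert t[0, 0, 0] == 0.0
        assert "zero-variance" in caplog.text


class TestThresholdAndCluster:
    def test_all_subthreshold_gives_empty_list(self, pair_montage):
        m, g = pair_montage
        assert threshold_and_cluster(np.zeros((2, 3, 3)), 10, g) == []

    def test_singleton_cluster_without_neighbor_rule(self, pair_montage):
        m, g = pair_montage
        t = np.zeros((2, 4, 4))
        t[0, 1, 2] = 3.2
        cls = threshold_and_cluster(t, df=30, graph=g, alpha=0.01,
                                    min_channel_neighbors=0)
        assert len(cls) == 1 and cls[0].mass == pytest.approx(3.2)
        assert cls[0].polarity == "positive" and cls[0].size == 1

    def test_block_on_connected_pair_is_one_cluster(self, pair_montage):
        """Brute-force oracle: a 2x2x2 suprathreshold block is one component."""
        m, g = pair_montage
        t = np.zeros((2, 4, 4))
        t[:, 1:3, 1:3] = 5.0
        cls = threshold_and_cluster(t, df=30, graph=g, min_channel_neighbors=0)
        nbr_lists = [[1], [0]]
        oracle = brute_force_clusters(t, t_threshold(30), None, 0, nbr_lists)
        oracle_masses = sorted(m_ for s, m_, _ in oracle if s == 1)
        assert [c.mass for c in cls] == pytest.approx(oracle_masses)
        assert len(cls) == 1 and cls[0].size == 8 and cls[0].mass == pytest.approx(40.0)

    def test_min_neighbor_criterion_prunes_isolated_channels(self, graph16, montage16):
        t = np.zeros((16, 3, 3))
        # suprathreshold at one channel only: pruned with min 2 neighbors
        t[0, 1, 1] = 9.0
        assert threshold_and_cluster(t, 10, graph16, montage16.channels) == []
        # a clique of frontal channels survives
        idx = montage16.index(("Fp1", "Fp2", "F3", "Fz", "F4"))
        t[idx, 1, 1] = 9.0
        cls = threshold_and_cluster(t, 10, graph16, montage16.channels)
        assert len(cls) == 1
        assert set(cls[0].members[:, 0]) <= set(idx)

    def test_polarities_cluster_separately(self, pair_montage):
        m, g = pair_montage
        t = np.zeros((2, 4, 4))
        t[:, 0, 0] = 6.0
        t[:, 3, 3] = -6.0
        cls = threshold_and_cluster(t, 20, g, min_channel_neighbors=0)
        assert {c.polarity for c in cls} == {"positive", "negative"}

    def test_exchangeability_swap_flips_polarity_with_same_mass(self, graph16):
        rng = np.random.default_rng(5)
        ha, la = generate_null_subject_ersp(8, 16, 6, 6, seed=5)
        ha = ha + 0.5  # induce some clusters
        t1 = paired_t_map(ha, la)
        t2 = paired_t_map(la, ha)
        c1 = threshold_and_cluster(t1, 7, graph16)
        c2 = threshold_and_cluster(t2, 7, graph16)
        m1 = sorted((c.polarity, round(c.mass, 9)) for c in c1)
        m2 = sorted(({"positive": "negative", "negative": "positive"}[c.polarity],
                     round(c.mass, 9)) for c in c2)
        assert m1 == m2 and len(m1) > 0


class TestPermutationNull:
    def test_exhaustive_equals_brute_force_enumeration(self, pair_montage):
        """Module's exhaustive null == independent flood-fill/scipy oracle."""
        m, g = pair_montage
        rng = np.random.default_rng(2)
        ha = rng.standard_normal((5, 2, 3, 3))
        la = rng.standard_normal((5, 2, 3, 3))
        ha[:, :, 1, 1] += 1.5
        null = permutation_null(ha, la, g, settings=ClusterSettings(
            min_channel_neighbors=0), exhaustive=True)
        thr = t_threshold(4)
        pos, neg = brute_force_max_masses(ha, la, thr, [[1], [0]], min_nbrs=0)
        np.testing.assert_allclose(np.sort(null["positive"]), np.sort(pos), atol=1e-9)
        np.testing.assert_allclose(np.sort(null["negative"]), np.sort(neg), atol=1e-9)

    def test_observed_mass_invariant_to_seed(self, graph16):
        ha, la = generate_null_subject_ersp(6, 16, 5, 5, seed=8)
        ha = ha + 0.6
        for seed in (0, 99):
            obs, _ = cluster_permutation_test(
                ha, la, graph16, np.arange(5.0), np.linspace(0, 0.5, 5),
                settings=ClusterSettings(n_perm=50), seed=seed)
            masses = [round(c.mass, 9) for c in obs]
            if seed == 0:
                ref = masses
        assert masses == ref and len(ref) > 0

    def test_identity_flip_keeps_p_positive(self, pair_montage):
        m, g = pair_montage
        rng = np.random.default_rng(3)
        ha = rng.standard_normal((5, 2, 3, 3)) + 2.0
        la = rng.standard_normal((5, 2, 3, 3))
        obs, null = cluster_permutation_test(
            ha, la, g, np.arange(3.0), np.linspace(0, 0.5, 3),
            settings=ClusterSettings(min_channel_neighbors=0), exhaustive=True)
        assert all(c.p_value > 0 for c in obs)

    def test_nperm_validation(self, pair_montage):
        m, g = pair_montage
        ha = np.random.default_rng(0).standard_normal((3, 2, 2, 2))
        with pytest.raises(ValueError):
            permutation_null(ha, ha, g, settings=ClusterSettings(n_perm=0))


class TestClusterPValues:
    def _cluster(self, mass):
        return Cluster(members=np.array([[0, 0, 0]]), polarity="positive", mass=mass)

    def test_counting_rule_extremes_and_median(self):
        null = {"positive": np.arange(1.0, 2001.0), "negative": np.zeros(2000)}
        top = self._cluster(5000.0)
        bottom = self._cluster(0.5)
        mid = self._cluster(1000.0)
        out = cluster_p_values([top, bottom, mid], null)
        assert out[0].p_value == pytest.approx(1 / 2001)
        assert out[1].p_value == pytest.approx(1.0)
        assert out[2].p_value == pytest.approx((1 + 1001) / 2001)
        assert out[0].significant and not out[1].significant

    def test_significance_threshold(self):
        null = {"positive": np.arange(1.0, 101.0), "negative": np.zeros(100)}
        c = cluster_p_values([self._cluster(99.5)], null)[0]
        assert c.p_value == pytest.approx(2 / 101)
        assert c.significant  # 0.0198 < 0.025
        c2 = cluster_p_values([self._cluster(99.5)], null, cluster_alpha=0.01)[0]
        assert not c2.significant


class TestExtractBounds:
    def test_bounds_are_member_minmax_in_axis_units(self):
        freqs = np.arange(4.0, 14.0)
        times = np.linspace(0, 0.5, 11)
        cl = Cluster(members=np.array([[0, 3, 2], [1, 5, 4], [0, 4, 3]]),
                     polarity="positive", mass=10.0)
        extract_bounds(cl, freqs, times, ("A", "B"))
        assert cl.f_bounds == (7.0, 9.0)
        assert cl.t_bounds == (pytest.approx(0.10), pytest.approx(0.20))
        assert cl.channel_set == ("A", "B")

    def test_singleton_degenerate_bounds(self):
        cl = Cluster(members=np.array([[1, 2, 3]]), polarity="negative", mass=4.0)
        extract_bounds(cl, np.arange(4.0, 10.0), np.linspace(0, 0.5, 6), ("A", "B"))
        assert cl.f_bounds[0] == cl.f_bounds[1]
        assert cl.t_bounds[0] == cl.t_bounds[1]
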