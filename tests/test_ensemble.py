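import itertools

import numpy as np
import pytest

from mcist import (
    LabelVector,
    ZetaCombination,
    ari,
    cluster_features,
    coassociation,
    concat_features,
    consensus_cluster,
    enumerate_combinations,
    nmi,
)
from mcist.spatial import SpatialEmbedding


def brute_force_coassociation(labelings):
    """O(R * N^2) pair-counting oracle."""
    n = len(labelings[0])
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            c[i, j] = sum(lab[i] == lab[j] for lab in labelings) / len(labelings)
    return c


def contingency_nmi(a, b):
    """NMI from hand-assembled contingency table, arithmetic normalization."""
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    mi = 0.0
    for va in ua:
        for vb in ub:
            nij = np.sum((a == va) & (b == vb))
            if nij:
                mi += (nij / n) * np.log(n * nij / (np.sum(a == va) * np.sum(b == vb)))
    ha = -sum(
        (np.sum(a == v) / n) * np.log(np.sum(a == v) / n) for v in ua
    )
    hb = -sum(
        (np.sum(b == v) / n) * np.log(np.sum(b == v) / n) for v in ub
    )
    if ha == 0 and hb == 0:
        return 1.0
    denom = 0.5 * (ha + hb)
    return mi / denom if denom > 0 else 0.0


def pair_counting_ari(a, b):
    """ARI from explicit pair counting."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        x, y = a[i] == a[j], b[i] == b[j]
        ss += x and y
        sd += x and not y
        ds += not x and y
        dd += not x and not y
    total = ss + sd + ds + dd
    exp = (ss + sd) * (ss + ds) / total
    mx = 0.5 * ((ss + sd) + (ss + ds))
    if mx == exp:
        return 1.0
    return (ss - exp) / (mx - exp)


class TestEnumerate:
    def test_four_scales_give_eight(self):
        combos = enumerate_combinations(4)
        assert len(combos) == 8
        assert all(c.zeta[0] == 1 for c in combos)
        assert len({tuple(c.zeta) for c in combos}) == 8

    def test_single_scale(self):
        combos = enumerate_combinations(1)
        assert len(combos) == 1
        np.testing.assert_array_equal(combos[0].zeta, [1.0])

    def test_three_scales_match_brute_force(self):
        got = {tuple(c.zeta) for c in enumerate_combinations(3)}
        want = {(1.0, a, b) for a in (0.0, 1.0) for b in (0.0, 1.0)}
        assert got == want

    def test_lexicographic_order(self):
        combos = enumerate_combinations(3)
        assert [tuple(c.zeta) for c in combos] == [
            (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1),
        ]

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            enumerate_combinations(0)

    def test_largest_scale_must_be_on(self):
        with pytest.raises(ValueError):
            ZetaCombination(np.array([0.0, 1.0]))


class TestConcatFeatures:
    def test_width_is_m_plus_d(self, rng):
        q = rng.normal(size=(20, 4))
        z = SpatialEmbedding(rng.normal(size=(20, 6)))
        assert concat_features(q, z).shape == (20, 10)

    def test_scaled_columns_standardized(self, rng):
        f = concat_features(rng.normal(size=(30, 3)), rng.normal(size=(30, 5)) * 7)
        assert np.all(np.abs(f.mean(axis=0)) <= 1e-9)
        np.testing.assert_allclose(f.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_dropped(self, rng):
        z = rng.normal(size=(20, 3))
        z[:, 1] = 4.0
        f = concat_features(rng.normal(size=(20, 2)), z)
        assert f.shape == (20, 4)

    def test_row_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            concat_features(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))


class TestClusterFeatures:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = np.repeat([0, 1, 2], 15)
        return centers[labels] + rng.normal(0, 0.5, (45, 2)), labels

    def test_gmm_separated_blobs_exact(self):
        f, labels = self._blobs()
        got = cluster_features(f, 3, "gaussian_mixture", seed=0)
        assert ari(got, labels) == pytest.approx(1.0)

    def test_leiden_separated_blobs_exact(self):
        # blobs of 20 so the k=15 graph stays within blobs
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = np.repeat([0, 1, 2], 20)
        f = centers[labels] + rng.normal(0, 0.5, (60, 2))
        got = cluster_features(f, 3, "leiden_graph", seed=0)
        assert ari(got, labels) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["gaussian_mixture", "leiden_graph"])
    def test_deterministic_given_seed(self, method):
        f, _ = self._blobs()
        a = cluster_features(f, 3, method, seed=3)
        b = cluster_features(f, 3, method, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_n_clusters_equal_n_all_singletons(self, rng):
        f = rng.normal(size=(8, 2))
        got = cluster_features(f, 8, "gaussian_mixture", seed=0)
        assert len(np.unique(got.labels)) == 8

    def test_leiden_hits_requested_count(self, rng):
        # the 45-point fixture's k=15 graph is connected, so the resolution
        # bisection can reach counts on both sides of the natural 3
        f, _ = self._blobs()
        for k in (2, 4):
            got = cluster_features(f, k, "leiden_graph", seed=0)
            assert len(np.unique(got.labels)) == k
        # a count the modularity landscape skips: nearest achieved is returned
        got = cluster_features(f, 5, "leiden_graph", seed=0)
        assert abs(len(np.unique(got.labels)) - 5) <= 1

    def test_impossible_n_clusters(self, rng):
        with pytest.raises(ValueError):
            cluster_features(rng.normal(size=(5, 2)), 6, "gaussian_mixture")


class TestCoassociation:
    def test_single_labeling(self):
        c = coassociation([np.array([0, 0, 1])])
        np.testing.assert_array_equal(c, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_unanimity_is_binary(self):
        lab = np.array([0, 1, 0, 2])
        c1 = coassociation([lab])
        c2 = coassociation([lab, lab.copy()])
        np.testing.assert_array_equal(c1, c2)
        assert set(np.unique(c2)) <= {0.0, 1.0}

    def test_matches_brute_force_pair_counting(self, rng):
        labelings = [rng.integers(0, 4, 12) for _ in range(5)]
        np.testing.assert_array_equal(
            coassociation(labelings), brute_force_coassociation(labelings)
        )

    def test_duplicate_labeling_mixture_property(self, rng):
        labelings = [rng.integers(0, 3, 10) for _ in range(4)]
        c = coassociation(labelings)
        c_dup = coassociation([labelings[0]])
        c_new = coassociation(labelings + [labelings[0]])
        np.testing.assert_allclose(c_new, (4 * c + c_dup) / 5, atol=1e-12)

    def test_entries_in_unit_interval(self, rng):
        labelings = [rng.integers(0, 5, 20) for _ in range(7)]
        c = coassociation(labelings)
        assert c.min() >= 0.0 and c.max() <= 1.0
        np.testing.assert_array_equal(np.diag(c), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            coassociation([np.array([0, 1]), np.array([0, 1, 2])])


class TestConsensus:
    def test_unanimous_recovery(self):
        lab = np.array([0, 0, 1, 1, 2, 2, 2])
        c = coassociation([lab, lab, lab])
        got = consensus_cluster(c, 3)
        assert ari(got, lab) == pytest.approx(1.0)

    def test_majority_beats_random_minority(self):
        rng = np.random.default_rng(0)
        rng1 = np.random.default_rng(1)
        majority = np.repeat([0, 1, 2], 10)
        labelings = [majority] * 8 + [rng.integers(0, 3, 30), rng1.integers(0, 3, 30)]
        got = consensus_cluster(coassociation(labelings), 3)
        assert ari(got, majority) == pytest.approx(1.0)

    def test_identity_coassoc_all_singletons(self):
        got = consensus_cluster(np.eye(6), 6)
        assert len(np.unique(got.labels)) == 6

    def test_permutation_invariance(self, rng):
        # structured C (clear majority) so linkage has no distance ties,
        # which would make merge order depend on input order
        majority = np.repeat([0, 1, 2], 5)
        labelings = [majority] * 6 + [rng.integers(0, 3, 15) for _ in range(3)]
        c = coassociation(labelings)
        got = consensus_cluster(c, 3)
        perm = rng.permutation(15)
        got_p = consensus_cluster(c[np.ix_(perm, perm)], 3)
        assert ari(got.labels[perm], got_p) == pytest.approx(1.0)

    def test_too_many_clusters(self):
        with pytest.raises(ValueError):
            consensus_cluster(np.eye(3), 4)


class TestMetrics:
    def test_identical_labelings(self):
        a = np.array([0, 1, 1, 2])
        assert nmi(a, a) == pytest.approx(1.0)
        assert ari(a, a) == pytest.approx(1.0)

    def test_constant_labeling_nmi_zero(self):
        assert nmi(np.zeros(6, dtype=int), np.array([0, 1, 2, 0, 1, 2])) == 0.0

    def test_relabel_invariance(self):
        assert ari(np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0])) == pytest.approx(
            1.0
        )

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, 2000)
        b = rng.integers(0, 5, 2000)
        assert abs(ari(a, b)) <= 0.1

    def test_nmi_matches_contingency_formula(self):
        a = np.array([0, 0, 1, 1, 1, 2])
        b = np.array([0, 1, 1, 1, 2, 2])
        assert nmi(a, b) == pytest.approx(contingency_nmi(a, b), abs=1e-10)

    def test_metrics_match_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert nmi(a, b) == pytest.approx(contingency_nmi(a, b), abs=1e-9)
            assert ari(a, b) == pytest.approx(pair_counting_ari(a, b), abs=1e-9)

    def test_label_vector_inputs_accepted(self):
        a = LabelVector(np.array(["x", "y", "x"]))
        b = LabelVector(np.array([5, 9, 5]))
        assert ari(a, b) == pytest.approx(1.0)
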