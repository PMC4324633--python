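"""Cosine similarity, geographic distances, nMDS, ANOSIM, Mantel."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata

import motupipe as mp


def sym(rng, n, scale=1.0):
    v = rng.random((n, n)) * scale
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return v


class TestCosine:
    def test_identical_vectors_give_one(self):
        cm = pd.DataFrame([[3, 1, 0], [3, 1, 0]], index=["a", "b"])
        s = mp.cosine_similarity_matrix(cm)
        assert s["a", "b"] == pytest.approx(1.0)

    def test_disjoint_motu_sets_give_zero(self):
        cm = pd.DataFrame([[2, 0, 1, 0], [0, 3, 0, 5]], index=["a", "b"])
        s = mp.cosine_similarity_matrix(cm)
        assert s["a", "b"] == 0.0

    def test_hand_dot_product(self):
        cm = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        s = mp.cosine_similarity_matrix(cm)
        assert s["a", "b"] == pytest.approx(0.5)

    def test_zero_row_is_error(self):
        cm = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            mp.cosine_similarity_matrix(cm)

    def test_bounds_on_random_counts(self, rng):
        cm = pd.DataFrame(
            rng.integers(0, 5, size=(6, 30)) , index=[f"s{i}" for i in range(6)]
        )
        cm.iloc[:, 0] = 1  # no zero rows
        s = mp.cosine_similarity_matrix(cm)
        assert np.all(s.values >= 0) and np.all(s.values <= 1)


class TestGeographic:
    def test_identical_coordinates(self):
        st = [
            mp.StationRecord("a", "german", 10, -110, 4000),
            mp.StationRecord("b", "german", 10, -110, 4000),
        ]
        assert mp.geographic_distance_matrix(st)["a", "b"] == 0.0

    def test_three_four_five(self):
        st = [
            mp.StationRecord("a", "german", 0, 0.0001, 4000),
            mp.StationRecord("b", "german", 3, 4.0001, 4000),
        ]
        d = mp.geographic_distance_matrix(st, mode="euclidean_degrees")
        assert d["a", "b"] == pytest.approx(5.0)

    def test_area_centers_about_1300_km_apart(self):
        cfg = mp.SimConfig()
        st = [
            mp.StationRecord("g", "german", *cfg.german_center, 4200),
            mp.StationRecord("f", "french", *cfg.french_center, 5000),
        ]
        d = mp.geographic_distance_matrix(st, mode="haversine_km")
        assert d["g", "f"] == pytest.approx(1300, rel=0.15)


class TestNmds:
    def test_equilateral_triangle_zero_stress(self):
        dm = mp.DistanceMatrix(list("abc"), sym(np.random.default_rng(0), 3) * 0 + (1 - np.eye(3)), "d")
        res = mp.nmds(dm, k=2, n_restarts=8, seed=0)
        assert res.stress < 1e-3

    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = mp.DistanceMatrix([f"s{i}" for i in range(8)], d, "d")
        res = mp.nmds(dm, k=2, n_restarts=16, seed=1)
        assert res.stress < 0.01
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)

    def test_high_dimensional_distances_strain(self, rng):
        pts = rng.random((10, 9))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = mp.DistanceMatrix([f"s{i}" for i in range(10)], d, "d")
        res = mp.nmds(dm, k=2, n_restarts=4, seed=0)
        assert res.stress > 0.01

    def test_k_too_large_rejected(self):
        dm = mp.DistanceMatrix(list("abc"), 1 - np.eye(3), "d")
        with pytest.raises(ValueError, match="k="):
            mp.nmds(dm, k=3)


class TestAnosim:
    def test_complete_separation_r_is_one(self):
        # within-pairs all smaller than between-pairs
        v = np.array(
            [
                [0, 1, 9, 9],
                [1, 0, 9, 9],
                [9, 9, 0, 2],
                [9, 9, 2, 0],
            ],
            dtype=float,
        )
        dm = mp.DistanceMatrix(list("abcd"), v, "d")
        res = mp.anosim(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, 99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio_statistic(self, rng):
        import skbio.stats.distance as sksd

        n = 8
        v = sym(rng, n)
        labels = [f"s{i}" for i in range(n)]
        groups = {l: ("g1" if i < 4 else "g2") for i, l in enumerate(labels)}
        dm = mp.DistanceMatrix(labels, v, "d")
        ours = mp.anosim(dm, groups, 9, seed=0).statistic
        ref = sksd.anosim(
            dm.to_skbio(),
            grouping=[groups[l] for l in labels],
            permutations=9,
        )["test statistic"]
        assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_exhaustive_p_matches_brute_force(self, rng):
        n = 5
        v = sym(rng, n)
        labels = [f"s{i}" for i in range(n)]
        groups = {l: ("g1" if i < 2 else "g2") for i, l in enumerate(labels)}
        dm = mp.DistanceMatrix(labels, v, "d")
        res = mp.anosim(dm, groups, exhaustive=True)

        # oracle: independent R recomputation over all label permutations
        def r_stat(perm_labels):
            iu = np.triu_indices(n, k=1)
            ranks = rankdata(v[iu])
            same = np.array(
                [perm_labels[i] == perm_labels[j] for i, j in zip(*iu)]
            )
            m = n * (n - 1) / 2
            return (ranks[~same].mean() - ranks[same].mean()) / (m / 2)

        base = [groups[l] for l in labels]
        obs = r_stat(base)
        hits = sum(
            1
            for order in itertools.permutations(range(n))
            if r_stat([base[i] for i in order]) >= obs - 1e-12
        )
        assert res.p_value == pytest.approx(hits / math.factorial(n))
        assert res.statistic == pytest.approx(obs)

    def test_null_r_near_zero(self, rng):
        n = 10
        stats = []
        for _ in range(60):
            v = sym(rng, n)
            labels = [f"s{i}" for i in range(n)]
            groups = {l: ("g1" if i < 5 else "g2") for i, l in enumerate(labels)}
            dm = mp.DistanceMatrix(labels, v, "d")
            stats.append(mp.anosim(dm, groups, 49, seed=0).statistic)
        assert abs(np.mean(stats)) < 0.1

    def test_singleton_group_rejected(self):
        dm = mp.DistanceMatrix(list("abc"), 1 - np.eye(3), "d")
        with pytest.raises(ValueError, match="fewer than 2"):
            mp.anosim(dm, {"a": "g1", "b": "g2", "c": "g2"})


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        v = sym(rng, 6)
        dm = mp.DistanceMatrix([f"s{i}" for i in range(6)], v, "d")
        res = mp.mantel(dm, dm, 99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_is_pearson_on_triangles(self, rng):
        a, b = sym(rng, 7), sym(rng, 7)
        labels = [f"s{i}" for i in range(7)]
        m1 = mp.DistanceMatrix(labels, a, "d")
        m2 = mp.DistanceMatrix(labels, b, "d")
        iu = np.triu_indices(7, k=1)
        assert mp.mantel(m1, m2, 9, seed=0).statistic == pytest.approx(
            pearsonr(a[iu], b[iu]).statistic
        )

    def test_exhaustive_p_matches_brute_force(self, rng):
        n = 5
        a, b = sym(rng, n), sym(rng, n)
        labels = [f"s{i}" for i in range(n)]
        m1 = mp.DistanceMatrix(labels, a, "d")
        m2 = mp.DistanceMatrix(labels, b, "d")
        res = mp.mantel(m1, m2, exhaustive=True, tail="greater")
        iu = np.triu_indices(n, k=1)
        obs = pearsonr(a[iu], b[iu]).statistic
        hits = 0
        for order in itertools.permutations(range(n)):
            p = np.array(order)
            r = pearsonr(a[iu], b[np.ix_(p, p)][iu]).statistic
            if r >= obs - 1e-12:
                hits += 1
        assert res.n_permutations == 120
        assert res.p_value == pytest.approx(hits / 120)

    def test_label_mismatch_and_reorder(self, rng):
        v = sym(rng, 5)
        labels = [f"s{i}" for i in range(5)]
        m1 = mp.DistanceMatrix(labels, v, "d")
        m2 = mp.DistanceMatrix(labels[::-1], v[::-1, ::-1], "d")
        assert mp.mantel(m1, m2, 9, seed=0).statistic == pytest.approx(1.0)
        m3 = mp.DistanceMatrix(["x"] + labels[1:], v, "d")
        with pytest.raises(ValueError, match="labels"):
            mp.mantel(m1, m3, 9)

    def test_zero_variance_rejected(self):
        dm1 = mp.DistanceMatrix(list("abcd"), 1 - np.eye(4), "d")
        rng = np.random.default_rng(3)
        dm2 = mp.DistanceMatrix(list("abcd"), sym(rng, 4), "d")
        with pytest.raises(ValueError, match="variance"):
            mp.mantel(dm2, dm1, 9)

    def test_seeded_reproducibility(self, rng):
        a, b = sym(rng, 8), sym(rng, 8)
        labels = [f"s{i}" for i in range(8)]
        m1, m2 = mp.DistanceMatrix(labels, a, "d"), mp.DistanceMatrix(labels, b, "d")
        r1 = mp.mantel(m1, m2, 999, seed=5)
        r2 = mp.mantel(m1, m2, 999, seed=5)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)
        r3 = mp.mantel(m1, m2, 999, seed=6)
        assert r3.statistic == r1.statistic  # statistic is permutation-free
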