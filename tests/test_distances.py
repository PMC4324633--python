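"""Alignment, identity, p-/K2P distances, matrices, group means."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motupipe as mp
from motupipe.distances import AlignedPair, SiteCounts, Scoring, site_counts

from conftest import mutate


def gotoh_score(a: str, b: str, sc: Scoring = Scoring()) -> float:
    """Independent quadratic affine-gap DP (oracle for the alignment score).

    Gap of length L costs open + (L-1)*extend, matching the production
    aligner's convention.
    """
    NEG = -1e18
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = sc.gap_open + (i - 1) * sc.gap_extend
    for j in range(1, m + 1):
        Y[0][j] = sc.gap_open + (j - 1) * sc.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + sc.gap_open,
                X[i - 1][j] + sc.gap_extend,
                Y[i - 1][j] + sc.gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + sc.gap_open,
                Y[i][j - 1] + sc.gap_extend,
                X[i][j - 1] + sc.gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignPair:
    def test_identical(self):
        pair = mp.align_pair("ACGT", "ACGT")
        assert len(pair.a) == 4 and pair.overlap == 4

    def test_terminal_gap(self):
        pair = mp.align_pair("ACGT", "ACG")
        assert len(pair.a) == 4
        assert (pair.a + pair.b).count("-") == 1
        assert pair.overlap == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mp.align_pair("", "ACGT")

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = mutate(a, int(rng.integers(0, 20)), rng)
        # also delete a random chunk so gaps are exercised
        if seed % 2:
            cut = int(rng.integers(0, 90))
            b = b[:cut] + b[cut + int(rng.integers(1, 8)):]
        pair = mp.align_pair(a, b)
        assert pair.score == pytest.approx(gotoh_score(a, b))


class TestIdentity:
    def test_identical_is_one(self):
        pair = AlignedPair("A" * 650, "A" * 650)
        assert mp.pairwise_identity(pair) == (1.0, 650)

    def test_constructed_97_of_100(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = mutate(a, 3, rng)
        ident, overlap = mp.pairwise_identity(AlignedPair(a, b))
        assert ident == pytest.approx(0.97) and overlap == 100

    def test_two_percent_substitutions(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=650))
        b = mutate(a, 13, rng)
        ident, _ = mp.pairwise_identity(mp.align_pair(a, b))
        assert ident == pytest.approx(1 - 13 / 650)

    def test_shorter_sequence_denominator(self):
        # 3 identical columns over shorter length 3 -> identity 1
        pair = AlignedPair("ACGT", "ACG-")
        ident, overlap = mp.pairwise_identity(pair)
        assert ident == 1.0 and overlap == 3

    def test_zero_overlap_flagged(self):
        pair = AlignedPair("AC--", "--GT")
        ident, overlap = mp.pairwise_identity(pair)
        assert math.isnan(ident) and overlap == 0

    def test_ambiguity_never_matches(self):
        pair = AlignedPair("ANNT", "ANNT")
        ident, _ = mp.pairwise_identity(pair)
        assert ident == 1.0  # 2 matches / 2 unambiguous of shorter


class TestDistances:
    def test_p_distance_trivial(self):
        assert mp.p_distance(AlignedPair("ACGT", "ACGT")) == 0.0
        a = "A" * 500
        b = "G" * 10 + "A" * 490
        assert mp.p_distance(AlignedPair(a, b)) == pytest.approx(0.02)

    def test_k2p_closed_form(self):
        assert mp.k2p_distance(SiteCounts(100, 0, 0)) == 0.0
        # P=0.1, Q=0.05 evaluated by hand from the closed form
        d = mp.k2p_distance(SiteCounts(100, 10, 5))
        assert d == pytest.approx(0.17018, abs=1e-5)

    def test_k2p_saturation_sentinel(self):
        assert math.isnan(mp.k2p_distance(SiteCounts(100, 50, 10)))

    def test_k2p_close_to_p_at_small_distance(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=1000))
        b = mutate(a, 20, rng)  # p = 0.02
        pair = AlignedPair(a, b)
        assert abs(mp.k2p_from_pair(pair) - mp.p_distance(pair)) < 0.005

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(200, 2000), st.integers(0, 60), st.integers(0, 60))
    def test_k2p_dominates_p(self, n, ts, tv):
        c = SiteCounts(n, ts, tv)
        d = mp.k2p_distance(c)
        if not math.isnan(d):
            assert d >= (ts + tv) / n - 1e-12


class TestDistanceMatrix:
    def test_two_identical_records(self):
        recs = [mp.SequenceRecord(id=i, residues="ACGT" * 120) for i in "ab"]
        dm = mp.build_distance_matrix(recs, metric="p")
        assert np.allclose(dm.values, 0.0)

    def test_symmetry_and_diagonal_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            mp.DistanceMatrix(["a", "b"], [[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            mp.DistanceMatrix(["a", "b"], [[1, 1], [1, 0]])

    @pytest.mark.parametrize("metric", ["p", "k2p", "identity_complement"])
    def test_vectorized_path_matches_per_pair_oracle(self, metric, rng):
        anc = mp.random_coding_ancestor(400, rng)
        recs = [
            mp.SequenceRecord(
                id=f"s{i}", residues=mp.evolve_sequence(anc, 0.08, 4.0, rng)
            )
            for i in range(20)
        ]
        dm = mp.build_distance_matrix(recs, metric=metric)
        fn = {
            "p": mp.p_distance,
            "k2p": mp.k2p_from_pair,
            "identity_complement": lambda p: 1 - mp.pairwise_identity(p)[0],
        }[metric]
        for i in range(20):
            for j in range(i + 1, 20):
                expected = fn(AlignedPair(recs[i].residues, recs[j].residues))
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)

    def test_msa_mode(self):
        msa = {"a": "AC-GT", "b": "ACTGT", "c": "AC-GA"}
        recs = [mp.SequenceRecord(id=i, residues=msa[i]) for i in "abc"]
        dm = mp.build_distance_matrix(recs, metric="p", msa=msa)
        assert dm["a", "c"] == pytest.approx(0.25)  # 1 mismatch over 4 sites

    def test_tsv_round_trip(self, tmp_path, rng):
        vals = rng.random((4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        dm = mp.DistanceMatrix(list("abcd"), vals, "p")
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        back = mp.DistanceMatrix.from_tsv(path, "p")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)


class TestGroupMeans:
    def test_identical_group_is_zero(self):
        recs = [mp.SequenceRecord(id=f"s{i}", residues="ACGT" * 120) for i in range(3)]
        dm = mp.build_distance_matrix(recs, metric="k2p")
        out = mp.group_mean_distances(dm, {r.id: "g" for r in recs})
        assert out.loc["g", "g"] == 0.0

    def test_between_mean_in_percent(self):
        # all cross-pairs at distance 0.355 -> 35.5% between-group mean
        vals = np.array(
            [
                [0.0, 0.01, 0.355, 0.355],
                [0.01, 0.0, 0.355, 0.355],
                [0.355, 0.355, 0.0, 0.02],
                [0.355, 0.355, 0.02, 0.0],
            ]
        )
        dm = mp.DistanceMatrix(["a1", "a2", "b1", "b2"], vals, "k2p")
        out = mp.group_mean_distances(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert out.loc["A", "B"] == pytest.approx(35.5)
        assert out.loc["A", "A"] == pytest.approx(1.0)

    def test_singleton_group_blank(self):
        vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        dm = mp.DistanceMatrix(list("abc"), vals, "p")
        out = mp.group_mean_distances(dm, {"a": "X", "b": "X", "c": "Y"})
        assert math.isnan(out.loc["Y", "Y"])

    def test_random_labels_match_brute_force(self, rng):
        n = 12
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        labels = [f"s{i}" for i in range(n)]
        dm = mp.DistanceMatrix(labels, vals, "p")
        assign = {l: rng.choice(["u", "v", "w"]) for l in labels}
        out = mp.group_mean_distances(dm, assign)
        for g in "uvw":
            for h in "uvw":
                pairs = [
                    vals[i, j]
                    for i in range(n)
                    for j in range(i + 1, n)
                    if {assign[labels[i]], assign[labels[j]]} == ({g, h} if g != h else {g})
                ]
                if pairs:
                    assert out.loc[g, h] == pytest.approx(100 * np.mean(pairs))


def test_k80_evolution_recovers_k2p_distance(rng):
    # quick parameter-recovery check (full calibration in the acceptance suite)
    anc = mp.random_coding_ancestor(650, rng)
    d_hat = [
        mp.k2p_from_pair(
            AlignedPair(anc, mp.evolve_sequence(anc, 0.1, 4.0, rng))
        )
        for _ in range(100)
    ]
    se = np.std(d_hat, ddof=1) / np.sqrt(len(d_hat))
    assert abs(np.mean(d_hat) - 0.1) < 3 * se + 1e-4
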