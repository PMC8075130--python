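"""FST, PhiST/AMOVA, pairwise distances, NJ tree."""

import numpy as np
import pytest

from mitoscan.io_and_matrix import AlignmentError, MitoSequence
from mitoscan.popgen_structure import (
    AmovaError,
    DistanceMatrix,
    UndefinedFstError,
    haplogroup_fst,
    nj_tree_newick,
    pairwise_differences,
    phi_st,
)


def amova_phi_oracle(d, labels):
    """Loop-based textbook AMOVA on squared distances (independent of the
    vectorized implementation)."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    groups = sorted(set(labels))
    d2 = d**2
    ssd_total = sum(d2[i, j] for i in range(n) for j in range(n)) / (2 * n)
    ssd_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ssd_within += sum(d2[i, j] for i in idx for j in idx) / (2 * len(idx))
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (len(groups) - 1)
    sigma_w = ssd_within / (n - len(groups))
    sizes = [labels.count(g) for g in groups]
    n_c = (n - sum(s**2 for s in sizes) / n) / (len(groups) - 1)
    sigma_a = (ms_among - sigma_w) / n_c
    return sigma_a / (sigma_a + sigma_w)


class TestHaplogroupFst:
    def test_identical_distributions_zero(self):
        res = haplogroup_fst(
            {"F": {"H": 10, "L3": 5}, "NF": {"H": 20, "L3": 10}},
            n_permutations=99, seed=0,
        )
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_fixed_groups_maximal(self):
        res = haplogroup_fst(
            {"F": {"H": 10}, "NF": {"L3": 10}}, n_permutations=99, seed=0
        )
        assert res.estimate == pytest.approx(1.0)

    def test_toy_counts_near_zero_with_arithmetic_oracle(self):
        """F:{H:20,L3:9} vs NF:{H:40,L3:19} via direct H_T/H_S arithmetic."""
        counts = {"F": {"H": 20, "L3": 9}, "NF": {"H": 40, "L3": 19}}
        p_f = np.array([20 / 29, 9 / 29])
        p_n = np.array([40 / 59, 19 / 59])
        w = np.array([29 / 88, 59 / 88])
        pooled = w[0] * p_f + w[1] * p_n
        h_t = 1 - np.sum(pooled**2)
        h_s = w[0] * (1 - np.sum(p_f**2)) + w[1] * (1 - np.sum(p_n**2))
        expected = (h_t - h_s) / h_t
        res = haplogroup_fst(counts, n_permutations=9999, seed=2)
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.estimate < 0.001
        assert res.p_value > 0.3

    def test_single_haplogroup_undefined(self):
        with pytest.raises(UndefinedFstError):
            haplogroup_fst({"F": {"H": 10}, "NF": {"H": 20}})

    def test_permutation_p_reproducible(self):
        counts = {"F": {"H": 12, "L3": 17}, "NF": {"H": 30, "L3": 29}}
        p1 = haplogroup_fst(counts, n_permutations=499, seed=7).p_value
        p2 = haplogroup_fst(counts, n_permutations=499, seed=7).p_value
        assert p1 == p2


class TestPairwiseDifferences:
    def mk(self, seqs):
        return [MitoSequence(f"s{i}", b, "F") for i, b in enumerate(seqs)]

    def test_identical_and_single_diff(self):
        dm = pairwise_differences(self.mk(["ACGT", "ACGT", "ACGA"]))
        assert dm.d[0, 1] == 0
        assert dm.d[0, 2] == 1
        assert np.allclose(dm.d, dm.d.T)

    def test_ambiguous_positions_skipped_pairwise(self):
        dm = pairwise_differences(self.mk(["ANGT", "ACCT"]))
        assert dm.d[0, 1] == 1  # N column skipped, one real mismatch

    def test_gap_and_iupac_skipped(self):
        dm = pairwise_differences(self.mk(["A-RT", "ACGT"]))
        assert dm.d[0, 1] == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            pairwise_differences(self.mk(["ACGT", "ACG"]))


class TestPhiSt:
    def test_perfect_separation(self):
        d = np.full((6, 6), 2.0)
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids=[f"s{i}" for i in range(6)], d=d)
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = phi_st(dm, groups, n_permutations=99, seed=0)
        assert res.estimate == pytest.approx(1.0)

    def test_matches_loop_oracle_on_hand_matrix(self):
        d = np.array(
            [
                [0, 1, 2, 5, 6, 5],
                [1, 0, 1, 4, 5, 6],
                [2, 1, 0, 5, 4, 5],
                [5, 4, 5, 0, 2, 1],
                [6, 5, 4, 2, 0, 1],
                [5, 6, 5, 1, 1, 0],
            ],
            dtype=float,
        )
        ids = [f"s{i}" for i in range(6)]
        labels = ["A", "A", "A", "B", "B", "B"]
        dm = DistanceMatrix(ids=ids, d=d)
        res = phi_st(dm, dict(zip(ids, labels)), n_permutations=99, seed=0)
        assert res.estimate == pytest.approx(amova_phi_oracle(d, labels), abs=1e-12)

    def test_unequal_group_sizes_match_oracle(self, rng):
        n = 9
        d = rng.integers(1, 10, size=(n, n)).astype(float)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"s{i}" for i in range(n)]
        labels = ["A"] * 4 + ["B"] * 5
        dm = DistanceMatrix(ids=ids, d=d)
        res = phi_st(dm, dict(zip(ids, labels)), n_permutations=99, seed=0)
        assert res.estimate == pytest.approx(amova_phi_oracle(d, labels), abs=1e-12)

    def test_null_labels_give_small_mean_estimate(self, rng):
        """Exchangeable sequences: mean estimate near 0, p well above 0.05
    on average."""
        ests, ps = [], []
        for rep in range(60):
            d = rng.integers(1, 8, size=(10, 10)).astype(float)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            ids = [f"s{i}" for i in range(10)]
            labels = list(rng.permutation(["A"] * 5 + ["B"] * 5))
            res = phi_st(
                DistanceMatrix(ids=ids, d=d), dict(zip(ids, labels)),
                n_permutations=199, seed=int(rng.integers(2**31)),
            )
            ests.append(res.estimate)
            ps.append(res.p_value)
        assert abs(np.mean(ests)) < 0.05
        assert 0.3 < np.mean(ps) < 0.7

    def test_group_of_one_raises(self):
        d = np.zeros((3, 3))
        dm = DistanceMatrix(ids=["a", "b", "c"], d=d)
        with pytest.raises(AmovaError):
            phi_st(dm, {"a": "A", "b": "B", "c": "B"}, n_permutations=99)

    def test_permutation_reproducible(self):
        d = np.array(
            [[0, 1, 3, 4], [1, 0, 4, 3], [3, 4, 0, 1], [4, 3, 1, 0]], dtype=float
        )
        dm = DistanceMatrix(ids=list("abcd"), d=d)
        groups = {"a": "A", "b": "A", "c": "B", "d": "B"}
        assert (
            phi_st(dm, groups, 199, seed=3).p_value
            == phi_st(dm, groups, 199, seed=3).p_value
        )


class TestNjTree:
    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        newick = nj_tree_newick(DistanceMatrix(ids=["a", "b", "c"], d=d))
        import skbio

        tree = skbio.TreeNode.read([newick])
        tips = {t.name: t for t in tree.tips()}
        # branch lengths solve (d_ab + d_ac - d_bc)/2 etc.
        assert tips["a"].length == pytest.approx((2 + 3 - 4) / 2)
        assert tips["b"].length == pytest.approx((2 + 4 - 3) / 2)
        assert tips["c"].length == pytest.approx((3 + 4 - 2) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4):1) -> additive distances
        d = np.array(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            dtype=float,
        )
        newick = nj_tree_newick(DistanceMatrix(ids=list("abcd"), d=d))
        import skbio

        tree = skbio.TreeNode.read([newick])
        dm_back = tree.tip_tip_distances()
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                assert dm_back[x, y] == pytest.approx(d[i, j])

    def test_two_founder_cohort_bipartitions(self, small_cohort):
        _, reference, seqs, truth, tree = small_cohort
        sub = seqs[:8]
        dm = pairwise_differences(sub)
        import skbio

        t = skbio.TreeNode.read([nj_tree_newick(dm)])
        assert {x.name for x in t.tips()} == {s.sample_id for s in sub}

    def test_too_few_samples(self):
        dm = DistanceMatrix(ids=["a", "b"], d=np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(ValueError):
            nj_tree_newick(dm)
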