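import math

import numpy as np
import pytest

from treecheck.distance_nj import (
    DistanceMatrix,
    bootstrap_support,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    root_tree,
)
from treecheck.io_formats import Alignment, SequenceRecord

from _oracles import (
    k2p_site_counting,
    random_additive_tree,
    random_pair,
    related_sequences,
    tuple_tree_bipartitions,
)


def make_aln(seqs):
    return Alignment([SequenceRecord(k, v) for k, v in seqs.items()])


class TestK2PDistance:
    def test_identical_sequences(self):
        r = k2p_distance("ACGT" * 25, "ACGT" * 25)
        assert r.d == 0.0 and r.P == 0.0 and r.Q == 0.0 and r.n_sites == 100

    def test_worked_example(self):
        # 100 comparable sites, 10 transitions, 5 transversions
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p_distance(a, b)
        assert (r.P, r.Q) == (0.10, 0.05)
        assert r.d == pytest.approx(0.17018, abs=5e-6)

    def test_gap_column_excluded_by_pairwise_deletion(self):
        r = k2p_distance("ACGT-ACGT", "ACGTTACGT")
        assert r.d == 0.0 and r.n_sites == 8

    def test_ambiguity_codes_treated_as_missing(self):
        r = k2p_distance("ACGTN", "ACGTA")
        assert r.n_sites == 4 and r.d == 0.0

    def test_saturation_is_undefined(self):
        # P = 0.5, Q = 0: log argument is exactly 0
        a = "A" * 100
        b = "G" * 50 + "A" * 50
        with pytest.raises(ValueError, match="undefined"):
            k2p_distance(a, b)
        assert math.isnan(k2p_distance(a, b, on_undefined="nan").d)
        assert k2p_distance(a, b, on_undefined="cap", cap=3.0).d == 3.0

    def test_no_comparable_sites_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            k2p_distance("----", "AAAA")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            k2p_distance("ACGT", "ACG")

    def test_matches_site_counting_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = random_pair(rng)
            got = k2p_distance(a, b, on_undefined="nan")
            want_d, want_p, want_q, want_n = k2p_site_counting(a, b)
            assert got.n_sites == want_n
            assert got.P == pytest.approx(want_p, abs=1e-15)
            assert got.Q == pytest.approx(want_q, abs=1e-15)
            if math.isnan(want_d):
                assert math.isnan(got.d)
            else:
                assert got.d == pytest.approx(want_d, abs=1e-12)

    def test_matrix_agrees_with_pairwise_calls(self, rng):
        seqs = {f"s{i}": random_pair(rng)[0] for i in range(6)}
        aln = make_aln(seqs)
        dm = k2p_matrix(aln, on_undefined="nan")
        for i, a in enumerate(aln.ids):
            for j, b in enumerate(aln.ids):
                want = k2p_distance(
                    aln[a].residues, aln[b].residues, on_undefined="nan"
                ).d
                got = dm.d[i, j]
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        t = nj_tree(dm)
        lengths = {n.name: n.length for n in t.leaves()}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_four_taxon_additive_split(self):
        # AB = CD = 0.2, cross pairs 0.4: split AB|CD, internal branch 0.2
        d = np.full((4, 4), 0.4)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.2
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert t.bipartitions() == frozenset([frozenset("CD")])
        internal = [
            n
            for n in t.root.postorder()
            if not n.is_leaf() and n is not t.root
        ]
        assert len(internal) == 1
        assert internal[0].length == pytest.approx(0.2)

    def test_equal_distances_tie_break_is_deterministic(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        t1 = nj_tree(DistanceMatrix(list("ABCD"), d))
        t2 = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert t1.newick() == t2.newick()
        # smallest (i,j) pair joined first: A and B
        assert t1.bipartitions() == frozenset([frozenset("CD")])

    def test_undefined_entries_rejected(self):
        d = np.full((3, 3), np.nan)
        np.fill_diagonal(d, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(list("ABC"), d))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n_leaves", [5, 6, 7, 8])
    def test_recovers_random_additive_topologies(self, rng, n_leaves):
        for _ in range(25):
            labels, tree, D = random_additive_tree(rng, n_leaves)
            got = nj_tree(DistanceMatrix(labels, D))
            assert got.bipartitions() == tuple_tree_bipartitions(tree, labels)

    def test_agrees_with_independent_nj_implementation(self, rng):
        # cross-check against scikit-bio on a generic random matrix
        skbio = pytest.importorskip("skbio")
        labels, tree, D = random_additive_tree(rng, 7)
        noise = rng.uniform(0, 1e-3, D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0.0)
        ours = nj_tree(DistanceMatrix(labels, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        their_bips = set()
        full = frozenset(labels)
        anchor = min(full)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(full - side) < 2:
                continue
            their_bips.add(side if anchor not in side else full - side)
        assert ours.bipartitions() == frozenset(their_bips)


class TestRooting:
    def test_outgroup_becomes_child_of_root(self):
        t = nj_tree(
            DistanceMatrix(
                ["A", "B", "C", "OUT"],
                np.array(
                    [
                        [0, 0.1, 0.4, 0.8],
                        [0.1, 0, 0.4, 0.8],
                        [0.4, 0.4, 0, 0.8],
                        [0.8, 0.8, 0.8, 0],
                    ]
                ),
            )
        )
        rooted = root_tree(t, "OUT")
        assert rooted.rooted
        kids = rooted.root.children
        assert any(k.name == "OUT" for k in kids)
        ls = rooted.leafsets()
        assert frozenset(["A", "B", "C"]) in set(ls.values())

    def test_rooting_preserves_bipartitions(self, rng):
        labels, tree, D = random_additive_tree(rng, 8)
        t = nj_tree(DistanceMatrix(labels, D))
        rooted = root_tree(t, labels[3])
        assert rooted.bipartitions() == t.bipartitions()

    def test_rooting_on_missing_leaf_errors(self, two_family_tree):
        with pytest.raises(KeyError):
            root_tree(two_family_tree, "nope")


class TestBootstrap:
    def test_conflict_free_signal_gets_full_support(self, conflict_free_alignment):
        t = bootstrap_support(conflict_free_alignment, n_replicates=100, seed=11)
        sups = [n.support for n in t.root.postorder() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_bit_identical(self, rng):
        aln = make_aln(related_sequences(rng, 6))
        t1 = bootstrap_support(aln, n_replicates=40, seed=5)
        t2 = bootstrap_support(aln, n_replicates=40, seed=5)
        assert t1.newick() == t2.newick()

    def test_supports_within_range(self, rng):
        aln = make_aln(related_sequences(rng, 7))
        t = bootstrap_support(aln, n_replicates=30, seed=2)
        for n in t.root.postorder():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0

    def test_invariant_to_leaf_order_permutation(self, rng):
        seqs = related_sequences(rng, 6, length=200)
        fwd = bootstrap_support(make_aln(seqs), n_replicates=50, seed=9)
        rev = bootstrap_support(
            make_aln(dict(reversed(list(seqs.items())))), n_replicates=50, seed=9
        )

        def support_by_bip(tree):
            ls = tree.leafsets()
            full = frozenset(tree.leaf_names)
            anchor = min(full)
            out = {}
            for n in tree.root.postorder():
                if n.support is None:
                    continue
                side = ls[n]
                out[side if anchor not in side else full - side] = n.support
            return out

        assert support_by_bip(fwd) == support_by_bip(rev)

    def test_zero_replicates_rejected(self, conflict_free_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(conflict_free_alignment, n_replicates=0, seed=1)
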