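import pytest
from hypothesis import given, strategies as st

from treecheck.clade_resolution import (
    Status,
    classify_families,
    classify_family,
    compare_analyses,
    resolution_summary,
)
from treecheck.io_formats import read_tree

from _oracles import (
    clade_bitmasks,
    oracle_classify_two_families,
    rooted_topologies,
    tuple_tree_newick,
)


class TestClassifyFamily:
    def test_mono_family_with_support(self, two_family_tree, two_family_taxonomy):
        r = classify_family(two_family_tree, "Fam1", two_family_taxonomy)
        assert r.status is Status.MONO
        assert r.support == 85.0
        assert r.fully_resolved
        assert r.intruder_ids == ()

    def test_paraphyletic_grade_with_whole_nested_family(
        self, grade_tree, grade_taxonomy
    ):
        r1 = classify_family(grade_tree, "Fam1", grade_taxonomy)
        assert r1.status is Status.PARA
        assert set(r1.intruder_ids) == {"f2a", "f2b"}
        r2 = classify_family(grade_tree, "Fam2", grade_taxonomy)
        assert r2.status is Status.MONO

    def test_interleaved_families_are_polyphyletic(self):
        t = read_tree("((f1a,f2a),(f1b,f2b));")
        tax = {"f1a": "F1", "f1b": "F1", "f2a": "F2", "f2b": "F2"}
        assert classify_family(t, "F1", tax).status is Status.POLY

    def test_missing_support_annotation_is_not_fully_resolved(self):
        t = read_tree("((f1a,f1b),(f2a,f2b));")
        tax = {"f1a": "F1", "f1b": "F1", "f2a": "F2", "f2b": "F2"}
        r = classify_family(t, "F1", tax)
        assert r.status is Status.MONO
        assert r.support is None and not r.fully_resolved

    def test_singleton_family_not_evaluable(self, grade_tree):
        tax = {"f1a": "F1", "f1b": "F1", "f1c": "F1", "f2a": "F2", "f2b": "Fx"}
        r = classify_family(grade_tree, "Fx", tax)
        assert r.status is Status.NOT_EVALUABLE

    def test_unrooted_tree_rejected(self):
        t = read_tree("((a,b),(c,d),(e,f));")
        with pytest.raises(ValueError, match="rooted"):
            classify_family(t, "F", {"a": "F", "b": "F"})

    def test_alternative_rules(self):
        # grade with two separated single-leaf intruders from a family that is
        # NOT wholly contained: PARA only under the fraction rule
        t = read_tree("(((((f1a,x1),f1b),f1c),f1d),((x2,x3),f9));")
        tax = {
            "f1a": "F1",
            "f1b": "F1",
            "f1c": "F1",
            "f1d": "F1",
            "x1": "FX",
            "x2": "FX",
            "x3": "FX",
            "f9": "F9",
        }
        assert classify_family(t, "F1", tax).status is Status.POLY
        assert (
            classify_family(t, "F1", tax, rule="single-intruder-clade").status
            is Status.PARA
        )
        assert (
            classify_family(t, "F1", tax, rule="intruder-fraction").status
            is Status.PARA
        )

    def test_status_invariant_to_lengths_and_supports(self, grade_taxonomy):
        a = read_tree("(f1a:1,(f1b:1,(f1c:1,(f2a:1,f2b:1)95:1)80:1)99:1);")
        b = read_tree("(f1a:9,(f1b:0.1,(f1c:2,(f2a:1,f2b:5)5:4)10:3)20:8);")
        for fam in ("Fam1", "Fam2"):
            assert (
                classify_family(a, fam, grade_taxonomy).status
                is classify_family(b, fam, grade_taxonomy).status
            )

    def test_removing_intruders_restores_monophyly(self, grade_tree, grade_taxonomy):
        r = classify_family(grade_tree, "Fam1", grade_taxonomy)
        assert r.status is Status.PARA
        pruned = grade_tree.prune(r.intruder_ids)
        assert classify_family(pruned, "Fam1", grade_taxonomy).status is Status.MONO

    def test_matches_bruteforce_on_six_leaf_enumeration(self):
        # full enumeration at n=6 here; the n<=7 sweep runs in the acceptance suite
        _enumeration_check(6)


def _enumeration_check(n: int) -> None:
    labels = [f"L{i}" for i in range(n)]
    index = {lab: i for i, lab in enumerate(labels)}
    for tup in rooted_topologies(labels):
        tree = read_tree(tuple_tree_newick(tup) + ";")
        clades = clade_bitmasks(tup, index)
        for mask in range(1 << (n - 1)):  # L0 always in family A: halves the work
            fam_a = (mask << 1) | 1
            fam_b = ((1 << n) - 1) & ~fam_a
            tax = {
                lab: ("A" if fam_a >> i & 1 else "B") for lab, i in index.items()
            }
            present = [("A", fam_a)] + ([("B", fam_b)] if fam_b else [])
            got = {
                r.family: r
                for r in classify_families(
                    tree, tax, families=[f for f, _ in present]
                )
            }
            for fam, S in present:
                want_status, want_intruders = oracle_classify_two_families(
                    clades, fam_a, fam_b, S
                )
                r = got[fam]
                assert r.status.value == want_status, (
                    f"{tuple_tree_newick(tup)} fam={fam} mask={mask:b}"
                )
                got_mask = 0
                for leaf in r.intruder_ids:
                    got_mask |= 1 << index[leaf]
                assert got_mask == want_intruders


class TestResolutionSummary:
    def test_counts_on_constructed_tree(self):
        # 3 MONO >= 70, 1 MONO at 50, and two families interleaved into POLY
        t = read_tree(
            "(((a1,a2)90,(b1,b2)80),(((c1,c2)75,(d1,d2)50),((e1,x1)60,(e2,x2)65)));"
        )
        tax = {
            "a1": "A", "a2": "A", "b1": "B", "b2": "B",
            "c1": "C", "c2": "C", "d1": "D", "d2": "D",
            "e1": "E", "e2": "E", "x1": "X", "x2": "X",
        }
        _, counts = resolution_summary(t, tax)
        assert counts == {
            "n_mono_resolved": 3,
            "n_mono_unresolved": 1,
            "n_para": 0,
            "n_poly": 2,
        }

    def test_counts_sum_to_evaluable_families(self, grade_tree, grade_taxonomy):
        records, counts = resolution_summary(grade_tree, grade_taxonomy)
        evaluable = [r for r in records if r.status is not Status.NOT_EVALUABLE]
        assert sum(counts.values()) == len(evaluable)

    def test_invariant_to_leaf_order(self):
        t1 = read_tree("((a1,a2)90,((b1,b2)80,(c1,c2)40));")
        t2 = read_tree("(((c2,c1)40,(b2,b1)80),(a2,a1)90);")
        tax = {x: x[0].upper() for x in ["a1", "a2", "b1", "b2", "c1", "c2"]}
        assert resolution_summary(t1, tax)[1] == resolution_summary(t2, tax)[1]

    def test_outgroup_excluded(self):
        t = read_tree("(((a1,a2)90,(b1,b2)80),OUT);")
        tax = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "OUT": "Priapulida"}
        records, counts = resolution_summary(t, tax, outgroup="OUT")
        assert {r.family for r in records} == {"A", "B"}
        assert sum(counts.values()) == 2


class TestCompareAnalyses:
    def _rec(self, tree_str, tax):
        return resolution_summary(read_tree(tree_str), tax)[0]

    def test_poly_to_mono_fully_resolved_codes_mr(self):
        tax = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        before = self._rec("((a1,b1),(a2,b2));", tax)
        after = self._rec("((a1,a2)93,(b1,b2)95);", tax)
        deltas, _, _ = compare_analyses(before, after)
        d = {x.family: x for x in deltas}
        assert d["A"].codes == ("M", "R")
        assert d["A"].formatted == "+93 MR"

    def test_mono_support_drop_below_threshold_codes_u(self):
        tax = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        before = self._rec("((a1,a2)74,(b1,b2)90);", tax)
        after = self._rec("((a1,a2)69,(b1,b2)90);", tax)
        d = {x.family: x for x in compare_analyses(before, after)[0]}
        assert d["A"].codes == ("U",)
        assert d["A"].formatted == "-5 U"
        assert d["B"].formatted == "0"

    def test_both_non_mono_codes_dash(self):
        tax = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        before = self._rec("(a1,(a2,(a3,(b1,b2))));", tax)  # A paraphyletic
        after = self._rec("((a1,b1),(a2,(a3,b2)));", tax)  # A polyphyletic
        d = {x.family: x for x in compare_analyses(before, after)[0]}
        assert d["A"].codes == ("–",)
        assert d["A"].formatted == "–"

    def test_mono_to_non_mono_codes_p(self):
        tax = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        before = self._rec("((a1,a2)80,(b1,b2)90);", tax)
        after = self._rec("((a1,b1),(a2,b2));", tax)
        d = {x.family: x for x in compare_analyses(before, after)[0]}
        assert d["A"].codes == ("P",)
        assert d["A"].formatted == "-80 P"

    def test_families_absent_from_one_side_reported_separately(self):
        tax1 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        tax2 = {"a1": "A", "a2": "A", "x1": "X", "x2": "X"}
        before = self._rec("((a1,a2)80,(b1,b2)90);", tax1)
        after = self._rec("((a1,a2)85,(x1,x2)70);", tax2)
        deltas, only_from, only_to = compare_analyses(before, after)
        assert {d.family for d in deltas} == {"A"}
        assert only_from == ["B"]
        assert only_to == ["X"]


@given(st.integers(0, 2**11 - 2))
def test_classifier_agrees_with_oracle_on_random_labelings(mask):
    """Property form of the brute-force check on one fixed 12-leaf topology."""
    n = 12
    labels = [f"L{i}" for i in range(n)]
    # fixed caterpillar-with-cherries shape exercises nested clades
    tup = labels[0]
    for lab in labels[1:]:
        tup = (tup, lab) if int(lab[1:]) % 3 else (lab, tup)
    index = {lab: i for i, lab in enumerate(labels)}
    tree = read_tree(tuple_tree_newick(tup) + ";")
    clades = clade_bitmasks(tup, index)
    fam_a = (mask << 1) | 1
    fam_b = ((1 << n) - 1) & ~fam_a
    tax = {lab: ("A" if fam_a >> i & 1 else "B") for lab, i in index.items()}
    got = {r.family: r for r in classify_families(tree, tax, families=["A", "B"])}
    for fam, S in (("A", fam_a), ("B", fam_b)):
        want_status, _ = oracle_classify_two_families(clades, fam_a, fam_b, S)
        assert got[fam].status.value == want_status
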