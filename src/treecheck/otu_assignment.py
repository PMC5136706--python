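"""Rule-based assignment of anonymous query OTUs to family-level taxa.

An OTU placed on a combined (references + queries) rooted tree is assigned by:

* Rule 1 (``mono_clade``): the OTU falls *within* the clade spanned by the
  references of a family that is monophyletic once all queries are masked.
  The outcome is ``identified`` when that family clade's bootstrap support is
  >= tau, otherwise ``identified_low_support`` (the "identified*" outcome).
* Rule 2 (``para_grade``): the OTU falls within the highly supported grade of
  a paraphyletic family, outside every nested intruder clade, and inside a
  highly supported subclade containing only that family's references; then it
  is ``identified`` with the subclade's support.
* Otherwise the OTU is ``unidentified`` - never guessed.

Each OTU is evaluated with all other query leaves masked, so assignments are
independent of the query batch composition. Family resolution (MONO/PARA) is
always computed on the reference-only tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .clade_resolution import (
    DEFAULT_TAU,
    Status,
    _family_map,
    classify_families,
    intruder_clades,
    round_half_up,
)
from .tree import SupportTree

OUTCOMES = ("identified", "identified_low_support", "unidentified")


@dataclass
class AssignmentRecord:
    otu_id: str
    outcome: str
    family: str | None = None
    rule_used: str = "none"
    clade_support: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "unidentified" and self.family is not None:
            raise ValueError("unidentified OTUs carry no family")
        if self.outcome != "unidentified" and not self.family:
            raise ValueError("identified OTUs must carry a family")


class _ReferenceContext:
    """Query-masked view of the combined tree, shared across OTUs."""

    def __init__(self, tree, taxonomy, query_ids, tau, rule, outgroup):
        self.tau = tau
        self.fammap = _family_map(taxonomy)
        self.query_ids = set(query_ids)
        self.outgroup = {outgroup} if isinstance(outgroup, str) else set(outgroup)
        ref_leaves = [
            x
            for x in tree.leaf_names
            if x not in self.query_ids and x in self.fammap
        ]
        if not ref_leaves:
            raise ValueError("tree has no reference leaves")
        self.ref_tree = tree.prune(self.query_ids) if self.query_ids & set(
            tree.leaf_names
        ) else tree
        self.resolution = {
            r.family: r
            for r in classify_families(
                self.ref_tree, taxonomy, rule=rule, tau=tau, exclude=self.outgroup
            )
        }
        self.fam_leaves = {
            fam: frozenset(
                x for x in self.ref_tree.leaf_names
                if x not in self.outgroup and self.fammap.get(x) == fam
            )
            for fam in self.resolution
        }
        # grade (MRCA) support and intruder structure for paraphyletic families
        self.grade_support = {}
        self.intruder_sets: dict[str, list[frozenset[str]]] = {}
        for fam, leaves in self.fam_leaves.items():
            if self.resolution[fam].status is Status.PARA:
                self.grade_support[fam] = self.ref_tree.mrca(leaves).support
                self.intruder_sets[fam] = intruder_clades(
                    self.ref_tree, leaves, exclude=self.outgroup
                )


def _meets(tau: float, support: float | None) -> bool:
    return support is not None and round_half_up(support) >= tau


def assign_otu(
    tree: SupportTree,
    taxonomy,
    otu_id: str,
    query_ids: Iterable[str] = (),
    tau: float = DEFAULT_TAU,
    rule: str = "nested-whole-taxa",
    outgroup: Iterable[str] | str = (),
    _ctx: _ReferenceContext | None = None,
) -> AssignmentRecord:
    """Assign one OTU on a rooted combined tree.

    ``query_ids`` lists all query leaves (including ``otu_id``); the others
    are masked before placement is read.
    """
    if not tree.rooted:
        raise ValueError("assignment requires a rooted tree")
    if otu_id not in set(tree.leaf_names):
        raise KeyError(f"OTU {otu_id!r} is not a leaf of the tree")
    ctx = _ctx or _ReferenceContext(tree, taxonomy, query_ids, tau, rule, outgroup)

    others = (set(query_ids) | ctx.query_ids) - {otu_id}
    t1 = tree.prune(others & set(tree.leaf_names)) if others else tree
    ls1 = t1.leafsets()

    # Rule 1: OTU inside the span of a monophyletic family's references
    mono_hits = []
    for fam, rec in ctx.resolution.items():
        if rec.status is not Status.MONO:
            continue
        node = t1.mrca(ctx.fam_leaves[fam])
        if otu_id in ls1[node]:
            mono_hits.append((len(ls1[node]), fam, rec))
    if mono_hits:
        _, fam, rec = min(mono_hits)  # smallest containing family span
        if _meets(tau, rec.support):
            return AssignmentRecord(otu_id, "identified", fam, "mono_clade", rec.support)
        return AssignmentRecord(
            otu_id, "identified_low_support", fam, "mono_clade", rec.support
        )

    # Rule 2: paraphyletic grade. Walk up from the OTU through ancestors whose
    # references all belong to one family F; the placement counts as "inside a
    # supported F-only subclade" as soon as one such ancestor carries support
    # >= tau.
    parent = t1.parent_map()
    node = t1.find_leaf(otu_id)
    ref_names = set(t1.leaf_names) - {otu_id} - ctx.outgroup
    fam = None
    subclade = None
    while node in parent:
        node = parent[node]
        refs_here = (ls1[node] - {otu_id}) & ref_names
        if not refs_here:
            continue
        fams_here = {ctx.fammap[x] for x in refs_here if x in ctx.fammap}
        if len(fams_here) != 1 or (fam is not None and fams_here != {fam}):
            break
        fam = next(iter(fams_here))
        if _meets(tau, node.support):
            subclade = node
            break
    if fam is not None and subclade is not None:
        rec = ctx.resolution.get(fam)
        if rec is not None and rec.status is Status.PARA:
            grade_ok = _meets(tau, ctx.grade_support.get(fam))
            grade_node = t1.mrca(ctx.fam_leaves[fam])
            inside_grade = otu_id in ls1[grade_node]
            outside_intruders = all(
                otu_id not in ls1[t1.mrca(clade_ids)]
                for clade_ids in ctx.intruder_sets[fam]
            )
            if grade_ok and inside_grade and outside_intruders:
                return AssignmentRecord(
                    otu_id, "identified", fam, "para_grade", subclade.support
                )

    return AssignmentRecord(otu_id, "unidentified", None, "none", None)


def assignment_report(
    tree: SupportTree,
    taxonomy,
    otu_ids: Sequence[str],
    tau: float = DEFAULT_TAU,
    rule: str = "nested-whole-taxa",
    outgroup: Iterable[str] | str = (),
) -> tuple[list[AssignmentRecord], dict[str, int]]:
    """Assign every OTU (rows ordered by otu_id) and summarize outcomes."""
    ctx = _ReferenceContext(tree, taxonomy, otu_ids, tau, rule, outgroup)
    records = [
        assign_otu(tree, taxonomy, otu, otu_ids, tau, rule, outgroup, _ctx=ctx)
        for otu in sorted(otu_ids)
    ]
    counts = {k: 0 for k in OUTCOMES}
    for r in records:
        counts[r.outcome] += 1
    return records, counts


def to_frame(records: Sequence[AssignmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu_id": r.otu_id,
                "outcome": r.outcome,
                "family": r.family or "",
                "rule": r.rule_used,
                "clade_support": r.clade_support,
            }
            for r in records
        ]
    )
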