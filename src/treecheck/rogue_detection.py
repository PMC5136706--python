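"""Detection of problematic ("rogue") reference sequences.

A leaf is *misplaced* on one tree when it falls outside the largest
family-pure clade of its labeled family; a leaf misplaced consistently
(misplacement rate >= threshold, default 1.0) across analyses is a rogue -
a candidate misidentified or erroneous reference sequence whose removal
defines the "filtered" dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .clade_resolution import _family_map
from .tree import SupportTree


@dataclass
class MisplacementRecord:
    id: str
    family: str
    flags: dict[str, bool]  # analysis label -> misplaced on that tree
    misplacement_rate: float
    rogue: bool
    affected_families: tuple[str, ...] = ()
    tie_broken: bool = False


def _family_cores(sides, fam_leaves, excluded, tree, ls):
    """Per family: the largest family-pure unrooted side (the plurality core)
    and the members outside it (candidate strays).

    Size ties are broken first by neighborhood coherence - the number of
    family members inside the smallest clade properly containing the side -
    so a lone stray parked far away never outranks a member sitting next to
    its relatives; remaining ties go to the side holding the
    lexicographically smallest id (recorded).
    """
    from .clade_resolution import _mrca_from_leafsets

    full = frozenset(tree.leaf_names)
    parent_map = tree.parent_map()

    def vicinity(side: frozenset[str], members: frozenset[str]) -> int:
        node = _mrca_from_leafsets(tree.root, ls, side)
        parent = parent_map.get(node)
        span = ls[parent] if parent is not None else full
        return len(span & members)

    cores: dict[str, frozenset[str]] = {}
    candidates: set[str] = set()
    ties: set[str] = set()
    for fam, members in fam_leaves.items():
        pure = {s - excluded for s in sides}
        pure = [s for s in pure if s and s <= members]
        maximal = [s for s in pure if not any(s < t for t in pure)]
        best = max(len(s) for s in maximal)
        biggest = [s for s in maximal if len(s) == best]
        if len(biggest) > 1:
            ties.add(fam)
            best_vic = max(vicinity(s, members) for s in biggest)
            biggest = [s for s in biggest if vicinity(s, members) == best_vic]
        cores[fam] = min(biggest, key=min)  # lexicographic last resort
        candidates |= members - cores[fam]
    return cores, candidates, ties


def misplaced_leaves(
    tree: SupportTree,
    taxonomy,
    outgroup: Iterable[str] | str = (),
) -> tuple[dict[str, bool], dict]:
    """Per-leaf misplacement flags on one rooted tree.

    For each family the leaves are partitioned into maximal family-pure
    groups, read on the unrooted splits of the tree so a family forming a
    grade around a nested intruder still counts as one core; every leaf
    outside the largest group is a candidate stray (plurality convention:
    the family core stays put). A candidate is confirmed misplaced only when
    non-candidate leaves of other families separate it from its family's
    core - so a host family's members are not flagged merely because a
    mislabeled intruder splits them. Size ties are recorded and broken by
    neighborhood coherence, then toward the group holding the
    lexicographically smallest id. Leaves of monophyletic families are never misplaced; branch
    lengths and supports play no role.

    Returns (flags, info); info holds ``tie_families`` and, per misplaced
    leaf, the families of the clade it intrudes into.
    """
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    excluded = set(outgroup)
    fammap = _family_map(taxonomy)
    ls = tree.leafsets()
    parent = tree.parent_map()
    full = frozenset(tree.leaf_names)

    sides: set[frozenset[str]] = set()
    for node in tree.root.postorder():
        if node is tree.root:
            continue
        sides.add(ls[node])
        sides.add(full - ls[node])

    acc: dict[str, set[str]] = {}
    leaf_nodes = {}
    for leaf in tree.leaves():
        leaf_nodes[leaf.name] = leaf
        if leaf.name in excluded or leaf.name not in fammap:
            continue
        acc.setdefault(fammap[leaf.name], set()).add(leaf.name)
    fam_leaves = {k: frozenset(v) for k, v in acc.items()}

    cores, candidates, ties = _family_cores(sides, fam_leaves, excluded, tree, ls)

    from .clade_resolution import _mrca_from_leafsets

    strays: set[str] = set()
    for x in candidates:
        fam = fammap[x]
        span = ls[_mrca_from_leafsets(tree.root, ls, cores[fam] | {x})]
        between = span - fam_leaves[fam] - excluded
        if any(y in fammap and y not in candidates for y in between):
            strays.add(x)

    flags = {
        name: name in strays
        for name in leaf_nodes
        if name not in excluded and name in fammap
    }
    intruded: dict[str, tuple[str, ...]] = {}
    for name in sorted(strays):
        fam = fammap[name]
        node = leaf_nodes[name]
        while node in parent:  # first ancestor holding other families' leaves
            node = parent[node]
            others = {
                fammap[x]
                for x in ls[node] - excluded
                if x in fammap and fammap[x] != fam
            }
            if others:
                intruded[name] = tuple(sorted(others))
                break

    return flags, {"tie_families": sorted(ties), "intruded": intruded}


def consistent_rogues(
    analyses: Sequence[tuple[SupportTree, str]],
    taxonomy,
    threshold: float = 1.0,
    outgroup: Iterable[str] | str = (),
) -> list[MisplacementRecord]:
    """Aggregate misplacement over several analyses.

    ``analyses`` is a list of (rooted tree, label) pairs. A leaf's rate is
    the mean of its flags over the analyses in which it appears; ``rogue``
    means rate >= threshold. Records are returned for every leaf flagged at
    least once, sorted by decreasing rate then id, each with the families its
    removal may affect (its own plus the families it intrudes into).
    """
    if not analyses:
        raise ValueError("need at least one analysis")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    fammap = _family_map(taxonomy)

    per_leaf_flags: dict[str, dict[str, bool]] = {}
    affected: dict[str, set[str]] = {}
    ties: dict[str, bool] = {}
    for tree, label in analyses:
        flags, info = misplaced_leaves(tree, taxonomy, outgroup)
        for name, flag in flags.items():
            per_leaf_flags.setdefault(name, {})[label] = flag
            if flag:
                affected.setdefault(name, set()).add(fammap[name])
                affected[name].update(info["intruded"].get(name, ()))
                ties[name] = ties.get(name, False) or (
                    fammap[name] in info["tie_families"]
                )

    records = []
    for name, flags in per_leaf_flags.items():
        if not any(flags.values()):
            continue
        rate = sum(flags.values()) / len(flags)
        records.append(
            MisplacementRecord(
                id=name,
                family=fammap[name],
                flags=flags,
                misplacement_rate=rate,
                rogue=rate >= threshold,
                affected_families=tuple(sorted(affected.get(name, ()))),
                tie_broken=ties.get(name, False),
            )
        )
    records.sort(key=lambda r: (-r.misplacement_rate, r.id))
    return records


def rogue_ids(records: Iterable[MisplacementRecord]) -> list[str]:
    """Exclusion list ready for the dataset filters."""
    return sorted(r.id for r in records if r.rogue)


def to_frame(records: Sequence[MisplacementRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "family": r.family,
            "misplacement_rate": r.misplacement_rate,
            "rogue": r.rogue,
            "affected_families": ";".join(r.affected_families),
            "tie_broken": r.tie_broken,
            **{f"misplaced[{k}]": v for k, v in sorted(r.flags.items())},
        }
        for r in records
    ]
    return pd.DataFrame(rows)
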