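"""Monophyly / paraphyly / polyphyly classification of family label sets.

A family is MONO when the leaves under the MRCA of its members are exactly
its members. Otherwise the extra leaves under that MRCA (the "intruders")
are decomposed into maximal family-free clades and a configurable rule
decides PARA vs POLY:

* ``nested-whole-taxa`` (default): PARA iff every maximal intruder clade is a
  union of whole families - i.e. the grade encloses entire other families,
  the pattern seen when one family is paraphyletic "in relation to" another;
  scattered single strays make the set polyphyletic.
* ``single-intruder-clade``: PARA iff there is exactly one intruder clade.
* ``intruder-fraction``: PARA iff the intruders make up at most a fraction
  ``f`` (default 0.2) of the MRCA clade.

"Fully resolved" means MONO with bootstrap support >= tau (default 70),
supports compared as integers after rounding half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import TaxonomyTable
from .tree import SupportTree

RULES = ("nested-whole-taxa", "single-intruder-clade", "intruder-fraction")
DEFAULT_TAU = 70.0


class Status(str, Enum):
    MONO = "MONO"
    PARA = "PARA"
    POLY = "POLY"
    NOT_EVALUABLE = "NOT_EVALUABLE"


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass
class ResolutionRecord:
    family: str
    status: Status
    support: float | None = None
    fully_resolved: bool = False
    n_members: int = 0
    intruder_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fully_resolved and self.status is not Status.MONO:
            raise ValueError("fully_resolved requires MONO status")
        if self.status is Status.MONO and self.intruder_ids:
            raise ValueError("MONO families have no intruders")


def _family_map(taxonomy) -> dict[str, str]:
    if isinstance(taxonomy, TaxonomyTable):
        return taxonomy.family_map()
    return dict(taxonomy)


def _mrca_from_leafsets(root, ls, target):
    node = root
    while True:
        nxt = [c for c in node.children if target <= ls[c]]
        if not nxt:
            return node
        node = nxt[0]


def _max_family_free_clades(ls, mrca, S, excluded) -> list[frozenset[str]]:
    """Maximal clades below ``mrca`` containing no member of ``S``."""
    out: list[frozenset[str]] = []
    stack = list(mrca.children)
    while stack:
        node = stack.pop()
        if ls[node] & S:
            stack.extend(node.children)
        else:
            members = ls[node] - excluded
            if members:
                out.append(frozenset(members))
    return out


def intruder_clades(
    tree: SupportTree, family_leaves: Iterable[str], exclude: Iterable[str] = ()
) -> list[frozenset[str]]:
    """Maximal intruder clades inside the MRCA span of a family's leaves."""
    S = frozenset(family_leaves)
    ls = tree.leafsets()
    return _max_family_free_clades(ls, tree.mrca(S), S, set(exclude))


def classify_families(
    tree: SupportTree,
    taxonomy,
    families: Iterable[str] | None = None,
    rule: str = "nested-whole-taxa",
    tau: float = DEFAULT_TAU,
    intruder_fraction: float = 0.2,
    exclude: Iterable[str] = (),
) -> list[ResolutionRecord]:
    """Classify every family (or the given ones) on a rooted support tree.

    ``exclude`` names leaves (e.g. the outgroup) ignored entirely. Families
    with fewer than two leaves in the tree are NOT_EVALUABLE.
    """
    if not tree.rooted:
        raise ValueError("classification requires a rooted tree")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    fammap = _family_map(taxonomy)
    excluded = set(exclude)
    ls = tree.leafsets()

    fam_leaves: dict[str, set[str]] = {}
    for name in tree.leaf_names:
        if name in excluded or name not in fammap:
            continue
        fam_leaves.setdefault(fammap[name], set()).add(name)

    if families is None:
        families = sorted(fam_leaves)
    else:
        families = list(families)
        missing = [f for f in families if f not in fam_leaves]
        if missing:
            raise KeyError(f"families absent from tree: {missing}")

    records = []
    for fam in families:
        S = frozenset(fam_leaves[fam])
        if len(S) < 2:
            records.append(
                ResolutionRecord(fam, Status.NOT_EVALUABLE, n_members=len(S))
            )
            continue
        mrca = _mrca_from_leafsets(tree.root, ls, S)
        mrca_set = ls[mrca]
        if mrca_set - excluded == S:
            sup = mrca.support
            fully = sup is not None and round_half_up(sup) >= tau
            records.append(
                ResolutionRecord(fam, Status.MONO, sup, fully, len(S))
            )
            continue

        clades = _max_family_free_clades(ls, mrca, S, excluded)
        intruders = frozenset().union(*clades) if clades else frozenset()

        if rule == "single-intruder-clade":
            is_para = len(clades) == 1
        elif rule == "intruder-fraction":
            is_para = len(intruders) <= intruder_fraction * len(mrca_set - excluded)
        else:  # nested-whole-taxa: every intruder clade is a union of whole
            # families (a nested family block), not a scatter of strays
            is_para = bool(intruders) and all(
                leaf in fammap and frozenset(fam_leaves[fammap[leaf]]) <= clade
                for clade in clades
                for leaf in clade
            )
        status = Status.PARA if is_para else Status.POLY
        records.append(
            ResolutionRecord(
                fam, status, None, False, len(S), tuple(sorted(intruders))
            )
        )
    return records


def classify_family(
    tree: SupportTree,
    family: str,
    taxonomy,
    rule: str = "nested-whole-taxa",
    tau: float = DEFAULT_TAU,
    intruder_fraction: float = 0.2,
    exclude: Iterable[str] = (),
) -> ResolutionRecord:
    """Classify one family; see :func:`classify_families`."""
    return classify_families(
        tree, taxonomy, [family], rule, tau, intruder_fraction, exclude
    )[0]


def resolution_summary(
    tree: SupportTree,
    taxonomy,
    tau: float = DEFAULT_TAU,
    rule: str = "nested-whole-taxa",
    intruder_fraction: float = 0.2,
    outgroup: Iterable[str] | str = (),
) -> tuple[list[ResolutionRecord], dict[str, int]]:
    """One record per evaluable family plus headline counts.

    Counts: families MONO and fully resolved, MONO below tau (or without a
    support annotation), PARA, POLY. NOT_EVALUABLE families are excluded.
    """
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    records = classify_families(
        tree, taxonomy, None, rule, tau, intruder_fraction, exclude=outgroup
    )
    counts = {"n_mono_resolved": 0, "n_mono_unresolved": 0, "n_para": 0, "n_poly": 0}
    for r in records:
        if r.status is Status.MONO:
            counts["n_mono_resolved" if r.fully_resolved else "n_mono_unresolved"] += 1
        elif r.status is Status.PARA:
            counts["n_para"] += 1
        elif r.status is Status.POLY:
            counts["n_poly"] += 1
    return records, counts


# ---------------------------------------------------------------- comparisons
@dataclass
class DeltaRecord:
    """Change of one family between two analyses, coded as in the comparison
    tables: 'M' became monophyletic, 'P' lost monophyly, '-' stayed
    non-monophyletic, 'R' crossed up through tau, 'U' crossed down."""

    family: str
    from_status: Status
    to_status: Status
    support_change: int | None = None
    codes: tuple[str, ...] = ()

    @property
    def formatted(self) -> str:
        if "–" in self.codes:
            return "–"
        if self.support_change is None:
            num = ""
        else:
            num = "0" if self.support_change == 0 else f"{self.support_change:+d}"
        return f"{num} {''.join(self.codes)}".strip() if self.codes else num


def compare_analyses(
    records_from: Sequence[ResolutionRecord],
    records_to: Sequence[ResolutionRecord],
    tau: float = DEFAULT_TAU,
) -> tuple[list[DeltaRecord], list[str], list[str]]:
    """Code per-family changes between two analyses.

    Returns (deltas over the common evaluable families, families evaluable
    only in the first analysis, families evaluable only in the second).
    """
    f_by = {r.family: r for r in records_from if r.status is not Status.NOT_EVALUABLE}
    t_by = {r.family: r for r in records_to if r.status is not Status.NOT_EVALUABLE}
    only_from = sorted(set(f_by) - set(t_by))
    only_to = sorted(set(t_by) - set(f_by))

    deltas = []
    for fam in sorted(set(f_by) & set(t_by)):
        f, t = f_by[fam], t_by[fam]
        codes: list[str] = []
        change: int | None = None
        f_mono, t_mono = f.status is Status.MONO, t.status is Status.MONO
        if t_mono and not f_mono:
            codes.append("M")
            if t.support is not None:
                change = round_half_up(t.support)
            if t.fully_resolved:
                codes.append("R")
        elif f_mono and not t_mono:
            codes.append("P")
            if f.support is not None:
                change = -round_half_up(f.support)
        elif not f_mono and not t_mono:
            codes.append("–")
        else:
            if f.support is not None and t.support is not None:
                change = round_half_up(t.support) - round_half_up(f.support)
            if t.fully_resolved and not f.fully_resolved:
                codes.append("R")
            elif f.fully_resolved and not t.fully_resolved:
                codes.append("U")
        deltas.append(
            DeltaRecord(fam, f.status, t.status, change, tuple(codes))
        )
    return deltas, only_from, only_to
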