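"""Leaf-labeled trees with branch lengths and per-branch bootstrap support.

Support values are attached to the *edge above* a node and stored on the node
itself (the common Newick convention, where an internal node label carries the
support of its subtending branch). Supports are percentages in [0, 100];
``None`` means "no annotation", which is distinct from 0.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping


class Node:
    """One vertex of a tree; leaves carry a name, internal nodes may not."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(
        self,
        name: str | None = None,
        children: Iterable["Node"] | None = None,
        length: float | None = None,
        support: float | None = None,
    ) -> None:
        self.name = name
        self.children: list[Node] = list(children) if children else []
        self.length = length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        # reverse of a preorder that pushes children left-to-right: every node
        # appears after all of its descendants
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def copy(self) -> "Node":
        return Node(
            self.name,
            [c.copy() for c in self.children],
            self.length,
            self.support,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf() else f"internal({len(self.children)})"
        return f"<Node {kind}>"


class SupportTree:
    """A (possibly rooted) tree over uniquely named leaves.

    ``rooted`` means the root is a meaningful bifurcation (e.g. placed on the
    outgroup's pendant edge); unrooted trees keep a trifurcating root node as
    an arbitrary anchor, as produced by neighbor joining.
    """

    def __init__(self, root: Node, rooted: bool = False, meta: Mapping | None = None):
        self.root = root
        self.rooted = rooted
        self.meta = dict(meta or {})
        names = [n.name for n in root.postorder() if n.is_leaf()]
        if any(name is None or name == "" for name in names):
            raise ValueError("every leaf must carry a non-empty name")
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")

    # ------------------------------------------------------------------ basics
    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf()]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), rooted=self.rooted, meta=self.meta)

    def parent_map(self) -> dict[Node, Node]:
        parent: dict[Node, Node] = {}
        for n in self.root.postorder():
            for c in n.children:
                parent[c] = n
        return parent

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def leafsets(self) -> dict[Node, frozenset[str]]:
        """Map every node to the frozenset of leaf names below it."""
        out: dict[Node, frozenset[str]] = {}
        for n in self.root.postorder():
            if n.is_leaf():
                out[n] = frozenset([n.name])
            else:
                acc: set[str] = set()
                for c in n.children:
                    acc.update(out[c])
                out[n] = frozenset(acc)
        return out

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of ``names`` (rooted reading)."""
        target = frozenset(names)
        if not target:
            raise ValueError("mrca of an empty set")
        missing = target - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        ls = self.leafsets()
        node = self.root
        while True:
            nxt = [c for c in node.children if target <= ls[c]]
            if not nxt:
                return node
            node = nxt[0]

    # ------------------------------------------------------------ bipartitions
    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted splits, canonicalized to the side that does
        not contain the lexicographically smallest leaf name."""
        full = frozenset(self.leaf_names)
        anchor = min(full)
        ls = self.leafsets()
        out = set()
        for n in self.root.postorder():
            if n is self.root or n.is_leaf():
                continue
            side = ls[n]
            if len(side) < 2 or len(full - side) < 2:
                continue
            out.add(side if anchor not in side else full - side)
        return frozenset(out)

    # ------------------------------------------------------------------ editing
    def prune(self, drop: Iterable[str]) -> "SupportTree":
        """Remove the given leaves; unary nodes are suppressed, merging branch
        lengths. The surviving edge keeps its own support annotation (the one
        closer to the leaves) when both merged edges were annotated."""
        dropset = set(drop)

        def rec(n: Node) -> Node | None:
            if n.is_leaf():
                return None if n.name in dropset else Node(n.name, None, n.length, n.support)
            kids = [k for k in (rec(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if n.length is not None or child.length is not None:
                    child.length = (n.length or 0.0) + (child.length or 0.0)
                if child.support is None:
                    child.support = n.support
                return child
            return Node(None, kids, n.length, n.support)

        root = rec(self.root)
        if root is None or root.is_leaf():
            raise ValueError("pruning removed all (or all but one) leaves")
        root.length = None
        root.support = None
        return SupportTree(root, rooted=self.rooted and len(root.children) == 2, meta=self.meta)

    def root_on(self, outgroup_id: str) -> "SupportTree":
        """Root the tree on the pendant edge of ``outgroup_id``.

        The pendant edge is split in half; internal-branch supports travel
        with their bipartitions, so the multiset of splits is unchanged.
        """
        t = self.copy()
        parent = t.parent_map()
        og = None
        for leaf in t.leaves():
            if leaf.name == outgroup_id:
                og = leaf
                break
        if og is None:
            raise KeyError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
        p = parent[og]
        if p is t.root and len(t.root.children) == 2:
            # already rooted on this pendant edge
            t.rooted = True
            return t

        p.children.remove(og)
        half = og.length / 2.0 if og.length is not None else None
        og.length = half

        # reorient the path p -> ... -> old root so that p becomes the apex;
        # the edge between path[i] and path[i+1] was stored on path[i] and is
        # stored on path[i+1] after the reversal
        path = [p]
        q = parent.get(p)
        while q is not None:
            path.append(q)
            q = parent.get(q)
        attrs = [(n.length, n.support) for n in path]
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        for i in range(len(path) - 1):
            path[i].children.append(path[i + 1])
            path[i + 1].length, path[i + 1].support = attrs[i]
        apex = path[0]
        apex.length, apex.support = half, None
        _suppress_unary(apex)

        root = Node(children=[og, apex])
        return SupportTree(root, rooted=True, meta=self.meta)

    # ------------------------------------------------------------------ output
    def newick(self, clamp_negative: bool = False) -> str:
        def fmt_len(x: float | None) -> str:
            if x is None:
                return ""
            if clamp_negative and x < 0:
                x = 0.0
            return f":{x:.10g}"

        def fmt_sup(s: float | None) -> str:
            if s is None:
                return ""
            return f"{int(round(s))}" if abs(s - round(s)) < 1e-9 else f"{s:.6g}"

        def rec(n: Node) -> str:
            if n.is_leaf():
                return f"{n.name}{fmt_len(n.length)}"
            inner = ",".join(rec(c) for c in n.children)
            return f"({inner}){fmt_sup(n.support)}{fmt_len(n.length)}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SupportTree n_leaves={len(self.leaf_names)} rooted={self.rooted}>"


def _suppress_unary(apex: Node) -> None:
    """Collapse unary internal nodes anywhere below (and including) apex's
    children. Merged edges sum lengths; the support closer to the leaves
    wins when both edges carried one."""
    stack = [apex]
    while stack:
        n = stack.pop()
        new_children = []
        for c in n.children:
            while len(c.children) == 1:
                g = c.children[0]
                if c.length is not None or g.length is not None:
                    g.length = (c.length or 0.0) + (g.length or 0.0)
                if g.support is None:
                    g.support = c.support
                c = g
            new_children.append(c)
            stack.append(c)
        n.children = new_children
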