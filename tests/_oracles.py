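"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the K2P oracle counts
site patterns one position at a time with scalar math; the classification
oracle works on enumerated clade bitmasks with pure set algebra; random
additive matrices are built from explicitly constructed trees whose
path-length metric is computed by leaf-pair traversal.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


# ------------------------------------------------------------------ K2P oracle
def k2p_site_counting(seq_a: str, seq_b: str):
    """Brute-force site classification and the closed form, scalar math."""
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan, 0.0, 0.0, 0
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan, P, Q, n
    return -0.5 * math.log(w1 * math.sqrt(w2)), P, Q, n


def random_pair(rng, length=300, p_gap=0.08):
    bases = np.array(list("ACGT-N"))
    probs = [0.23, 0.23, 0.23, 0.23, p_gap / 2, p_gap / 2]
    a = "".join(rng.choice(bases, p=probs, size=length))
    # derive b from a with moderate divergence so distances stay defined
    b = []
    for ch in a:
        r = rng.random()
        if ch not in "ACGT" or r < 0.75:
            b.append(ch)
        elif r < 0.92:
            b.append({"A": "G", "G": "A", "C": "T", "T": "C"}[ch])
        else:
            b.append({"A": "C", "G": "T", "C": "A", "T": "G"}[ch])
    return a, "".join(b)


def related_sequences(rng, n, length=300, divergence=0.08):
    """n gapless sequences lightly mutated from one ancestor: all pairwise
    distances stay small and well-defined."""
    bases = "ACGT"
    anc = rng.integers(0, 4, size=length)
    out = {}
    for i in range(n):
        mask = rng.random(length) < divergence
        row = anc.copy()
        row[mask] = (row[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        out[f"s{i}"] = "".join(bases[b] for b in row)
    return out


# ---------------------------------------------------- rooted topology machinery
def rooted_topologies(labels):
    """All rooted binary topologies over the labels, as nested 2-tuples."""
    labels = list(labels)
    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [t for tr in trees for t in _insertions(tr, lab)]
    return trees


def _insertions(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def tuple_tree_newick(tree) -> str:
    if isinstance(tree, tuple):
        return "(" + ",".join(tuple_tree_newick(c) for c in tree) + ")"
    return str(tree)


def clade_bitmasks(tree, index: dict[str, int]) -> list[int]:
    """Every clade of the tuple-tree as a bitmask over the leaf index."""
    out = []

    def rec(t) -> int:
        if isinstance(t, tuple):
            m = rec(t[0]) | rec(t[1])
        else:
            m = 1 << index[t]
        out.append(m)
        return m

    rec(tree)
    return out


def oracle_classify_two_families(clades: list[int], fam_a: int, fam_b: int, S: int):
    """Brute-force verdict for label set S (one of fam_a/fam_b) by clade-set
    algebra: MONO iff S is a clade; otherwise PARA under the
    nested-whole-taxa rule iff the whole other family forms a clade nested
    inside S's MRCA clade (with two families, every intruder belongs to the
    other family, so each intruder clade is a union of whole families exactly
    when the other family is one nested clade). Returns (status, mask)."""
    if bin(S).count("1") < 2:
        return "NOT_EVALUABLE", 0
    if S in clades:
        return "MONO", 0
    mrca = min((c for c in clades if c & S == S), key=lambda c: bin(c).count("1"))
    intruders = mrca & ~S
    other = fam_b if S == fam_a else fam_a
    is_para = other & ~mrca == 0 and other in clades
    return ("PARA" if is_para else "POLY"), intruders


# ------------------------------------------------------------ additive metrics
def random_additive_tree(rng, n_leaves: int, min_len=0.01, max_len=0.5):
    """Random unrooted binary tree (as a rooted tuple with 3 root children)
    plus its exact path-length distance matrix."""
    labels = [f"t{i}" for i in range(n_leaves)]
    # random rooted topology by sequential insertion at a random position
    tree = labels[0]
    for lab in labels[1:]:
        spots = list(_insertions(tree, lab))
        tree = spots[int(rng.integers(len(spots)))]
    lengths: dict[int, float] = {}

    # assign branch lengths by traversal; compute leaf depths per subtree
    dist = {a: {} for a in labels}

    def rec(t):
        """Return {leaf: distance to this node}."""
        if not isinstance(t, tuple):
            return {t: 0.0}
        maps = []
        for child in t:
            m = rec(child)
            edge = float(rng.uniform(min_len, max_len))
            maps.append({k: v + edge for k, v in m.items()})
        for m1, m2 in itertools.combinations(maps, 2):
            for a, da in m1.items():
                for b, db in m2.items():
                    dist[a][b] = dist[b][a] = da + db
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    rec(tree)
    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = dist[a][b]
    return labels, tree, D


def tuple_tree_bipartitions(tree, labels):
    """Non-trivial unrooted splits of a tuple-tree, canonicalized like
    SupportTree.bipartitions (side without the lexicographically smallest
    leaf)."""
    full = frozenset(labels)
    anchor = min(full)
    sides = []

    def rec(t) -> frozenset:
        if not isinstance(t, tuple):
            return frozenset([t])
        acc = frozenset()
        for child in t:
            s = rec(child)
            sides.append(s)
            acc |= s
        return acc

    rec(tree)
    out = set()
    for s in sides:
        if len(s) < 2 or len(full - s) < 2:
            continue
        out.add(s if anchor not in s else full - s)
    return frozenset(out)
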