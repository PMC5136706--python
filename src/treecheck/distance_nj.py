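"""Kimura 2-parameter distances, neighbor joining, bootstrap, rooting.

The distance follows the two-parameter substitution model that separates
transitions (A<->G, C<->T) from transversions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over the sites
compared. Missing data is handled by *pairwise deletion*: a column is used
for a pair only when both sequences carry an unambiguous base (A, C, G, T);
gaps and ambiguity codes are treated as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import Alignment
from .tree import Node, SupportTree

# base codes: A=0 C=1 G=2 T=3, anything else = 4 (missing under pairwise
# deletion). Transitions are 0<->2 and 1<->3 (code XOR 2).
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i


def encode_alignment(alignment: Alignment | Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as an (n, L) uint8 matrix of base codes."""
    seqs = (
        [r.residues for r in alignment.records]
        if isinstance(alignment, Alignment)
        else list(alignment)
    )
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _LUT[raw].reshape(len(seqs), -1)


@dataclass
class K2PResult:
    d: float
    P: float
    Q: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.d)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances with per-pair site bookkeeping. Undefined
    entries (log argument <= 0 or no comparable sites) are NaN."""

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray | None = None
    n_transitions: np.ndarray | None = None
    n_transversions: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.d[off]).any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def k2p_distance(
    seq_a: str, seq_b: str, on_undefined: str = "raise", cap: float = 5.0
) -> K2PResult:
    """K2P distance between two aligned sequences under pairwise deletion.

    ``on_undefined``: 'raise' (default), 'nan', or 'cap' (return ``cap``)
    when the log argument is <= 0 or no comparable sites remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences have unequal aligned lengths")
    x = _LUT[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    y = _LUT[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    ok = (x < 4) & (y < 4)
    n = int(ok.sum())
    if n == 0:
        return _undefined(0.0, 0.0, 0, on_undefined, cap, "no comparable sites")
    diff = ok & (x != y)
    ts = int((diff & ((x ^ y) == 2)).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return _undefined(P, Q, n, on_undefined, cap, "K2P log argument <= 0")
    return K2PResult(-0.5 * math.log(w1 * math.sqrt(w2)), P, Q, n)


def _undefined(P, Q, n, on_undefined, cap, why) -> K2PResult:
    if on_undefined == "raise":
        raise ValueError(f"undefined K2P distance: {why}")
    if on_undefined == "cap":
        return K2PResult(cap, P, Q, n)
    return K2PResult(float("nan"), P, Q, n)


def _k2p_matrix_from_codes(X: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized all-pairs K2P from an encoded alignment. Counting is exact
    (0/1 float64 matmuls); undefined entries come out as NaN."""
    M = [(X == b).astype(np.float64) for b in range(4)]
    valid = (X < 4).astype(np.float64)
    n = valid @ valid.T
    match = sum(Mb @ Mb.T for Mb in M)
    ts_half = M[0] @ M[2].T + M[1] @ M[3].T
    ts = ts_half + ts_half.T
    tv = n - match - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n > 0, ts / n, np.nan)
        Q = np.where(n > 0, tv / n, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        ok = (n > 0) & (w1 > 0) & (w2 > 0)
        d = np.where(ok, -0.5 * np.log(np.where(ok, w1 * np.sqrt(np.abs(w2)), 1.0)), np.nan)
    np.fill_diagonal(d, 0.0)
    return d, n.astype(np.int64), ts.astype(np.int64), tv.astype(np.int64)


def k2p_matrix(
    alignment: Alignment, on_undefined: str = "raise", cap: float = 5.0
) -> DistanceMatrix:
    """All-pairs K2P distance matrix under pairwise deletion."""
    X = encode_alignment(alignment)
    d, n, ts, tv = _k2p_matrix_from_codes(X)
    dm = DistanceMatrix(alignment.ids, d, n, ts, tv)
    if dm.has_undefined:
        if on_undefined == "raise":
            raise ValueError(
                f"undefined K2P distances for pairs: {dm.undefined_pairs()[:10]}"
            )
        if on_undefined == "cap":
            off = ~np.eye(len(dm.ids), dtype=bool)
            d[np.isnan(d) & off] = cap
    return dm


# -------------------------------------------------------------------------- NJ
def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining; unrooted, no supports.

    Deterministic: ties in the Q criterion are broken by the smallest (i, j)
    index pair of the current (shrinking) matrix, where original taxa keep
    their input order and merged nodes are appended at the end. Negative
    branch lengths are retained (write with ``clamp_negative`` to zero them
    for display).
    """
    if dm.has_undefined:
        raise ValueError("distance matrix contains undefined entries")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [Node(name=i) for i in dm.ids]
    D = np.array(dm.d, dtype=np.float64, copy=True)

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        Q[np.tril_indices(m)] = np.inf  # keep i < j; row-major argmin = smallest (i, j)
        i, j = divmod(int(np.argmin(Q)), m)
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        nodes[i].length = li
        nodes[j].length = dij - li
        new = Node(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = (dab + dac - dbc) / 2.0
    b.length = (dab + dbc - dac) / 2.0
    c.length = (dac + dbc - dab) / 2.0
    return SupportTree(Node(children=[a, b, c]), rooted=False)


def root_tree(tree: SupportTree, outgroup_id: str) -> SupportTree:
    """Root on the outgroup's pendant edge; supports carry over."""
    return tree.root_on(outgroup_id)


# ------------------------------------------------------------------- bootstrap
def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    max_redraw_factor: int = 10,
) -> SupportTree:
    """Column bootstrap for the NJ tree of ``alignment``.

    The reference NJ tree is built on the original alignment; each of the
    ``n_replicates`` column resamples (with replacement, seeded RNG) yields an
    NJ tree, and each internal branch of the reference tree gets support
    100 x (fraction of replicate trees containing its bipartition) - mapped
    onto the original tree, not a consensus. Replicates with an undefined
    pairwise distance are redrawn and counted (``meta['n_redrawn']``).
    Bit-for-bit reproducible for a given (alignment, n_replicates, seed).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    X = encode_alignment(alignment)
    ids = alignment.ids
    L = X.shape[1]

    d0, *_ = _k2p_matrix_from_codes(X)
    ref_dm = DistanceMatrix(ids, d0)
    if ref_dm.has_undefined:
        raise ValueError(
            f"undefined K2P distances in the original alignment: {ref_dm.undefined_pairs()[:10]}"
        )
    ref = nj_tree(ref_dm)

    full = frozenset(ids)
    anchor = min(full)
    ls = ref.leafsets()
    node_bip: dict = {}
    for node in ref.root.postorder():
        if node is ref.root or node.is_leaf():
            continue
        side = ls[node]
        if len(side) < 2 or len(full - side) < 2:
            continue
        node_bip[node] = side if anchor not in side else full - side

    counts = {bip: 0 for bip in node_bip.values()}
    rng = np.random.default_rng(seed)
    done = redraws = 0
    max_redraws = max_redraw_factor * n_replicates + 100
    off = ~np.eye(len(ids), dtype=bool)
    while done < n_replicates:
        idx = rng.integers(0, L, size=L)
        db, *_ = _k2p_matrix_from_codes(X[:, idx])
        if np.isnan(db[off]).any():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "bootstrap failed: replicates persistently yield undefined distances"
                )
            continue
        rep = nj_tree(DistanceMatrix(ids, db))
        rep_bips = rep.bipartitions()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
        done += 1

    for node, bip in node_bip.items():
        node.support = 100.0 * counts[bip] / n_replicates
    ref.meta.update(n_replicates=n_replicates, seed=seed, n_redrawn=redraws)
    return ref
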