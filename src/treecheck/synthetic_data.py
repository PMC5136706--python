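"""Family-structured synthetic reference datasets with known ground truth.

The generator emulates the kind of curated 18S barcode reference set used in
marine nematode metabarcoding: ~50 family-level clades of 2-10 taxa each,
barcode-length (~400 nt) alignments with a few hypervariable blocks standing
in for the V1/V2 regions, a fraction of sequences truncated at the 5' end,
a handful of mislabeled ("erroneous") sequences, and anonymous query OTUs
derived from known families. Everything is recorded in a truth log so the
curation filters, rogue detection and OTU assignment can be tested against a
known answer without any downloads.

Sequences evolve along the simulated tree under the Kimura 2-parameter
substitution process (transition/transversion rate ratio ``kappa``), the
same model family the distance engine assumes. No indels are simulated: the
alignment is correct by construction, keeping alignment quality - which is
produced by external tools - out of the tested core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io_formats import Alignment, SequenceRecord, TaxonomyTable
from .tree import Node, SupportTree

OUTGROUP_ID = "OUTGROUP"


@dataclass
class SimConfig:
    """Study-design parameters.

    Defaults mirror the curated reference set the generator emulates:
    50 families of 2-10 taxa, a 400 nt barcode with two hypervariable blocks,
    eight mislabeled sequences, 5'-truncations spanning both curation
    thresholds (some >= 40 missing bases, all > 10), and 25 query OTUs.
    Heights are expected substitutions/site; within-family divergence is kept
    well below between-family divergence so true families are cleanly
    separated clades.
    """

    n_families: int = 50
    members_min: int = 2
    members_max: int = 10
    barcode_length: int = 400
    within_family_height: float = 0.03
    between_family_height: float = 0.30
    kappa: float = 2.0
    n_variable_blocks: int = 2
    variable_block_length: int = 40
    variable_rate_multiplier: float = 4.0
    n_mislabel: int = 8
    n_truncate: int = 60
    truncate_min: int = 11
    truncate_max: int = 120
    n_queries: int = 25
    query_branch_length: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.members_min < 1:
            raise ValueError("need at least one family with one member")
        if self.members_min > self.members_max:
            raise ValueError("members_min > members_max")
        if self.barcode_length < 50:
            raise ValueError("barcode_length must be >= 50")
        if self.within_family_height <= 0 or self.between_family_height <= 0:
            raise ValueError("tree heights must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if min(self.n_mislabel, self.n_truncate, self.n_queries) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    family_by_id: dict[str, str] = field(default_factory=dict)
    mislabeled: list[dict] = field(default_factory=list)  # id, true/reported family
    truncated: list[dict] = field(default_factory=list)  # id, missing_5prime
    queries: list[dict] = field(default_factory=list)  # id, true family

    @property
    def mislabeled_ids(self) -> list[str]:
        return sorted(m["id"] for m in self.mislabeled)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _family_name(i: int) -> str:
    return f"Family{i:02d}"


def _random_ultrametric(
    tip_names: Sequence[str], height: float, rng: np.random.Generator
) -> Node:
    """Random topology by uniform sequential joins, node depths rescaled so
    the root sits at ``height`` substitutions/site above the tips."""
    lineages = [(Node(name=n), 0.0) for n in tip_names]
    if len(lineages) == 1:
        node, _ = lineages[0]
        node.length = height
        return node
    t = 0.0
    while len(lineages) > 1:
        t += float(rng.exponential(1.0 / len(lineages)))
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        joined = (Node(children=[a, b]), t)
        a.length, b.length = t - ha, t - hb
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(joined)
    root, total = lineages[0]
    scale = height / total if total > 0 else 0.0
    for n in root.postorder():
        if n.length is not None:
            n.length *= scale
    return root


def _random_backbone(
    tip_names: Sequence[str], height: float, rng: np.random.Generator
) -> Node:
    """Random topology by sequential insertion with every edge drawn uniform
    in [0.5, 1], rescaled so the mean root-to-tip depth equals ``height``.
    The bounded edge lengths guarantee every family a substantial stem, so
    true family clades are separated by construction."""
    tup = tip_names[0]
    for lab in tip_names[1:]:
        spots = _all_insertions(tup, lab)
        tup = spots[int(rng.integers(len(spots)))]

    def conv(t) -> Node:
        length = float(rng.uniform(0.5, 1.0))
        if isinstance(t, tuple):
            return Node(children=[conv(c) for c in t], length=length)
        return Node(name=t, length=length)

    root = conv(tup)
    root.length = None
    if len(tip_names) == 1:
        root.length = height
        return root
    depths = []

    def depth(node, acc):
        if node.is_leaf():
            depths.append(acc)
        for c in node.children:
            depth(c, acc + c.length)

    depth(root, 0.0)
    scale = height / (sum(depths) / len(depths))
    for n in root.postorder():
        if n.length is not None:
            n.length *= scale
    return root


def _all_insertions(tree, leaf):
    out = [(tree, leaf)]
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((t, right) for t in _all_insertions(left, leaf))
        out.extend((left, t) for t in _all_insertions(right, leaf))
    return out


def simulate_family_tree(
    config: SimConfig, seed: int | None = None
) -> tuple[SupportTree, SyntheticTruth]:
    """Rooted true tree: one clade per family on a shared backbone, plus an
    outgroup attached at the root. Every family is monophyletic by
    construction; there are no support values."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    families = [_family_name(i) for i in range(config.n_families)]
    sizes = {
        fam: int(rng.integers(config.members_min, config.members_max + 1))
        for fam in families
    }

    backbone_height = max(
        config.between_family_height - config.within_family_height,
        config.within_family_height,
    )
    backbone = _random_backbone(families, backbone_height, rng)

    truth = SyntheticTruth()
    for node in backbone.postorder():
        if node.is_leaf() and node.name in sizes:
            fam = node.name
            members = [f"{fam}_t{k:02d}" for k in range(sizes[fam])]
            for m in members:
                truth.family_by_id[m] = fam
            if len(members) == 1:
                node.name = members[0]
            else:
                sub = _random_ultrametric(members, config.within_family_height, rng)
                node.name = None
                node.children = sub.children

    outgroup = Node(name=OUTGROUP_ID, length=config.between_family_height)
    ingroup = backbone
    ingroup.length = config.between_family_height * 0.5
    root = Node(children=[ingroup, outgroup])
    return SupportTree(root, rooted=True), truth


# ------------------------------------------------------------------- evolution
_TI_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV1 = np.array([1, 0, 1, 0])  # A->C, C->A, G->C, T->A
_TV2 = np.array([3, 2, 3, 2])  # A->T, C->G, G->T, T->G


def _k2p_step(
    parent: np.ndarray, t_sites: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a coded sequence for per-site durations ``t_sites`` (expected
    substitutions/site) under the K2P process with ts/tv rate ratio kappa."""
    # rates normalized so alpha + 2*beta = 1 substitution per unit time
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * t_sites)
    e2 = np.exp(-2.0 * (alpha + beta) * t_sites)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(parent.shape[0])
    child = parent.copy()
    ti_mask = (u >= p_same) & (u < p_same + p_ti)
    tv1_mask = (u >= p_same + p_ti) & (u < p_same + p_ti + p_tv)
    tv2_mask = u >= p_same + p_ti + p_tv
    child[ti_mask] = _TI_PARTNER[parent[ti_mask]]
    child[tv1_mask] = _TV1[parent[tv1_mask]]
    child[tv2_mask] = _TV2[parent[tv2_mask]]
    return child


def variable_block_multipliers(config: SimConfig) -> np.ndarray:
    """Per-site rate multipliers: evenly spaced hypervariable blocks.

    The profile is normalized to mean 1 so branch lengths keep their
    expected-substitutions-per-site meaning; consequently the background
    between the blocks evolves slower than average, concentrating the
    discriminating signal in the variable regions, as in real rRNA barcodes.
    """
    mult = np.ones(config.barcode_length)
    if config.n_variable_blocks <= 0:
        return mult
    spacing = config.barcode_length // (config.n_variable_blocks + 1)
    for b in range(config.n_variable_blocks):
        start = (b + 1) * spacing - config.variable_block_length // 2
        start = max(0, min(start, config.barcode_length - config.variable_block_length))
        mult[start : start + config.variable_block_length] = (
            config.variable_rate_multiplier
        )
    return mult / mult.mean()


_BASES = "ACGT"


def evolve_sequences(
    tree: SupportTree,
    config: SimConfig,
    seed: int | None = None,
    truth: SyntheticTruth | None = None,
) -> Alignment:
    """Simulate a gapless alignment along ``tree`` under the K2P process.

    The root sequence is i.i.d. uniform over {A,C,G,T}; hypervariable blocks
    evolve at ``variable_rate_multiplier`` times the branch rate. Rows are
    ordered by leaf id for determinism.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mult = variable_block_multipliers(config)
    root_seq = rng.integers(0, 4, size=config.barcode_length).astype(np.int64)

    seqs: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        # children visited in stored order with a single RNG stream: fully
        # deterministic for a fixed tree and seed
        for child in node.children:
            t_sites = (child.length or 0.0) * mult
            child_seq = _k2p_step(seq, t_sites, config.kappa, rng)
            if child.is_leaf():
                seqs[child.name] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.root, root_seq)

    fam = truth.family_by_id if truth is not None else {}
    records = []
    for name in sorted(seqs):
        residues = "".join(_BASES[b] for b in seqs[name])
        records.append(
            SequenceRecord(
                name,
                residues,
                family=fam.get(name, "" if name != OUTGROUP_ID else "Priapulida"),
                genus=f"genus_{fam.get(name, 'out')}",
                species=f"species_{name}",
            )
        )
    return Alignment(records)


def inject_errors(
    alignment: Alignment,
    truth: SyntheticTruth,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[Alignment, SyntheticTruth]:
    """Mislabel ``n_mislabel`` leaves (labels only; sequences untouched) and
    5'-truncate ``n_truncate`` others (leading bases replaced by gaps and
    ``missing_5prime`` set). The two sets are disjoint and exclude the
    outgroup. Everything is recorded in the truth log."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    ingroup = [r.id for r in alignment.records if r.id in truth.family_by_id]
    if config.n_mislabel + config.n_truncate > len(ingroup):
        raise ValueError("more corruptions requested than ingroup leaves")
    chosen = rng.choice(len(ingroup), config.n_mislabel + config.n_truncate, replace=False)
    mislabel_ids = {ingroup[i] for i in chosen[: config.n_mislabel]}
    truncate_ids = {ingroup[i] for i in chosen[config.n_mislabel :]}

    families = sorted({f for f in truth.family_by_id.values()})
    out_records = []
    for r in alignment.records:
        if r.id in mislabel_ids:
            true_fam = truth.family_by_id[r.id]
            others = [f for f in families if f != true_fam]
            new_fam = others[int(rng.integers(len(others)))]
            truth.mislabeled.append(
                {"id": r.id, "true_family": true_fam, "reported_family": new_fam}
            )
            out_records.append(
                SequenceRecord(
                    r.id, r.residues, new_fam, f"genus_{new_fam}", r.species, r.missing_5prime
                )
            )
        elif r.id in truncate_ids:
            m = int(rng.integers(config.truncate_min, config.truncate_max + 1))
            m = min(m, len(r.residues) - 1)
            truth.truncated.append({"id": r.id, "missing_5prime": m})
            out_records.append(
                SequenceRecord(
                    r.id, "-" * m + r.residues[m:], r.family, r.genus, r.species, m
                )
            )
        else:
            out_records.append(r)
    return Alignment(out_records), truth


def simulate_queries(
    tree: SupportTree,
    alignment: Alignment,
    config: SimConfig,
    seed: int | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Query OTUs: each evolves from a randomly chosen ingroup leaf's sequence
    along an extra branch of ``query_branch_length``."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    fam = truth.family_by_id if truth is not None else {}
    sources = [r for r in alignment.records if r.id in fam] or [
        r for r in alignment.records if r.id != OUTGROUP_ID
    ]
    mult = variable_block_multipliers(config)
    from .distance_nj import encode_alignment  # local import avoids a cycle

    queries, qtruth = [], []
    for k in range(config.n_queries):
        src = sources[int(rng.integers(len(sources)))]
        parent = encode_alignment([src.residues])[0].astype(np.int64)
        child = _k2p_step(parent, config.query_branch_length * mult, config.kappa, rng)
        qid = f"OTU{k:03d}"
        queries.append(
            SequenceRecord(qid, "".join(_BASES[b] for b in child), species="sp.")
        )
        entry = {"id": qid, "true_family": fam.get(src.id, ""), "source": src.id}
        qtruth.append(entry)
        if truth is not None:
            truth.queries.append(entry)
    return queries, qtruth


@dataclass
class SyntheticDataset:
    tree: SupportTree
    alignment: Alignment  # reference rows only, possibly corrupted
    queries: list[SequenceRecord]
    taxonomy: TaxonomyTable
    truth: SyntheticTruth
    config: SimConfig

    @property
    def outgroup(self) -> str:
        return OUTGROUP_ID


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """End-to-end generation: true tree, evolved alignment, injected errors,
    query OTUs, taxonomy table and truth log. Fully determined by
    ``config.seed``."""
    tree, truth = simulate_family_tree(config)
    clean = evolve_sequences(tree, config, truth=truth)
    corrupted, truth = inject_errors(clean, truth, config)
    queries, _ = simulate_queries(tree, clean, config, truth=truth)
    taxonomy = TaxonomyTable.from_records(corrupted.records)
    return SyntheticDataset(tree, corrupted, queries, taxonomy, truth, config)
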