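"""Standard-format I/O and reference-dataset curation filters.

The curation filters mirror the sorting rules used to build family-level 18S
reference sets for marine nematode metabarcoding: prefer longer sequences of
the same species, cap each species at two sequences, prefer species-level
records over genus-level ("sp.") ones, keep only families with at least two
species-level units, and exclude sequences missing too much of the 5' end of
the barcode (>= 40 bases for the complete dataset, > 10 for the "long" one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .tree import Node, SupportTree

VALID_RESIDUES = set("ACGTUN-")


# ----------------------------------------------------------------- containers
@dataclass
class SequenceRecord:
    """One reference or query sequence plus its taxonomy and 5'-truncation
    metadata. ``missing_5prime`` counts bases absent at the 5' end relative
    to the full barcode region (supplied as metadata, not inferred)."""

    id: str
    residues: str
    family: str = ""
    genus: str = ""
    species: str = ""
    missing_5prime: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        self.residues = self.residues.upper().replace("U", "T")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        if self.missing_5prime < 0:
            raise ValueError(f"{self.id}: missing_5prime must be >= 0")

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")

    def is_species_level(self) -> bool:
        return bool(self.species) and self.species != "sp."


class Alignment:
    """Ordered equal-length SequenceRecords; gap character ``-``.

    Gap-only columns are removed on construction.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in records}
        if len(lengths) != 1:
            offender = max(records, key=lambda r: len(r.residues))
            raise ValueError(
                f"ragged alignment: row lengths {sorted(lengths)} (e.g. {offender.id})"
            )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        self.records = _drop_all_gap_columns(records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in wanted])

    def concat_rows(self, other: "Alignment") -> "Alignment":
        if other.length != self.length:
            raise ValueError("alignments have different lengths")
        return Alignment(self.records + other.records)


def _drop_all_gap_columns(records: list[SequenceRecord]) -> list[SequenceRecord]:
    length = len(records[0].residues)
    keep = [
        j for j in range(length) if any(r.residues[j] != "-" for r in records)
    ]
    if len(keep) == length:
        return records
    out = []
    for r in records:
        res = "".join(r.residues[j] for j in keep)
        out.append(
            SequenceRecord(r.id, res, r.family, r.genus, r.species, r.missing_5prime)
        )
    return out


class TaxonomyTable:
    """id -> (family, genus, species[, missing5p]) lookup, one row per id."""

    REQUIRED = ("id", "family", "genus", "species")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        if df["id"].duplicated().any():
            dupes = sorted(df.loc[df["id"].duplicated(), "id"])
            raise ValueError(f"duplicate taxonomy ids: {dupes}")
        if "missing5p" not in df.columns:
            df = df.assign(missing5p=0)
        self.df = df.reset_index(drop=True)
        self._by_id = self.df.set_index("id").to_dict("index")

    @classmethod
    def read(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"id": str}))

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "TaxonomyTable":
        rows = [
            {
                "id": r.id,
                "family": r.family,
                "genus": r.genus,
                "species": r.species,
                "missing5p": r.missing_5prime,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    def family_of(self, rec_id: str) -> str:
        return self._by_id[rec_id]["family"]

    def family_map(self) -> dict[str, str]:
        return {i: row["family"] for i, row in self._by_id.items()}

    @property
    def families(self) -> list[str]:
        return sorted(set(self.df["family"]))

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])


def attach_taxonomy(
    records: Iterable[SequenceRecord], taxonomy: TaxonomyTable
) -> list[SequenceRecord]:
    """Return copies of ``records`` with taxonomy (and missing5p) filled in.
    Records absent from the table are passed through untouched."""
    out = []
    for r in records:
        if r.id in taxonomy:
            row = taxonomy._by_id[r.id]
            out.append(
                SequenceRecord(
                    r.id,
                    r.residues,
                    str(row["family"]),
                    str(row["genus"]),
                    str(row["species"]),
                    int(row.get("missing5p", 0) or 0),
                )
            )
        else:
            out.append(r)
    return out


# ------------------------------------------------------------------- FASTA IO
def read_fasta(path, aligned: bool = True):
    """Read a FASTA file.

    Residues are uppercased and U is normalized to T. With ``aligned=True``
    (default) returns an :class:`Alignment` and enforces equal row lengths;
    otherwise returns a plain list of :class:`SequenceRecord`.
    """
    records = []
    seen = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    if aligned:
        return Alignment(records)
    return records


def write_fasta(records, path) -> None:
    if isinstance(records, Alignment):
        records = records.records
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ------------------------------------------------------------------ Newick IO
def read_tree(path_or_string, taxonomy: TaxonomyTable | None = None) -> SupportTree:
    """Parse a Newick tree with optional internal-node support labels.

    Supports given as proportions (every annotated value <= 1.0) are rescaled
    to percentages; mixing proportions with percentages is rejected. With a
    taxonomy, leaves that cannot be resolved are collected into
    ``tree.meta['unresolved_leaves']`` (a warning list, not an error).
    """
    src = str(path_or_string)
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if src.lstrip().startswith("("):
        dtree = dendropy.Tree.get(data=src, **kwargs)
    else:
        dtree = dendropy.Tree.get(path=src, **kwargs)

    def conv(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(name=name, length=dnode.edge.length)
        support = None
        if dnode.label not in (None, ""):
            try:
                support = float(dnode.label)
            except ValueError as exc:
                raise ValueError(f"non-numeric support label: {dnode.label!r}") from exc
        return Node(
            children=[conv(c) for c in dnode.child_nodes()],
            length=dnode.edge.length,
            support=support,
        )

    root = conv(dtree.seed_node)
    root.support = None  # a label on the root is not a branch support
    supports = [
        n.support for n in root.postorder() if not n.is_leaf() and n.support is not None
    ]
    if supports:
        if max(supports) <= 1.0:
            for n in root.postorder():
                if n.support is not None:
                    n.support *= 100.0
        elif any(0.0 < s < 1.0 for s in supports):
            raise ValueError(
                "mixed support dialects: both proportions in (0,1) and values > 1 present"
            )
        out_of_range = [s for s in supports if not (0.0 <= s <= 100.0)]
        if max(supports) > 1.0 and out_of_range:
            raise ValueError(f"support values outside [0,100]: {out_of_range}")
    tree = SupportTree(root, rooted=len(root.children) == 2)
    if taxonomy is not None:
        tree.meta["unresolved_leaves"] = sorted(
            name for name in tree.leaf_names if name not in taxonomy
        )
    return tree


def write_tree(tree: SupportTree, path, clamp_negative: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(clamp_negative=clamp_negative) + "\n")


# ------------------------------------------------------------ curation filters
@dataclass
class FilterReport:
    """Partition of the input ids into kept and dropped (with the first
    criterion that removed each id: '1' shorter duplicate, '4' per-species
    cap, '2' genus-level record superseded, '6' family below two species-level
    units, '7' 5'-incomplete in complete mode, 'LONG' in long mode)."""

    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    mode: str = "complete"

    def validate(self, input_ids: Iterable[str]) -> None:
        inp = set(input_ids)
        k, d = set(self.kept), set(self.dropped)
        if k | d != inp or k & d:
            raise AssertionError("FilterReport does not partition the input ids")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"mode": self.mode, "kept": sorted(self.kept), "dropped": self.dropped},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def apply_reference_filters(
    records: Sequence[SequenceRecord], mode: str = "complete"
) -> FilterReport:
    """Apply the curation criteria in a fixed, documented order.

    (i) drop 5'-incomplete sequences (missing >= 40 bases in ``complete``
    mode, > 10 in ``long`` mode); (ii) keep at most two sequences per species,
    preferring longer ungapped residues, ties broken by lexicographic id;
    (iii) within a genus, drop genus-level ("sp.") records when species-level
    records remain; (iv) drop families left with fewer than two species-level
    units (all "sp." records of a genus count as one unit). Idempotent.
    """
    if mode not in ("complete", "long"):
        raise ValueError(f"mode must be 'complete' or 'long', got {mode!r}")

    dropped: dict[str, str] = {}
    pool = list(records)

    # (i) 5'-coverage
    kept1 = []
    for r in pool:
        if mode == "complete" and r.missing_5prime >= 40:
            dropped[r.id] = "7"
        elif mode == "long" and r.missing_5prime > 10:
            dropped[r.id] = "LONG"
        else:
            kept1.append(r)

    # (ii) per species: longer sequences win over shorter ones (criterion 1),
    # then at most two of the longest are kept (criterion 4, ties broken by
    # lexicographic id); genus-level records are grouped per (genus, 'sp.')
    by_species: dict[tuple[str, str], list[SequenceRecord]] = {}
    for r in kept1:
        by_species.setdefault((r.genus, r.species), []).append(r)
    kept2 = []
    for group in by_species.values():
        longest = max(r.ungapped_length for r in group)
        survivors = []
        for r in group:
            if r.ungapped_length < longest:
                dropped[r.id] = "1"
            else:
                survivors.append(r)
        survivors.sort(key=lambda r: r.id)
        kept2.extend(survivors[:2])
        for r in survivors[2:]:
            dropped[r.id] = "4"

    # (iii) species-level preferred over genus-level within a genus
    genera_with_species = {r.genus for r in kept2 if r.is_species_level()}
    kept3 = []
    for r in kept2:
        if not r.is_species_level() and r.genus in genera_with_species:
            dropped[r.id] = "2"
        else:
            kept3.append(r)

    # (iv) families need >= 2 species-level units
    units: dict[str, set[tuple[str, str]]] = {}
    for r in kept3:
        unit = (r.genus, r.species if r.is_species_level() else "sp.")
        units.setdefault(r.family, set()).add(unit)
    kept4 = []
    for r in kept3:
        if len(units[r.family]) < 2:
            dropped[r.id] = "6"
        else:
            kept4.append(r)

    report = FilterReport(
        kept=sorted(r.id for r in kept4), dropped=dropped, mode=mode
    )
    report.validate([r.id for r in records])
    return report
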