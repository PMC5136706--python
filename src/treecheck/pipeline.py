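"""Orchestration of the full evaluation design.

One configuration drives the complete -> "filtered" -> "long" dataset
progression across several analyses (internally inferred NJ trees and/or
imported support-annotated trees), producing per-analysis family resolution
records, a count matrix of fully resolved families (datasets x analyses),
coded per-family deltas between consecutive stages, the rogue report that
feeds the filtered stage, and - when queries are configured - OTU assignment
reports on the final-stage reference set. Every output embeds the config
hash, seed and software version; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clade_resolution import (
    DEFAULT_TAU,
    DeltaRecord,
    ResolutionRecord,
    compare_analyses,
    resolution_summary,
)
from .distance_nj import bootstrap_support, root_tree
from .io_formats import (
    Alignment,
    TaxonomyTable,
    apply_reference_filters,
    attach_taxonomy,
    read_fasta,
    read_tree,
)
from .otu_assignment import AssignmentRecord, assignment_report
from .otu_assignment import to_frame as assignments_to_frame
from .rogue_detection import consistent_rogues, rogue_ids
from .rogue_detection import to_frame as rogues_to_frame
from .tree import SupportTree

STAGES = ("complete", "filtered", "long")


@dataclass
class AnalysisInput:
    """One analysis: either an aligned FASTA for internal NJ inference, or an
    externally inferred support-annotated tree (e.g. from a maximum
    likelihood run)."""

    label: str
    alignment: Alignment | None = None
    tree: SupportTree | None = None

    def __post_init__(self) -> None:
        if (self.alignment is None) == (self.tree is None):
            raise ValueError(f"{self.label}: provide exactly one of alignment/tree")


@dataclass
class EvalConfig:
    analyses: list[AnalysisInput]
    taxonomy: TaxonomyTable
    outgroup: str
    tau: float = DEFAULT_TAU
    n_boot: int = 1000
    seed: int = 0
    rule: str = "nested-whole-taxa"
    rogue_threshold: float = 1.0
    stages: tuple[str, ...] = STAGES
    query_alignment: Alignment | None = None  # queries, same coordinates as refs

    def __post_init__(self) -> None:
        labels = [a.label for a in self.analyses]
        if len(set(labels)) != len(labels):
            raise ValueError("analysis labels must be unique")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    def hash(self) -> str:
        payload = {
            "analyses": [a.label for a in self.analyses],
            "outgroup": self.outgroup,
            "tau": self.tau,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "rule": self.rule,
            "rogue_threshold": self.rogue_threshold,
            "stages": list(self.stages),
            "n_queries": 0 if self.query_alignment is None else len(self.query_alignment),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StageResult:
    stage: str
    kept_ids: list[str]
    records: dict[str, list[ResolutionRecord]]  # analysis label -> records
    counts: dict[str, dict[str, int]]
    trees: dict[str, SupportTree]


@dataclass
class ReportBundle:
    stages: list[StageResult]
    count_matrix: pd.DataFrame  # rows: stages, cols: analyses, values: fully resolved
    deltas: dict[tuple[str, str, str], list[DeltaRecord]]  # (from, to, label)
    rogue_records: list
    rogue_exclusions: list[str]
    assignments: list[AssignmentRecord] = field(default_factory=list)
    assignment_counts: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.count_matrix.to_csv(out / "counts.tsv", sep="\t")
        for stage in self.stages:
            for label, recs in stage.records.items():
                df = pd.DataFrame(
                    [
                        {
                            "family": r.family,
                            "status": r.status.value,
                            "support": r.support,
                            "fully_resolved": r.fully_resolved,
                            "n_members": r.n_members,
                            "intruders": ";".join(r.intruder_ids),
                        }
                        for r in recs
                    ]
                )
                df.to_csv(out / f"resolution_{stage.stage}_{label}.tsv", sep="\t", index=False)
        for (frm, to, label), deltas in self.deltas.items():
            df = pd.DataFrame(
                [
                    {
                        "family": d.family,
                        "from": d.from_status.value,
                        "to": d.to_status.value,
                        "change": d.formatted,
                    }
                    for d in deltas
                ]
            )
            df.to_csv(out / f"delta_{frm}_to_{to}_{label}.tsv", sep="\t", index=False)
        if self.rogue_records:
            rogues_to_frame(self.rogue_records).to_csv(
                out / "rogues.tsv", sep="\t", index=False
            )
        if self.assignments:
            assignments_to_frame(self.assignments).to_csv(
                out / "assignments.tsv", sep="\t", index=False
            )
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "provenance": self.provenance,
                    "counts": {
                        s.stage: {lbl: c for lbl, c in s.counts.items()}
                        for s in self.stages
                    },
                    "rogues": self.rogue_exclusions,
                    "assignment_counts": self.assignment_counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _analysis_seed(base: int, stage_idx: int, analysis_idx: int) -> int:
    # simple arithmetic derivation keeps seeds small, distinct and stable
    return (base * 1009 + stage_idx * 101 + analysis_idx + 1) % (2**31 - 1)


def _tree_for(
    analysis: AnalysisInput,
    keep_ids: list[str],
    outgroup: str,
    n_boot: int,
    seed: int,
) -> SupportTree:
    wanted = set(keep_ids) | {outgroup}
    if analysis.alignment is not None:
        missing = wanted - set(analysis.alignment.ids)
        if missing:
            raise ValueError(
                f"{analysis.label}: ids absent from alignment: {sorted(missing)[:5]}"
            )
        sub = analysis.alignment.subset(wanted)
        tree = bootstrap_support(sub, n_replicates=n_boot, seed=seed)
        return root_tree(tree, outgroup)
    tree = analysis.tree
    if outgroup not in tree.leaf_names:
        raise ValueError(f"{analysis.label}: outgroup {outgroup!r} missing from tree")
    extra = set(tree.leaf_names) - wanted
    if extra:
        tree = tree.prune(extra)
    return tree if tree.rooted else tree.root_on(outgroup)


def run_evaluation(config: EvalConfig) -> ReportBundle:
    """Run the staged evaluation; see module docstring."""
    taxonomy = config.taxonomy
    outgroup = config.outgroup

    # records available for filtering come from the first alignment-based
    # analysis (all analyses share the taxon universe)
    base_records = None
    for a in config.analyses:
        if a.alignment is not None:
            base_records = attach_taxonomy(a.alignment.records, taxonomy)
            break
    ingroup_records = (
        [r for r in base_records if r.id != outgroup] if base_records else None
    )

    stage_results: list[StageResult] = []
    deltas: dict[tuple[str, str, str], list[DeltaRecord]] = {}
    rogue_records: list = []
    exclusions: list[str] = []

    current_ids: list[str] | None = None
    for s_idx, stage in enumerate(config.stages):
        if ingroup_records is not None:
            if stage == "complete":
                report = apply_reference_filters(ingroup_records, "complete")
                current_ids = list(report.kept)
            elif stage == "filtered":
                current_ids = [x for x in current_ids if x not in exclusions]
            else:  # long
                pool = [r for r in ingroup_records if r.id in set(current_ids)]
                report = apply_reference_filters(pool, "long")
                current_ids = list(report.kept)
        else:
            # imported trees only: curation uses the taxonomy metadata
            leaves = set()
            for a in config.analyses:
                leaves |= set(a.tree.leaf_names)
            leaves.discard(outgroup)
            if stage == "complete" or current_ids is None:
                current_ids = sorted(
                    x
                    for x in leaves
                    if x not in taxonomy
                    or int(taxonomy._by_id[x].get("missing5p", 0) or 0) < 40
                )
            elif stage == "filtered":
                current_ids = [x for x in current_ids if x not in exclusions]
            else:  # long
                current_ids = [
                    x
                    for x in current_ids
                    if x not in taxonomy
                    or int(taxonomy._by_id[x].get("missing5p", 0) or 0) <= 10
                ]

        records_by_label: dict[str, list[ResolutionRecord]] = {}
        counts_by_label: dict[str, dict[str, int]] = {}
        trees_by_label: dict[str, SupportTree] = {}
        for a_idx, analysis in enumerate(config.analyses):
            tree = _tree_for(
                analysis,
                current_ids,
                outgroup,
                config.n_boot,
                _analysis_seed(config.seed, s_idx, a_idx),
            )
            recs, counts = resolution_summary(
                tree, taxonomy, tau=config.tau, rule=config.rule, outgroup=outgroup
            )
            records_by_label[analysis.label] = recs
            counts_by_label[analysis.label] = counts
            trees_by_label[analysis.label] = tree

        stage_results.append(
            StageResult(stage, list(current_ids), records_by_label, counts_by_label, trees_by_label)
        )

        if stage == "complete" and "filtered" in config.stages:
            rogue_records = consistent_rogues(
                [(t, lbl) for lbl, t in trees_by_label.items()],
                taxonomy,
                threshold=config.rogue_threshold,
                outgroup=outgroup,
            )
            exclusions = rogue_ids(rogue_records)

    for prev, cur in zip(stage_results, stage_results[1:]):
        for label in prev.records:
            d, _, _ = compare_analyses(
                prev.records[label], cur.records[label], tau=config.tau
            )
            deltas[(prev.stage, cur.stage, label)] = d

    count_matrix = pd.DataFrame(
        {
            a.label: [s.counts[a.label]["n_mono_resolved"] for s in stage_results]
            for a in config.analyses
        },
        index=[s.stage for s in stage_results],
    )

    assignments: list[AssignmentRecord] = []
    assignment_counts: dict[str, int] = {}
    if config.query_alignment is not None:
        final = stage_results[-1]
        ref_analysis = next(
            (a for a in config.analyses if a.alignment is not None), None
        )
        if ref_analysis is None:
            raise ValueError("query assignment needs an alignment-based analysis")
        refs = ref_analysis.alignment.subset(set(final.kept_ids) | {outgroup})
        combined = refs.concat_rows(config.query_alignment)
        seed = _analysis_seed(config.seed, len(config.stages), 0)
        combined_tree = root_tree(
            bootstrap_support(combined, n_replicates=config.n_boot, seed=seed),
            outgroup,
        )
        assignments, assignment_counts = assignment_report(
            combined_tree,
            taxonomy,
            config.query_alignment.ids,
            tau=config.tau,
            rule=config.rule,
            outgroup=outgroup,
        )

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "n_boot": config.n_boot,
        "tau": config.tau,
        "rule": config.rule,
    }
    return ReportBundle(
        stages=stage_results,
        count_matrix=count_matrix,
        deltas=deltas,
        rogue_records=rogue_records,
        rogue_exclusions=exclusions,
        assignments=assignments,
        assignment_counts=assignment_counts,
        provenance=provenance,
    )


# ------------------------------------------------------------------ YAML entry
def load_config(path) -> EvalConfig:
    """Build an EvalConfig from a YAML file of paths and parameters."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent

    def _p(rel):
        p = Path(rel)
        return p if p.is_absolute() else base / p

    taxonomy = TaxonomyTable.read(_p(raw["taxonomy"]))
    analyses = []
    for item in raw["analyses"]:
        label = item["label"]
        if "alignment" in item:
            analyses.append(AnalysisInput(label, alignment=read_fasta(_p(item["alignment"]))))
        elif "tree" in item:
            analyses.append(AnalysisInput(label, tree=read_tree(_p(item["tree"]))))
        else:
            raise ValueError(f"analysis {label!r} needs 'alignment' or 'tree'")
    query_alignment = (
        read_fasta(_p(raw["queries"])) if raw.get("queries") else None
    )
    return EvalConfig(
        analyses=analyses,
        taxonomy=taxonomy,
        outgroup=raw["outgroup"],
        tau=float(raw.get("tau", DEFAULT_TAU)),
        n_boot=int(raw.get("n_boot", 1000)),
        seed=int(raw.get("seed", 0)),
        rule=raw.get("rule", "nested-whole-taxa"),
        rogue_threshold=float(raw.get("rogue_threshold", 1.0)),
        stages=tuple(raw.get("stages", STAGES)),
        query_alignment=query_alignment,
    )
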