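"""Scaled-down study designs exercising the whole pipeline on synthetic data.

Each experiment uses a 20-family x 4-taxon reference set with a 400 nt
barcode and 200 bootstrap replicates - small enough to run on one CPU in
seconds while keeping family clades realistically separated - and returns
the quantities the full study design reports: fully-resolved family counts,
rogue-detection recall, support changes under 5'-truncation, and OTU
assignment accuracy. Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .clade_resolution import ResolutionRecord, Status, resolution_summary
from .distance_nj import bootstrap_support, root_tree
from .io_formats import Alignment, TaxonomyTable, apply_reference_filters
from .otu_assignment import assignment_report
from .rogue_detection import consistent_rogues, rogue_ids
from .synthetic_data import OUTGROUP_ID, SequenceRecord, SimConfig, simulate_dataset

N_BOOT = 200


def base_config(seed: int, **overrides) -> SimConfig:
    cfg = SimConfig(
        n_families=20,
        members_min=4,
        members_max=4,
        barcode_length=400,
        n_mislabel=0,
        n_truncate=0,
        n_queries=0,
        seed=seed,
    )
    return replace(cfg, **overrides)


def _true_taxonomy(ds) -> TaxonomyTable:
    rows = []
    for r in ds.alignment.records:
        fam = ds.truth.family_by_id.get(r.id, r.family)
        rows.append(SequenceRecord(r.id, r.residues, fam, r.genus, r.species, r.missing_5prime))
    return TaxonomyTable.from_records(rows)


def _run(alignment: Alignment, taxonomy, seed: int, n_boot: int = N_BOOT):
    tree = root_tree(bootstrap_support(alignment, n_boot, seed=seed), OUTGROUP_ID)
    records, counts = resolution_summary(tree, taxonomy, outgroup=OUTGROUP_ID)
    return tree, records, counts


def mean_mono_support(records: list[ResolutionRecord]) -> float:
    sups = [r.support for r in records if r.status is Status.MONO and r.support is not None]
    return float(np.mean(sups)) if sups else float("nan")


# --------------------------------------------------------------- experiments
@dataclass
class CleanRun:
    n_families: int
    n_fully_resolved: int
    mean_mono_support: float
    records: list
    tree: object
    dataset: object


def clean_design(seed: int, n_boot: int = N_BOOT) -> CleanRun:
    """Reference set with no corruption: how many families come out
    monophyletic with bootstrap support >= 70?"""
    ds = simulate_dataset(base_config(seed))
    tree, records, counts = _run(ds.alignment, ds.taxonomy, seed + 10_000, n_boot)
    return CleanRun(
        n_families=ds.config.n_families,
        n_fully_resolved=counts["n_mono_resolved"],
        mean_mono_support=mean_mono_support(records),
        records=records,
        tree=tree,
        dataset=ds,
    )


@dataclass
class MislabelRun:
    n_injected: int
    clean_fully_resolved: int
    corrupted_fully_resolved: int
    restored_fully_resolved: int
    n_detected: int
    n_true_positives: int
    n_false_positives: int
    recall: float


def mislabel_experiment(seed: int, n_mislabel: int = 5, n_boot: int = N_BOOT) -> MislabelRun:
    """Inject mislabeled references, detect them as rogues (misplacement rate
    1.0 on the NJ tree), and re-run after removing the detected set.

    Mislabeling touches labels only, so the clean and corrupted analyses
    share one tree; the restored analysis rebuilds the tree without the
    detected rogues, as the staged design does.
    """
    ds = simulate_dataset(base_config(seed, n_mislabel=n_mislabel))
    clean_tax = _true_taxonomy(ds)
    tree, _, counts_clean = _run(ds.alignment, clean_tax, seed + 10_000, n_boot)
    _, counts_corr = resolution_summary(tree, ds.taxonomy, outgroup=OUTGROUP_ID)

    detected = rogue_ids(
        consistent_rogues([(tree, "nj")], ds.taxonomy, threshold=1.0, outgroup=OUTGROUP_ID)
    )
    injected = set(ds.truth.mislabeled_ids)
    tp = len(injected & set(detected))

    kept = [r.id for r in ds.alignment.records if r.id not in set(detected)]
    restored_aln = ds.alignment.subset(kept)
    _, _, counts_restored = _run(restored_aln, ds.taxonomy, seed + 20_000, n_boot)

    return MislabelRun(
        n_injected=n_mislabel,
        clean_fully_resolved=counts_clean["n_mono_resolved"],
        corrupted_fully_resolved=counts_corr["n_mono_resolved"],
        restored_fully_resolved=counts_restored["n_mono_resolved"],
        n_detected=len(detected),
        n_true_positives=tp,
        n_false_positives=len(detected) - tp,
        recall=tp / n_mislabel if n_mislabel else 1.0,
    )


@dataclass
class TruncationRun:
    clean_fully_resolved: int
    truncated_fully_resolved: int
    long_fully_resolved: int
    clean_mean_mono_support: float
    truncated_mean_mono_support: float
    n_truncated: int


def truncation_experiment(seed: int, n_boot: int = N_BOOT) -> TruncationRun:
    """5'-truncate 30% of references by 50-90% of the barcode, then apply the
    long-dataset filter (missing <= 10 bases) and re-run."""
    cfg = base_config(seed)
    n_refs = cfg.n_families * cfg.members_min
    n_truncate = round(0.3 * n_refs)
    cfg = replace(
        cfg,
        n_truncate=n_truncate,
        truncate_min=cfg.barcode_length // 2,
        truncate_max=int(cfg.barcode_length * 0.9),
    )
    ds = simulate_dataset(cfg)

    # the untruncated alignment from the same simulation (same seed chain)
    from .synthetic_data import evolve_sequences, simulate_family_tree

    tree0, truth0 = simulate_family_tree(cfg)
    clean_aln = evolve_sequences(tree0, cfg, truth=truth0)

    _, clean_recs, counts_clean = _run(clean_aln, ds.taxonomy, seed + 10_000, n_boot)
    _, trunc_recs, counts_trunc = _run(ds.alignment, ds.taxonomy, seed + 10_000, n_boot)

    ingroup = [r for r in ds.alignment.records if r.id != OUTGROUP_ID]
    report = apply_reference_filters(ingroup, "long")
    long_aln = ds.alignment.subset(set(report.kept) | {OUTGROUP_ID})
    _, _, counts_long = _run(long_aln, ds.taxonomy, seed + 20_000, n_boot)

    return TruncationRun(
        clean_fully_resolved=counts_clean["n_mono_resolved"],
        truncated_fully_resolved=counts_trunc["n_mono_resolved"],
        long_fully_resolved=counts_long["n_mono_resolved"],
        clean_mean_mono_support=mean_mono_support(clean_recs),
        truncated_mean_mono_support=mean_mono_support(trunc_recs),
        n_truncated=n_truncate,
    )


@dataclass
class AssignmentRun:
    n_queries: int
    n_identified: int
    n_identified_low_support: int
    n_unidentified: int
    n_correct: int
    n_misassigned: int
    removed_family: str
    removed_n_queries: int
    removed_n_unidentified: int
    removed_n_misassigned: int


def assignment_experiment(seed: int, n_queries: int = 25, n_boot: int = N_BOOT) -> AssignmentRun:
    """Place simulated query OTUs on the reference NJ tree and assign them;
    then drop one query's family from the references and re-assign."""
    ds = simulate_dataset(base_config(seed, n_queries=n_queries))
    query_ids = [q.id for q in ds.queries]
    truth = {q["id"]: q["true_family"] for q in ds.truth.queries}

    combined = ds.alignment.concat_rows(Alignment(ds.queries))
    tree = root_tree(bootstrap_support(combined, n_boot, seed=seed + 10_000), OUTGROUP_ID)
    records, counts = assignment_report(
        tree, ds.taxonomy, query_ids, outgroup=OUTGROUP_ID
    )
    n_correct = sum(
        1
        for r in records
        if r.outcome != "unidentified" and r.family == truth[r.otu_id]
    )
    n_wrong = sum(
        1
        for r in records
        if r.outcome != "unidentified" and r.family != truth[r.otu_id]
    )

    # remove the family of the first query from the references entirely
    removed_family = truth[sorted(query_ids)[0]]
    keep = [
        r.id
        for r in ds.alignment.records
        if ds.truth.family_by_id.get(r.id) != removed_family
    ]
    reduced = ds.alignment.subset(keep).concat_rows(Alignment(ds.queries))
    tree2 = root_tree(
        bootstrap_support(reduced, n_boot, seed=seed + 20_000), OUTGROUP_ID
    )
    orphan_queries = [q for q in query_ids if truth[q] == removed_family]
    records2, _ = assignment_report(tree2, ds.taxonomy, query_ids, outgroup=OUTGROUP_ID)
    by_id = {r.otu_id: r for r in records2}
    removed_unident = sum(
        1 for q in orphan_queries if by_id[q].outcome == "unidentified"
    )
    removed_wrong = len(orphan_queries) - removed_unident

    return AssignmentRun(
        n_queries=n_queries,
        n_identified=counts["identified"],
        n_identified_low_support=counts["identified_low_support"],
        n_unidentified=counts["unidentified"],
        n_correct=n_correct,
        n_misassigned=n_wrong,
        removed_family=removed_family,
        removed_n_queries=len(orphan_queries),
        removed_n_unidentified=removed_unident,
        removed_n_misassigned=removed_wrong,
    )
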