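#!/usr/bin/env python
"""Assign the 25 simulated query OTUs on the combined reference + query tree
and score the outcomes against the simulation truth.

Mirrors the final step of the evaluation design: queries are placed on an NJ
tree of the (long-filtered) references plus queries, each query is assigned
with the other queries masked, and the outcome table distinguishes identified
/ identified-with-low-support / unidentified. Results land in results/.
"""

import json
from pathlib import Path

from treecheck.distance_nj import bootstrap_support, root_tree
from treecheck.io_formats import (
    TaxonomyTable,
    apply_reference_filters,
    attach_taxonomy,
    read_fasta,
)
from treecheck.otu_assignment import assignment_report, to_frame
from treecheck.synthetic_data import OUTGROUP_ID

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
SEED = 7
N_BOOT = 200


def main() -> None:
    refs = read_fasta(SIM / "references.fasta")
    queries = read_fasta(SIM / "queries.fasta")
    taxonomy = TaxonomyTable.read(SIM / "taxonomy.tsv")
    truth = json.loads((SIM / "truth.json").read_text())
    true_family = {q["id"]: q["true_family"] for q in truth["queries"]}

    ingroup = attach_taxonomy(
        [r for r in refs.records if r.id != OUTGROUP_ID], taxonomy
    )
    kept = apply_reference_filters(ingroup, "long").kept
    combined = refs.subset(set(kept) | {OUTGROUP_ID}).concat_rows(queries)

    tree = root_tree(
        bootstrap_support(combined, n_replicates=N_BOOT, seed=SEED), OUTGROUP_ID
    )
    records, counts = assignment_report(
        tree, taxonomy, queries.ids, outgroup=OUTGROUP_ID
    )

    df = to_frame(records)
    df["true_family"] = [true_family[r.otu_id] for r in records]
    df["correct"] = [
        r.outcome != "unidentified" and r.family == true_family[r.otu_id]
        for r in records
    ]
    df.to_csv(RESULTS / "03_assignments.tsv", sep="\t", index=False)

    n_correct = int(df["correct"].sum())
    n_wrong = sum(
        r.outcome != "unidentified" and r.family != true_family[r.otu_id]
        for r in records
    )
    print(df.to_string(index=False))
    print(f"\noutcomes: {counts}")
    print(
        f"correct family: {n_correct}/{len(records)}; misassigned: {n_wrong}"
    )


if __name__ == "__main__":
    main()
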