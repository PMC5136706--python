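# Methods

`treecheck` evaluates how well a barcode-length reference phylogeny resolves
family-level taxa, curates the reference set, and assigns anonymous
metabarcoding OTUs to families from their placement on the tree. This note
documents the models, rules, parameters and numerical conventions, and what
the synthetic benchmark does and does not establish.

## Distance model and tree inference

Pairwise distances use the Kimura two-parameter (K2P) model,

    d = -1/2 · ln((1 - 2P - Q) · sqrt(1 - 2Q)),

where `P` and `Q` are the transition (A↔G, C↔T) and transversion proportions
over the sites compared. Missing data is handled by **pairwise deletion**: a
column counts for a pair only when both sequences carry an unambiguous base;
gaps and ambiguity codes (anything outside A/C/G/T) are treated as missing —
the conservative reading of "pairwise deletion for missing data". The
distance is undefined when the logarithm's argument is ≤ 0 (saturation) or no
comparable sites remain; callers choose between an error (default), NaN, or a
cap. Site counting is exact (0/1 float64 matrix products), so the vectorized
all-pairs path agrees with scalar site classification to machine precision.

Trees are built by canonical Saitou–Nei neighbor joining. Ties in the
Q-criterion are broken by the smallest `(i, j)` index pair of the current
matrix (original taxa keep input order; merged nodes append at the end), so
output is deterministic. Negative NJ branch lengths are retained; writers
offer `clamp_negative` for display. Topology and supports — the quantities
the evaluation uses — are unaffected by negative lengths.

Branch support is the column bootstrap: `B` resamples of alignment columns
(i.i.d. uniform with replacement, one seeded `numpy` generator), an NJ tree
per replicate, and for each internal branch of the tree built on the
*original* alignment the percentage of replicates containing the same
(unrooted) bipartition — supports are mapped onto the original tree, not a
consensus. Replicates in which any pairwise distance is undefined are redrawn
and counted (`meta['n_redrawn']`); the run aborts if redraws exceed
10·B + 100, which distinguishes sporadic saturation from a degenerate
alignment. The conventional replicate count is B = 1000; the test suite and
the bundled analyses use B = 200 (B = 100 where only determinism is probed),
which bounds the Monte-Carlo error of a support value by roughly ±3.5
percentage points — immaterial for a threshold at 70 in these designs.

Trees are rooted on the outgroup's pendant edge (the edge is split in half);
internal-branch supports travel with their bipartitions, so rooting never
changes the multiset of supported splits. Newick input accepts supports as
internal-node labels either as percentages or as proportions (every annotated
value ≤ 1.0 → rescaled ×100); mixed dialects are rejected.

## Family resolution

A family's leaf set `S` is **monophyletic** (MONO) when the leaves under
`MRCA(S)` are exactly `S`; the clade's support is read from the branch
subtending the MRCA. A MONO family is **fully resolved** when that support,
rounded half-up to an integer, is ≥ τ (default τ = 70). A MONO clade without
a support annotation is never fully resolved (absent ≠ 0).

Non-monophyletic families are split into PARA vs POLY by a configurable rule,
because the boundary is a judgment call in practice. The default,
`nested-whole-taxa`, calls PARA exactly when every maximal intruder clade
under the MRCA is a union of *whole* families — the "grade around a nested
family" pattern (e.g. one family paraphyletic with respect to another that
evolved from within it). Scattered single strays therefore make a family
POLY. Alternatives: `single-intruder-clade` (PARA iff exactly one intruder
clade) and `intruder-fraction` (PARA iff intruders are ≤ f of the MRCA clade,
default f = 0.2). Reports always name the rule used. Families with fewer than
two leaves in a tree are NOT_EVALUABLE and excluded from all counts, as a
singleton cannot be non-monophyletic. The designated outgroup is excluded
from label sets.

Changes between two analyses are coded per family: `M` (became MONO), `P`
(lost monophyly), `R` (crossed up through τ), `U` (crossed down), `–` (stayed
non-MONO). The support change is `to − from` when both sides are MONO, `+s`
for a family that becomes MONO at support `s`, and `−s` when monophyly is
lost from support `s`; formatting composes, e.g. `+93 MR`.

## Rogue (problematic-sequence) detection

A reference sequence is *misplaced* on a tree when it falls outside its
family's plurality core. Cores are computed on the **unrooted splits**: the
largest family-pure side. Reading sides rather than rooted clades means a
family forming a grade around one nested family still has a single core —
paraphyly is not misplacement. Size ties are broken first by neighborhood
coherence (number of family members in the smallest clade properly containing
the side) and then toward the side holding the lexicographically smallest id;
ties are flagged in the report. A candidate outside the core is **confirmed**
misplaced only when non-candidate leaves of *other* families separate it from
its core — so a host family's members are not flagged merely because one
mislabeled intruder splits them. Branch lengths and supports play no role.

Across analyses, a leaf's misplacement rate is the mean of its flags; a
**rogue** is a leaf with rate ≥ threshold (default 1.0 — "consistently
misplaced"). The rate is exposed so a human can review borderline cases: in
real studies the tree evidence is combined with visual inspection of the
alignment, which is outside this package's scope. Each rogue's report lists
the families its removal may affect (its own and those it intrudes into).

## Reference-set curation filters

Applied in a fixed, documented order (the source criteria state no order):

1. 5′-coverage: drop sequences missing ≥ 40 bases at the 5′ end of the
   barcode (`complete` mode) or > 10 bases (`long` mode). `missing5p` is
   metadata from the taxonomy table, not inferred from gaps, because
   truncation is measured against the full barcode, which unaligned input
   cannot reveal.
2. Per species, longer sequences win over shorter ones (only the longest
   length class survives), then at most two are kept (lexicographic id
   tie-break).
3. Within a genus, genus-level ("sp.") records are dropped when species-level
   records remain.
4. Families with fewer than two species-level units are dropped (all "sp."
   records of a genus count as one unit).

The filter returns a partition (kept ∪ dropped = input, with the first
criterion that removed each id) and is idempotent.

## OTU assignment

Family resolution is always computed on the reference-only tree (all query
leaves pruned), and each OTU is evaluated with the other queries masked, so
assignments are independent of batch composition and a query can never make a
reference family look paraphyletic during its own assignment.

* **Rule 1 (mono_clade).** The OTU is assigned family F when it lies *within*
  the clade spanned by F's references (the smallest clade containing all of
  F's references also contains the OTU) and F is MONO. Outcome `identified`
  when F's clade support ≥ τ, else `identified_low_support` (kept distinct so
  consumers can pick their own cutoff). "Within" is strict: an OTU attaching
  as sister to the whole family clade is not inside it — this is what
  guarantees that queries whose family is absent from the references are
  never borrowed by the nearest family.
* **Rule 2 (para_grade).** Else, if the OTU lies inside the MRCA span of a
  PARA family F whose grade clade has support ≥ τ, outside every nested
  intruder clade, and some ancestor of the OTU containing only F references
  has support ≥ τ, the OTU is `identified` as F with that subclade's support.
* Otherwise `unidentified` — never guessed. Placement within polyphyletic
  families is deliberately not assigned.

## Synthetic data generator

The generator emulates a curated family-level 18S barcode reference set with
known truth. Defaults (one `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| families × members | 50 × (2–10) | a few hundred references across ~50 family-level taxa |
| barcode length | 400 nt | 5′ rRNA barcode spanning two hypervariable regions |
| within-family height | 0.03 subst/site | congeneric/confamilial 18S divergence |
| between-family height | 0.30 subst/site | deep family-level divergence in the variable regions |
| κ (ts/tv rate ratio) | 2.0 | typical rRNA value |
| variable blocks | 2 × 40 nt, ×4 rate | V1/V2-like hypervariable blocks |
| mislabels | 8 | matches the scale of erroneous references found in curated sets |
| truncations | 60, missing 11–120 nt | spans both curation thresholds (kept by `complete`, dropped by `long`; some dropped by both) |
| queries | 25, extra branch 0.02 | anonymous OTUs derived from known families |

The true tree places one clade per family on a random backbone whose edges
are drawn uniform in [0.5, 1] and rescaled so the mean root-to-tip depth is
the between-family height; the bounded edges guarantee every family a
substantial stem, so families are separated by construction (the uncorrupted
benchmark asks whether inference *recovers* a resolvable signal, not whether
the signal exists). Within-family subtrees are random ultrametric topologies
scaled to the within-family height; an outgroup attaches at the root.

Sequences evolve site-independently under the K2P process (exact
transition-probability matrix per branch, i.i.d. uniform root). The per-site
rate profile (hypervariable blocks ×4) is normalized to mean 1 so branch
lengths keep their expected-substitutions-per-site meaning; consequently the
between-block background evolves below average and the discriminating signal
concentrates in the variable blocks, as in real rRNA — which is also the
mechanism by which 5′-truncation (encoded as leading gaps plus `missing5p`
metadata, interacting with pairwise deletion) degrades support. Mislabeling
changes labels only, never sequences. There are **no indels** — the alignment
is correct by construction, keeping alignment quality (produced by external
tools) out of the tested core — no rate heterogeneity beyond the block
multipliers, no base-composition bias, and no secondary-structure
constraints. Passing tests therefore demonstrate correctness of the
evaluation machinery under a faithful-alignment, clock-like regime; they do
not certify performance on real alignments of hypervariable rRNA, where
alignment error is a dominant factor.

All randomness flows through seeded `numpy` generators with integer-indexed
draws; datasets, bootstrap supports and reports are bit-reproducible for a
given seed and the pipeline is a pure function of (inputs, config, seed).

## Study designs used by the tests and the acceptance script

The end-to-end checks run a scaled-down design — 20 families × 4 taxa, 400 nt,
B = 200 — chosen so each run takes seconds on one CPU while family clades
stay realistically separated: (i) clean recovery (fraction of families fully
resolved); (ii) five injected mislabels → drop in fully resolved count, rogue
recall/false positives at rate 1.0, and recovery after removing the detected
set; (iii) 30% of references truncated by 50–90% of the barcode → drop in
mean monophyly support, then the `long` filter's effect on the fully resolved
count; (iv) 25 simulated queries → fraction assigned to their true family,
misassignments (expected: none), and the orphan-family check (removing a
query's family from the references must leave its queries unidentified). The
bundled `analysis/` drivers run the same machinery at the full default scale
(50 families, ~320 references). The long-filter gain in (iii) is directional
but noisy at this scale: truncation damage competes with family attrition
(families whose full-length members fall below two are excluded by the
filter), so individual seeds can tie.

## Known limitations

* PARA/POLY is not uniquely defined by topology alone; the configurable rule
  covers the common readings but no mechanical rule reproduces every manual
  expert call (hence the rule name in every report).
* Rogue detection is purely topological; it cannot distinguish a mislabeled
  reference from genuine (correctly labeled) placement contradicting the
  classification, and it needs at least a plurality of a family's labels to
  be correct.
* Maximum-likelihood trees are consumed as support-annotated Newick, not
  inferred.
* The generator's clean alignments make bootstrap supports optimistic
  relative to real barcode alignments.
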