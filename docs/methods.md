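# Methods

This note records the measurement definitions, the conventions chosen where
a definition is genuinely open, what the synthetic-data generators emulate,
and the limits of what the tests demonstrate.

## Gene-structure accuracy

Structures are compared as parsed from GTF/GFF3, with 1-based inclusive
coordinates and CDS features by default (`feature_kind="exon"` is available
for annotations without CDS rows). Unstranded (`.`) rows of the selected
feature type are rejected: an unstranded coding interval cannot be matched
meaningfully.

* **Exon level** uses set semantics: a coding interval annotated in several
  transcripts counts once per annotation set. Counting with multiplicity is
  the other defensible convention; it differs only on duplicated intervals
  and would couple exon counts to isoform inflation, which set semantics
  avoids.
* **Transcript level** requires exact equality of the full coordinate
  chain, sequence id and strand included — no partial credit, no UTRs.
* **Gene level** is asymmetric by construction: the sensitivity TP counts
  reference genes with at least one chain present anywhere in the
  prediction, the precision TP counts predicted genes with at least one
  chain present in the reference. `EvalCounts.tp_predicted` carries the
  second number.
* Zero denominators (empty inputs, no matches) yield Sn/Pr/F1 = 0 rather
  than an exception, so cohort sweeps never abort; F1 is 0 when
  Pr + Sn = 0.
* GTF dialects disagree on whether the stop codon is inside the terminal
  CDS. Inputs are compared as parsed; `trim_stop_codons` (CLI
  `--trim-stop 3`) shortens the translation-terminal CDS of every
  transcript — the last interval on `+`, the first on `-` — when the user
  knows the dialects differ.

The implementation is validated two ways on every synthetic annotation
pair: against an O(n²) pairwise-comparison oracle that uses no set
machinery, and against truth counts the generator tallied constructively
while writing the files.

## Taxon selection

The objective of a leaf set is the total branch length of the union of its
root paths, each edge counted once; the root has no incoming edge and
contributes 0. Every edge must carry a length — taxonomy trees derived
from rank hierarchies use the integer number of levels a branch spans, but
any non-negative lengths are accepted.

`select_max_diversity` is greedy: anchors enter first (sorted), then each
step adds the leaf with the largest marginal gain, breaking ties toward
the lexicographically smallest label so runs are reproducible. On trees
this objective is monotone and submodular and the greedy choice is exact;
`brute_force_select` (exhaustive over all subsets, guarded to ≤ 20 leaves)
confirms greedy = optimum on every tested instance, so the toolkit reports
the greedy result as the optimum while keeping both entry points.

## GO agreement

Coverage treats a protein as annotated when it has ≥ 1 GO term; proteins
with no terms are absent from a `GOAnnotationMap` by contract.

The relaxed criterion declares two terms agreeing when they share an
ancestor reachable within `max_levels` (default 3) upward steps from
**each** term — the joint reading; the alternative ("near at least one")
would make agreement near-universal in a shallow DAG. A level is the
minimum path length over the DAG's multiple routes up. A term is its own
ancestor at level 0, so exact matches of non-root terms imply relaxed
agreement and the relaxed rate can never undercut the exact rate when
roots are excluded. Roots — the parentless terms of the loaded ontology —
are excluded from the candidate-ancestor set by default (they still count
for coverage); `exclude_roots=False` restores them.

Whether `part_of` edges participate is fixed when the ontology is loaded
(`parse_obo(include_part_of=True)`); the agreement functions see a single
parent relation. Rates are computed per protein over the co-annotated set;
a co-annotated protein whose terms are all unknown to the loaded ontology
on one side counts as not agreeing under the relaxed criterion (the exact
criterion, a pure set operation, is unaffected). Gene-level rates can be
obtained by collapsing maps to longest-isoform ids before calling the
summary functions.

Agreement under a specific public GO release depends on that release's
topology; the relaxed rate is therefore reproducible only relative to the
ontology file supplied.

## Tree comparison

Trees are compared unrooted: the canonical split form (the side not
containing a fixed reference leaf) makes the two edges of a degree-2 root
encode one split. Only non-trivial splits (≥ 2 leaves on both sides)
participate. Multifurcations simply contribute fewer splits. Both
shared-fraction normalizations are reported because published
"% of splits shared" statements rarely name a denominator; the sum-based
form is the complement of the classic normalized RF distance and the two
coincide exactly when the split sets are equal. `prune_to_common` restricts
both trees to their shared leaf set before extraction.

## Cohort statistics

Quartiles use linear interpolation between order statistics (numpy's
default percentile rule) and the median of an even-sized sample is the
mean of the two middle values; IQRs under other quantile conventions can
differ by a few percent on small cohorts.

tRNA conventions: a record is a pseudogene when its note column contains
the substring "pseudo", and "confirmed" means not-pseudogene — no
additional score or isotype exclusion is applied. Density is confirmed
tRNAs per Mbp. Occupancy sums `|end − begin| + 1` over **all** rows
(reverse-strand rows, stored begin > end, contribute positively) including
pseudogenes, divided by genome size. Intron percentage is among confirmed
tRNAs; isotype shares are among confirmed tRNAs; selenocysteine and
suppressor presence are flags per species, aggregated as the fraction of
species with the flag set.

## Synthetic-data generators

Every generator is a pure function of its parameters and an explicit seed
(`random.Random`; regeneration is byte-identical) and emits truth computed
with plain set/arithmetic logic inside the generator, never by calling the
analysis code it will validate.

* `make_annotation_pair` plants exact copies, CDS boundary shifts
  (1–10 bp into reserved inter-gene slack, so no accidental collisions),
  dropped CDS and novel genes, and recounts TP/FP/FN at all three levels
  from the emitted unit sets.
* `make_taxonomy_tree` builds random 2–3-ary rooted trees with integer
  branch lengths in `[1, max_depth]`, emulating level-count taxonomies.
* `make_ontology` grows an acyclic `is_a` DAG whose namespace components
  (one per root, cycling BP/MF/CC) never connect — cross-namespace term
  pairs share no ancestor, which the disagreement planting relies on.
* `make_go_maps` plants per-protein outcomes: exact agreement (shared
  non-root term), relaxed-only agreement (siblings under a shared non-root
  parent — within 3 levels, no shared term), and disagreement
  (cross-namespace terms). Its default probabilities describe the target
  cohort conditions: coverage partition 56.5% both / 39.4% only-A /
  4.1% only-B, 80.8% exact and 94.2% relaxed agreement among co-annotated
  proteins.
* `make_tree_pair` applies a known number of NNI moves to a random binary
  tree; each move rewrites exactly one internal split, so RF ≤ 2·moves
  (with equality for one move). Defaults (200 leaves, 10 moves) emulate a
  pair of cohort-scale species trees agreeing on ~95% of their splits.
* `make_trna_table` draws species around insect-genome medians: ~3.6
  confirmed tRNAs per Mbp on log-normal genome sizes with median
  ~135 Mbp (hence ~489 confirmed tRNAs and ~0.03% occupancy at the
  median), a wide pseudogene proportion centred near 20%, ~7% intron
  fraction, SeC in 46% and suppressor tRNAs in 42.5% of species, and
  isotype shares led by Ser/Ala/Gly/Arg/Leu.

What the generators do **not** emulate: real sequence content, overlapping
or nested gene models, trans-splicing, GTF attribute dialect quirks beyond
`gene_id`/`transcript_id`, ontology cross-products between namespaces,
correlated errors between the two GO pipelines, or assembly fragmentation.
Passing tests therefore demonstrate that the metrics are computed exactly
as defined on well-formed inputs, not that any upstream annotation
pipeline achieves particular accuracy on real genomes.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen so the whole suite completes in seconds: 100 annotation pairs of
12–20 genes for oracle equivalence, 200 selection instances on ≤ 12-leaf
trees (exhaustive enumeration stays cheap), 100 random DAGs of ≤ 50 terms
for the relaxed-agreement oracle, split enumeration cross-checks on ≤ 16
leaves, and 200-species cohorts for the GO, tree and tRNA summaries.

## Known limitations

* GFF3 parsing covers the gene → mRNA/transcript → CDS/exon hierarchy with
  `ID`/`Parent`/`Ontology_term`; discontinuous features sharing one ID and
  other GFF3 generality are out of scope.
* The greedy/brute-force equivalence is verified on trees; on arbitrary
  matroid-free structures greedy submodular maximization is only a
  (1 − 1/e)-approximation, so the exactness claim is specific to
  tree-induced objectives.
* Robinson–Foulds comparison is topology-only; branch-length-weighted
  variants and quartet distances are not implemented.
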