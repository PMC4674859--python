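# Methods

## Scope and data model

The package consumes BioNLP-ST standoff annotations: per document a `.txt`
file with the raw text, a `.a1` file with entity mentions
(`Tid<TAB>Type start end<TAB>surface`), and a `.a2` file with event
triggers and event lines (`Eid<TAB>Type:Ttrig Theme:X Cause:Y`). Offsets
are 0-based, half-open, and counted in characters, which avoids encoding
ambiguity and matches the convention of GENIA-style extractors. The event
inventory is the nine GE types (gene expression, transcription, protein
catabolism, phosphorylation, localization, binding, and the three
regulation types). Arguments may be mentions or nested events; parsers
reject dangling references and cycles rather than repairing them, and a
mention whose surface disagrees with the document slice is an integrity
error, never silently fixed. Roles outside Theme/Cause (e.g. the Site of
a phosphorylation) are parsed and re-emitted but carry no interaction
semantics.

Two mapping tables stand behind normalization: a gene lexicon
(`surface → Entrez ID`) and a pathway database whose records carry a
canonical ID, a canonical name, `(source_db, synonym)` pairs and member
Entrez IDs. Records sharing a canonical ID union their synonym and member
sets, reflecting that integrative pathway resources hold several
representations of e.g. the Wnt signaling pathway (KEGG, WikiPathways,
PID, BioCarta) that should act as one node.

## Pathway mention recognition

Two recognizers are combined and their overlapping candidates resolved by
longest-span-wins (ties to the smaller start offset), because pathway
mentions must never overlap:

- **Soft matching.** Every token window (up to `max_entity_tokens` content
  tokens, default 5) is normalized — lowercased, split on
  whitespace/slash/hyphen, pathway head terms removed — and scored
  against every synonym by token-set Jaccard. Windows at or above
  `similarity_threshold` (default 0.8) become candidates; at threshold
  1.0 the matcher degenerates to exact normalized matching, which is how
  it is cross-checked in the tests. The same normalization and score are
  reused to normalize pathway mentions, so recognition and normalization
  cannot disagree about what "close" means. Jaccard of an empty token set
  is defined as 0 so that a bare head term ("the pathway") can never
  match anything.
- **Head-term rule.** An occurrence of a head term (`pathway`,
  `signaling`, `signalling`, `cascade`, `signal transduction`; multi-word
  terms are matched as token sequences) extends left over at most
  `max_entity_tokens` contiguous entity-like tokens — tokens with an
  uppercase letter, a digit, a slash/hyphen compound, or a Greek letter
  (so `Wnt/β-catenin` counts as one entity token). A head term with no
  entity-like token to its left is dropped.

Gene mentions frequently nest inside pathway names, so before event
extraction all mentions are merged: overlap (≥ 1 shared character,
containment included) is treated transitively, and each connected
component collapses to a single mention spanning the interval union.
A component containing at least one pathway mention becomes a pathway
mention; gene-only overlap components collapse to one gene mention, which
keeps the output overlap-free in all cases. The merge is idempotent and
insensitive to input order.

## The disguise bridge

Gene-only extractors accept only `Protein` entities. Merged mentions are
therefore renumbered `T1..Tn` and all written as `Protein`, with a
sidecar recording which IDs are really pathways (and their spans, as a
consistency check). After extraction, the sidecar restores the `Pathway`
class on those mentions throughout nested event structures. The
composition is the identity on entity classes and the restore step is
idempotent; a span mismatch between sidecar and mention is an integrity
error.

## Normalization and the discard rule

Gene mentions normalize by exact lookup after case folding; there is
deliberately no fuzzy gene matching, since unmapped gene mentions are
treated as likely NER false positives and fuzziness would re-admit them.
Pathway mentions normalize to the best-scoring synonym at or above the
threshold, ties broken by lexicographically smallest canonical ID for
determinism.

Events are then filtered twice:

1. **Type validity.** Pathways cannot take part in gene expression,
   transcription, protein catabolism, phosphorylation, localization or
   binding; an event with a pathway participant anywhere in its argument
   tree is valid only if its own type and the type of every sub-event on
   the path to that pathway are regulation types.
2. **Normalizability.** An event is kept only if *every* mention
   participant, gathered recursively through nested arguments,
   normalizes. Discarding is all-or-nothing per event — one bad mention
   in a nested sub-event discards the whole top-level event — and each
   discard is logged as `doc_id, event_id, reason, surface`.

Kept events are passed through unchanged, so |kept| + |discarded| always
equals the input count.

## From events to pairs

Nested arguments are expanded recursively to their participating entity
sets. A regulation event with a cause yields the cross product of the
cause-side and theme-side participant sets (self-pairs removed) with the
event type as category; a regulation event without a cause yields
nothing. A binding event yields all unordered pairs over its distinct
theme participants (duplicated themes are collapsed first; fewer than two
distinct themes yield nothing). The cross product is the maximal faithful
reading when a side has several participants, and it reduces to a single
pair in the common one-cause/one-theme case. Pathway–pathway pairs are
allowed: regulatory interplay between two pathways is exactly the kind of
statement this pipeline exists to capture. Directionality is ignored
throughout; pairs compare equal regardless of endpoint order and
deduplicate corpus-wide on (unordered node pair, category), merging
`(doc_id, event_id)` provenance. The uniqueness key's category component
is configurable (`key_includes_category=False` collapses on the node pair
alone) since either convention is defensible for corpus-level counting.

## Network construction and topology

Nodes are typed keys — `("GENE", entrez)` and `("PATHWAY", canonical_id)`
— printed in SIF as the bare Entrez integer and a `PW:`-prefixed
canonical ID so the namespaces cannot collide. The network is a
multigraph: one text-mined edge per unique pair (relation `reg`,
`pos_reg`, `neg_reg` or `binding`) plus one curated `member_of` edge for
every gene node contained in a co-present pathway node. A text-mined edge
and a membership edge between the same endpoints coexist; that is what
the multi-edge node-pair statistic counts. An `expand_members` flag
additionally pulls in member genes of present pathways as new nodes,
for the network variant where curated membership contributes vertices and
not just edges.

Statistics follow the conventions of the Cytoscape NetworkAnalyzer
plugin, computed on the simplified graph (parallel edges collapsed):
clustering coefficient is the mean over all nodes of 2e/(k(k−1)) with
k < 2 contributing 0; diameter and characteristic path length pool
unweighted shortest paths over connected pairs only, so multi-component
networks get finite values; average neighbours is the mean distinct-
neighbour count and density is that mean divided by N−1. On an edgeless
network the path statistics are reported as undefined (`None`/`NA`)
rather than zero. Hubs are ranked by degree with edge multiplicity
counted (a gene joined to a pathway by both regulation and membership is
genuinely better connected); bottlenecks by unnormalized shortest-path
betweenness centrality with fractional credit for tied shortest paths.
All rankings break score ties by ascending node key, so output is
deterministic. Score parity with plugin-specific bottleneck heuristics is
not attempted — betweenness as defined above is the contract.

## Evaluation

Precision is measured on sampled reported events; recall cannot be
measured over the full event space at literature scale, so a
**pseudo-recall** is estimated on a candidate set: all same-document
⟨pathway, gene⟩ mention pairs whose character distance is strictly below
100. Distance is the number of characters strictly between the nearer
span boundaries (0 for adjacent or overlapping spans) — the measurement
convention is not dictated by the threshold itself, so the package fixes
the gap convention and keeps the threshold configurable. Candidates are
enumerated deterministically and sampled uniformly without replacement
under an explicit seed; if fewer than requested qualify, all are returned
with a warning.

Predicted events score against gold by maximum bipartite matching under
an equivalence predicate: same event type and identical per-role
participant sets after nested expansion ("the event and the arguments are
both correct"). TP is the matching size, unmatched predictions are FP,
unmatched gold events FN, and TN is the remainder of the candidate count
when one is supplied. F1 is computed from unrounded precision and
pseudo-recall.

## Synthetic corpora

The generator emits documents from a small template grammar —
`"{C} activates {T}."`, `"Overexpression of {C} inhibits {T}."`,
`"{A} interacts with {B} and {D}."` — with exactly controlled character
offsets, alongside the standoff files, a gene lexicon (`GEN1..GENn` →
Entrez-style IDs) and a pathway database (`PWX1..PWXm` with three-source
synonym sets and random membership). Planted events respect the same
restrictions the pipeline enforces (pathways only in regulation events,
binding themes gene-only), and the planted pair set is computed by an
independent naive walk over the generated events, not by the pipeline
under test. Defaults: 100 documents, 30 genes, 10 pathways, 1–4 events
per document, nesting probability 0.2, binding fraction 0.2, pathway
theme/cause probabilities 0.35/0.15, membership probability 0.2 — sizes
at which a single corpus exercises every template and still runs in
seconds. A configurable fraction of mentions receives surfaces absent
from the lexicons; the generator records both the realized discard count
and the analytic expectation (mean over events of 1−(1−u)^m for m mention
slots), which the calibration test compares across seeds.

The generator deliberately does **not** model realistic English syntax,
extractor error profiles, gene-name ambiguity across species, or noisy
offsets. Passing recovery tests therefore demonstrates that the
post-processing chain is lossless and correct on well-formed
annotations — not that any upstream extractor is accurate on real text.
An `expected_network` reference builder (plain nested loops) provides a
second, independent route to the merged network for dual-implementation
testing.

## Numerical and design choices

- Similarity threshold 0.8 balances synonym variation ("X signaling" vs
  "X signaling pathway" still score 1.0 after head-term stripping)
  against spurious token overlap; it is exposed in every API that uses
  it.
- All tie-breaks (pathway normalization, hub/bottleneck ranking, pair
  ordering) are lexicographic, making every output byte-deterministic;
  writers sort their lines, so identical inputs give identical files.
- Per-document parallelism merges results in sorted doc-id order, so the
  worker count never changes any output byte.
- Degenerate inputs are first-class: empty files parse to empty lists,
  an empty network writes an empty SIF, metrics with zero denominators
  raise an explicit undefined-metric error instead of returning 0.

## Known limitations

- The pathway recognizer is a transparent stand-in for dedicated pathway
  NER systems; no published NER accuracy is claimed for it.
- Gene normalization is table lookup; species disambiguation and
  gene-family resolution are out of scope.
- Event polarity, speculation and negation are ignored, as are Site
  arguments.
- The pipeline consumes extractor output; it does not bundle or learn an
  event extractor.
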