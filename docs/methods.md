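# Methods

## The data model

A model is a directed multigraph. Nodes are *individuals*: instances of
ontology classes, never the classes themselves. Instancing matters
scientifically — a compiled circuit model deliberately carries two serotonin
individuals so that a synaptic pool (HSN→VC) and an extra-synaptic pool
(HSN→VM) remain distinguishable — and it is why identity is never merged
across ingested statements: two rows mentioning *membrane depolarization*
yield two nodes unless a curator merges them explicitly.

Edges are *assertions* with a relation from a fixed registry, a list of
evidence records (ECO class + reference + optional quote; evidence is
edge-level, matching causal-activity-model practice), and a provenance flag
(`asserted` by a curator, `derived` by reasoning). Instance ids are
deterministic (`<classLocalId>#<ordinal>` in insertion order) so that
serializations of the same construction are byte-stable.

Inverse relations (*has part*, *enables*, *is small molecule activator of*)
are canonicalized at assertion time to one stored direction; the inverse is
answered by query, never stored twice. This keeps the validator and the
reasoners single-direction and makes round trips exact.

### Identifier normalization

Published sources are untidy about identifiers: stray spaces (`GO: 0051899`),
thousands separators (`CHEBI: 28,790`), underscore separators (`RO_0002479`),
truncated local ids (`RO:002304`). Every identifier entering the library is
normalized to `PREFIX:LOCALID` with zero-padded fixed-width numeric local
ids where the ontology uses them. Proposed classes with no public id use the
package-local `CeNCAM:` prefix with snake_case local ids; *egg deposition*
(GO:0160027) and *carbon dioxide receptor activity* (GO:0170015) keep their
assigned GO ids. `occurs in` is registered as BFO:0000066.

### The relation registry and signs

The registry is closed and shipped in code: the causal family under
*causally upstream of or within* (RO:0002418 → RO:0002411 → RO:0002304/05 →
RO:0002213/12), the mereological pair, *enabled by*, *occurs in*, the
chemical-participation relations and *has quality*. Two deliberate choices:

- *part of* is classified under RO:0002418 (the agnostic relation is a
  parent of both the causal relations and part/whole), but carries the
  `mereological` category so the validator dispatches it to its own rule
  row, and the *causal* registry subset remains exactly the six causal
  relations.
- Signs live on relations: +1 for the positive-effect lineage, −1 for the
  negative lineage, 0 for the agnostic relations; *part of* transmits
  influence toward the whole without flipping. Signs are undefined (an
  error, not 0) for location/enablement/participation relations — asking
  for the sign of *occurs in* is a category mistake.

## Validation

The validator applies a rule table over (subject aspect, relation family,
object aspect) and returns a list of violations; it never raises. Severity
encodes how normative the underlying convention is: aspect-pair rules stated
as conventions of the data model are **errors** (`BAD_PARTOF`,
`BAD_ENABLED_BY`, `BAD_OCCURS_IN`, `BAD_SMALL_MOL`, `BAD_INPUT_OUTPUT`,
`BAD_QUALITY`, `BAD_CAUSAL_DOMAIN`, plus `BAD_EVIDENCE_CLASS` for a
non-evidence class in an evidence slot), while patterns the corpus tolerates
case-by-case are **warnings**: a causal edge mixing MF and BP aspects
(`CAUSAL_MF_BP`), an evidence-free asserted edge (`UNEVIDENCED`), a *part
of* self-loop (`SELF_PART`). Validation is order-independent (the violation
multiset is a function of the assertion set) and subsumption-aware: a rule
row matched by a relation is matched by every same-family descendant, so
specializing an edge can never introduce a violation.

## Templates

Six generic statement-category templates ship as data (YAML): neuron→
behavior by ablation and by activation, input→neuron→behavior rescue, and
neuron→neuron connections (mechanism-agnostic, synaptic, extra-synaptic
peptidergic — the last built on the proposed signaling classes, since the
public vocabulary has no extra-synaptic term). Instantiation binds each slot
to the slot generic *or one of its is_a descendants*; anything else is
rejected (`BINDING_NOT_SUBSUMED`). Design choices:

- Gene and receptor-activity slots are optional: rescue results whose
  receptor is implied but unidentified instantiate cleanly, with the
  placeholder activity node retained to mark missing information.
- The rescue template's chemical edge accepts *has input* as an alternative
  to *has small molecule activator*, since input statements are modelled
  both ways; edge overrides must descend from the edge generic or a listed
  alternative.
- The category vocabulary (61 labels) maps onto templates partially and
  many-to-one; unmapped categories (G-protein cascades, biosynthesis,
  gene-expression phenomena) are tagging vocabulary only.

The fixture catalog assigns templates to the five single-statement worked
examples and builds them *by* instantiation; the compiled, AND-logic, and
subcellular examples are richer than any one statement template and are
built directly.

## Statement-table ingestion

The TSV dialect is UTF-8, tab-separated, fixed case-insensitive headers
(`Local ID`, `Reference`, `Author Statement`, optional `Categories`, then
alternating `Node i`/`Relation i` columns). Chains have variable length;
trailing empty cells are allowed, an even number of chain cells is a
row-numbered error, and statement text — the only free-text column — is
sanitized of tabs/newlines on write.

The chain is read left-to-right, but *context* links (occurs in, enabled
by, chemical participation, has quality) qualify the current process rather
than extending it: in `[membrane depolarization] occurs in [uv1] part of
[negative regulation of egg deposition]`, the *part of* subject is the
depolarization process, not the cell. Model building therefore keeps a
backbone pointer that context relations do not advance; without this rule
the example above would produce an anatomically ill-typed `uv1 part_of ...`
edge. Causal and mereological links advance the backbone.

Curation statistics count rows as *entries*, distinct local identifiers as
*unique statements* (the supplementary-table convention of one id per
statement repeated across entries; the uniqueness key is a documented choice
since none is stated), and distinct references as *papers*.

## Reasoning

- **Part-of closure** materializes the transitive closure of asserted *part
  of* edges as `derived` assertions; derived edges are never re-fed into the
  closure, making it idempotent, and output is independent of edge order.
- **Net effect** enumerates *simple* directed paths (no node revisits) over
  asserted causal and *part of* edges, the latter traversed only toward the
  whole. A path through a sign-0 causal edge contributes `unknown`;
  otherwise the path contributes its sign product. Aggregation precedence:
  any +/− disagreement yields `ambiguous` even when other paths are
  unknown — disagreement is stronger information than ignorance. The
  source-equals-target case is `positive` via the empty product. A depth
  cap (default 12) guards pathological inputs; curated models are small,
  so exhaustive enumeration is the intended regime. Cyclic feedback is cut
  by the simple-path rule, not resolved by fixpoint semantics.
- **Pattern queries** match a connected variable graph against a model,
  modulo subsumption on both classes and relations, with *injective*
  variable-to-individual assignment (avoiding degenerate self-matches).
  Results are sorted by the answer binding.

## Connectome overlay

Chemical synapses are directed; gap junctions are stored once in
lexicographic order and traversed both ways — whether gap junctions
participate in the connects-with chain is unstated in the domain, and
bidirectional traversal is this package's choice. `connects_with` is the
reflexive-transitive closure minus identity, including direct synapses (the
superproperty reading of the chain rule).

The overlay reads functional signs out of models: behavior effects are net
effects from processes located in a neuron to behavior-class instances;
stimulus responses combine a chemical-activator edge into an activity with
that activity's net effect on a process in the neuron; edge modality is
`synaptic` when a contributing path touches a chemical-synaptic-transmission
instance and `extrasynaptic_or_indirect` otherwise. Ambiguous or unknown
verdicts, and sign conflicts across models, are dropped with a logged audit
entry rather than rendered — the rendering contract has only activating and
inhibiting — and the overlay is independent of model order. Candidate links
are the responder × effector pairs filtered by the connects-with closure.

## The fixture substrate

The embedded ontology is a hand-built subset (~100 terms): every class is
placed under a real ancestor but intermediate levels are elided, so
subsumption queries within the fixture are correct even though the skeleton
is shallower than the public ontologies. Neuron classes beyond the three
with verified WBbt ids, and gene ids in the `WBGene:99xxxxxx` range, are
fixture-local placeholders and are labelled as such in the file. The
mini-connectome is likewise a synthetic, hand-derived edge list among eight
named neurons — illustrative topology, not an EM reconstruction. The
twelve worked-example models attach evidence (experimental phenotypic,
optogenetic, or the proposed assay classes) with citation keys even where a
figure would omit them, so `UNEVIDENCED` warnings stay meaningful on user
data.

The seeded generators are pure functions of their seed. `random_model`
draws edges from valid rule rows, or with probability `p_invalid` from
deliberate single-error breakages, returning the planted error count — the
ground truth the validator must recover exactly. `random_statement_table`
plants curation statistics alongside the TSV. What the generators emulate is
the *typing* structure of curated models (aspects, relation families,
chain shapes), not biological plausibility: passing tests show the
machinery is correct on well-typed and deliberately ill-typed graphs, not
that any particular circuit hypothesis is right, and real curated corpora
additionally contain free-text noise, inter-curator disagreement and
identifier drift that the generators do not model.

## Problem sizes

The test suite and the acceptance script run the validator over 200 seeded
random models (15 nodes, 25 edges), the subsumption-retype property over
1,000 edges, each reasoning oracle over 100 random graphs (≤40 nodes), and
the round-trip properties over 210 cases; the whole suite completes in a few
seconds on one CPU. These sizes were chosen to exercise every rule row and
path-algebra case many times over while staying instant to run.

## Known limitations

- Negative results (a neuron shown *not* necessary for an activity) are not
  representable — the underlying data model has no negation — so some
  findings in any curated corpus cannot be captured.
- No OWL reasoning or consistency checking beyond the rule table; *part of*
  parentage printed for proposed classes is stored as a term annotation,
  not classification.
- No automated extraction of author statements from text; ingestion starts
  at the curated table.
- The printed corpus-level curation counts can only be recomputed from the
  publisher's supplementary tables, which are not redistributable; the
  statistics operation is instead verified against corpora with planted
  accounting of the same shape.
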