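# cencam

Typed causal-activity knowledge graphs of *Caenorhabditis elegans* neural
circuits: a library and CLI for building, validating, and reasoning over
semantic models that link environmental inputs, molecular activities,
cellular processes, neurons, and behaviors.

## The problem

Neurobiological knowledge in *C. elegans* — which neuron drives which
behavior, which receptor responds to which chemical, which connections are
synaptic versus extra-synaptic — is scattered across decades of papers as
prose. Causal-activity modelling turns each curated *author statement* into
semantic triples over standard ontologies: GO molecular functions and
biological processes, WormBase anatomy (WBbt), ChEBI chemicals, ECO evidence
classes, ECTO exposures, and PATO qualities, connected by typed relations
from RO/BFO (*causally upstream of, positive/negative effect*,
*positively/negatively regulates*, *part of*, *enabled by*, *occurs in*,
*has small molecule activator*, *has input/output*, *has quality*).

A model is a multigraph of **individuals** (instances of ontology classes —
two serotonin mentions stay two nodes, so a synaptic and an extra-synaptic
pool can be told apart) and **assertions** (subject–relation–object edges
carrying ECO-classed evidence). The package enforces the data-model
conventions as a validator rule table over *(subject aspect × relation
family × object aspect)*: causal edges link MF→MF or BP→BP, *part of*
builds the MF→BP→behavior composition, *enabled by* is MF→gene, *occurs in*
places activities in cells or cellular components, and so on.

On top of the graphs it computes:

- **part-of closure** — *part of* is transitive; implied edges are
  materialized as `derived` assertions;
- **net causal effect** — each causal relation carries a sign
  (+1 activating lineage, −1 inhibiting, 0 agnostic; *part of* transmits
  toward the whole without flipping); the net effect of node *s* on node
  *t* is the aggregate over all simple directed paths of the per-path sign
  product, with verdicts `positive`, `negative`, `ambiguous` (paths
  disagree), `unknown` (a sign-0 edge on every decisive route), or `none`;
- **subsumption-constrained templates** — six generic statement-category
  models (ablation, activation, rescue, and three neuron-to-neuron
  connection kinds); a template slot accepts the generic class or any is_a
  descendant, never anything else;
- **connectome overlay** — a synapse/gap-junction edge list plus the
  property chain *synapses to ∘ synapses to ⇒ connects with*; per-neuron
  stimulus-response and behavior-effect signs are read out of the models,
  and responder→effector pairs linked in the closure become candidate
  functional links between circuits.

## Worked example

The compiled egg-laying circuit model (`fig5` in the fixture catalog) links
AWC, HSN, VC, and the vulval muscles through serotonin signaling:

```python
from cencam import fixtures, net_effect, validate, overlay, candidate_links

idx = fixtures.builtin_ontology()
m = fixtures.worked_example("fig5")
print(len(m.individuals), len(m.assertions))   # 20 22
print(validate(m, idx))                        # [] — conforms, no warnings

# sign of HSN depolarization on egg-laying behavior
r = net_effect(m, "0051899#1", "0018991#1", idx)
print(r.value)                                 # positive
print(net_effect(m, "0051899#2", "0051899#1", idx).value)  # negative
```

HSN's depolarization promotes egg laying (through the VM serotonin-receptor
pathway and the *positive regulation of egg deposition* process), while VC
depolarization inhibits HSN — exactly the signed circuit the source
statements describe.

Overlaying per-neuron functional models on the mini-connectome predicts
cross-circuit links: neurons that respond to carbon dioxide and
connect—directly or transitively—to neurons that affect egg laying:

```python
conn = fixtures.fixture_connectome()
ov = overlay(conn, fixtures.overlay_models(), idx)
print(candidate_links(conn, ov, "CHEBI:16526", "GO:0018991")[:5])
# [('AFD', 'HSN'), ('AFD', 'VC'), ('AFD', 'VM'), ('AFD', 'uv1'), ('ASH', 'HSN')]
```

The `('ASH', 'HSN')` pair is the notable one: a CO₂-responsive sensory
neuron synaptically upstream of the main egg-laying motor neuron, a link
later confirmed experimentally.

The same operations are on the command line:

```sh
cencam stats table.tsv                 # unique statements / entries / papers
cencam build table.tsv -o model.json   # statement rows -> model
cencam validate model.json
cencam export model.json --format graphml
cencam templates list
cencam effect model.json --from '0051899#1' --to '0018991#1'
```

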