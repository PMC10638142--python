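"""Anatomical connectivity, the synapses-to property chain, and functional
overlay.

The anatomy ontology carries no synaptic or gap-junction wiring, so the
connectome is supplied separately as an edge list (chemical synapses are
directed, gap junctions symmetric).  Two inferences run over it:

* the property chain *synapses to* o *synapses to* => *connects with*
  (reflexive-transitive closure of the synapse graph minus identity, with
  gap junctions traversed in both directions);

* the functional overlay: per-neuron stimulus-response signs and
  behavior-effect signs read out of a collection of causal-activity models
  via :func:`cencam.reasoning.net_effect`, plus per-edge sign/modality
  annotations (an edge whose connecting functional path runs through a
  chemical-synaptic-transmission process is *synaptic*, anything else is
  *extrasynaptic_or_indirect*).

Candidate functional links between circuits follow: a neuron with a recorded
response to a stimulus that *connects with* a neuron with a recorded effect
on a behavior is a candidate route from that stimulus to that behavior —
e.g. a CO2-responsive sensory neuron synaptically upstream of an egg-laying
motor neuron.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import CencamError
from .model import CeNCAMModel
from .ontology import OntologyIndex
from .reasoning import net_effect

logger = logging.getLogger(__name__)

CHEMICAL = "chemical_synapse"
GAP = "gap_junction"
_KINDS = (CHEMICAL, GAP)

_BEHAVIOR_ROOT = "GO:0007610"
_CELLULAR_PROCESS = "GO:0009987"
_SYNAPTIC_TRANSMISSION = "GO:0007268"
_OCCURS_IN = "BFO:0000066"
_ACTIVATOR = "RO:0012001"


@dataclass(frozen=True)
class ConnectomeEdge:
    pre: str
    post: str
    kind: str
    weight: int | None = None


@dataclass
class Connectome:
    """Neuron wiring graph; gap junctions are stored once in lexicographic
    pair order and treated symmetrically."""

    neurons: set[str] = field(default_factory=set)
    edges: list[ConnectomeEdge] = field(default_factory=list)

    def add_edge(self, pre: str, post: str, kind: str,
                 weight: int | None = None) -> None:
        if kind not in _KINDS:
            raise CencamError(f"unknown connection kind {kind!r}")
        if kind == GAP and post < pre:
            pre, post = post, pre
        key = (pre, post, kind)
        if any((e.pre, e.post, e.kind) == key for e in self.edges):
            return  # deduplicated
        self.neurons.update((pre, post))
        self.edges.append(ConnectomeEdge(pre, post, kind, weight))

    def graph(self) -> nx.DiGraph:
        """Directed traversal graph (gap junctions in both directions)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.neurons)
        for e in self.edges:
            g.add_edge(e.pre, e.post, kind=e.kind)
            if e.kind == GAP:
                g.add_edge(e.post, e.pre, kind=e.kind)
        return g


def load_connectome(stream) -> Connectome:
    """Read a TSV edge list with columns pre, post, kind, weight (weight may
    be empty); duplicates are dropped, gap junctions canonicalized."""
    import csv

    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    rows = list(csv.reader(stream, delimiter="\t"))
    rows = [r for r in rows if r and any(c.strip() for c in r)
            and not r[0].lstrip().startswith("#")]
    conn = Connectome()
    if not rows:
        return conn
    header = [h.strip().lower() for h in rows[0]]
    if header[:3] != ["pre", "post", "kind"]:
        raise CencamError(f"bad connectome header {header!r}")
    for row in rows[1:]:
        pre, post, kind = (row[0].strip(), row[1].strip(), row[2].strip())
        weight = None
        if len(row) > 3 and row[3].strip():
            weight = int(row[3])
        conn.add_edge(pre, post, kind, weight)
    return conn


def infer_connects_with(connectome: Connectome) -> list[tuple[str, str, str]]:
    """Derived (A, connects_with, B) pairs: transitive closure over directed
    chemical synapses (gap junctions bidirectional), direct connections
    included as connects_with (superproperty convention), self-pairs
    excluded.  Idempotent and monotone in the edge set."""
    g = connectome.graph()
    out = []
    for a in sorted(g.nodes):
        for b in sorted(nx.descendants(g, a)):
            if a != b:
                out.append((a, "connects_with", b))
    return out


@dataclass
class FunctionalOverlay:
    """Per-neuron stimulus responses and behavioral effects plus per-edge
    sign/modality; signs are 'positive'/'negative' (ambiguous or unknown net
    effects are dropped with a log line — the rendering contract only has
    activating and inhibiting)."""

    responses: dict[str, dict[str, str]] = field(default_factory=dict)
    effects: dict[str, dict[str, str]] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], tuple[str, str]] = field(default_factory=dict)
    dropped: list[tuple] = field(default_factory=list)


def _record(table: dict, neuron: str, key: str, sign: str,
            dropped: list, what: str) -> None:
    cur = table.setdefault(neuron, {})
    if key in cur and cur[key] != sign:
        dropped.append((what, neuron, key, "conflict"))
        logger.warning("conflicting %s sign for %s/%s; dropping", what, neuron, key)
        del cur[key]
        return
    cur[key] = sign


def overlay(connectome: Connectome, models: list[CeNCAMModel],
            index: OntologyIndex) -> FunctionalOverlay:
    """Annotate the connectome with functional signs read from the models.

    For each neuron the behavior sign is the net effect from any cellular
    process occurring in that neuron to each behavior-class instance;
    the stimulus sign combines a chemical-activator edge into an activity
    with that activity's net effect on a process occurring in the neuron.
    Positive/negative verdicts are kept; ambiguous/unknown are logged and
    dropped.  The result is independent of model order.
    """
    ov = FunctionalOverlay()
    label_is_neuron = set(connectome.neurons)
    sign_word = {"positive": "positive", "negative": "negative"}

    for m in sorted(models, key=lambda m: m.model_id):
        # processes located in connectome neurons
        in_neuron: dict[str, list[str]] = {}
        for a in m.assertions:
            if a.relation != _OCCURS_IN:
                continue
            cell_cls = m.class_of(a.object)
            if cell_cls not in index:
                continue
            name = index.label(cell_cls)
            if name in label_is_neuron:
                in_neuron.setdefault(name, []).append(a.subject)
        behaviors = [iid for iid in sorted(m.individuals)
                     if index.is_descendant(m.class_of(iid), _BEHAVIOR_ROOT)]
        by_id = {a.assertion_id: a for a in m.assertions}

        # behavior effects
        for neuron, procs in sorted(in_neuron.items()):
            for p in procs:
                for b in behaviors:
                    r = net_effect(m, p, b, index=index)
                    if r.value in sign_word:
                        _record(ov.effects, neuron, m.class_of(b), r.value,
                                ov.dropped, "effect")
                    elif r.value in ("ambiguous", "unknown"):
                        ov.dropped.append(("effect", neuron, m.class_of(b), r.value))
                        logger.info("dropping %s effect %s->%s", r.value,
                                    neuron, m.class_of(b))

        # stimulus responses
        for a in m.assertions:
            if a.relation != _ACTIVATOR:
                continue
            activity, chem_cls = a.subject, m.class_of(a.object)
            for neuron, procs in sorted(in_neuron.items()):
                for p in procs:
                    r = net_effect(m, activity, p, index=index)
                    if r.value in sign_word:
                        _record(ov.responses, neuron, chem_cls, r.value,
                                ov.dropped, "response")
                    elif r.value in ("ambiguous", "unknown"):
                        ov.dropped.append(("response", neuron, chem_cls, r.value))

        # edge annotations
        for e in connectome.edges:
            for p in in_neuron.get(e.pre, []):
                for q in in_neuron.get(e.post, []):
                    r = net_effect(m, p, q, index=index)
                    if r.value not in sign_word:
                        if r.value not in ("none",):
                            ov.dropped.append(("edge", e.pre, e.post, r.value))
                        continue
                    synaptic = False
                    for path in r.paths:
                        nodes = {p}
                        for aid in path:
                            nodes.add(by_id[aid].subject)
                            nodes.add(by_id[aid].object)
                        if any(index.is_descendant(m.class_of(n),
                                                   _SYNAPTIC_TRANSMISSION)
                               for n in nodes):
                            synaptic = True
                    modality = "synaptic" if synaptic else "extrasynaptic_or_indirect"
                    key = (e.pre, e.post, e.kind)
                    prev = ov.edges.get(key)
                    if prev is not None and prev != (r.value, modality):
                        ov.dropped.append(("edge", e.pre, e.post, "conflict"))
                        del ov.edges[key]
                    else:
                        ov.edges[key] = (r.value, modality)
    return ov


def candidate_links(connectome: Connectome, overlay_result: FunctionalOverlay,
                    stimulus: str, behavior: str) -> list[tuple[str, str]]:
    """(responder, effector) pairs: the responder has a recorded response to
    *stimulus*, the effector a recorded effect on *behavior*, and responder
    connects-with effector in the synapse graph.  Sorted deterministically.
    """
    responders = sorted(n for n, d in overlay_result.responses.items()
                        if stimulus in d)
    effectors = sorted(n for n, d in overlay_result.effects.items()
                       if behavior in d)
    closure = {(a, b) for a, _, b in infer_connects_with(connectome)}
    return [(r, e) for r in responders for e in effectors
            if r != e and (r, e) in closure]


def export_overlay(connectome: Connectome, overlay_result: FunctionalOverlay,
                   stimulus: str, behavior: str, format: str = "graphml") -> str:
    """Styled export of the annotated connectome (fill = stimulus-response
    sign, outline = behavior-effect sign, dash marks extrasynaptic/indirect
    edges)."""
    import json

    g = nx.MultiDiGraph()
    for n in sorted(connectome.neurons):
        g.add_node(
            n,
            fill=overlay_result.responses.get(n, {}).get(stimulus, "none"),
            outline=overlay_result.effects.get(n, {}).get(behavior, "none"),
        )
    for e in connectome.edges:
        ann = overlay_result.edges.get((e.pre, e.post, e.kind))
        g.add_edge(e.pre, e.post, key=f"{e.pre}->{e.post}:{e.kind}",
                   kind=e.kind,
                   sign=ann[0] if ann else "none",
                   dash=(ann is not None and ann[1] == "extrasynaptic_or_indirect"))
    if format == "graphml":
        return "\n".join(nx.generate_graphml(g)) + "\n"
    if format == "cx_json":
        doc = {
            "nodes": [{"id": n, **g.nodes[n]} for n in sorted(g.nodes)],
            "edges": [{"id": k, "source": s, "target": t, **g.edges[s, t, k]}
                      for s, t, k in sorted(g.edges(keys=True), key=lambda e: e[2])],
        }
        return json.dumps(doc, indent=2) + "\n"
    raise CencamError(f"unknown overlay export format {format!r}")
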