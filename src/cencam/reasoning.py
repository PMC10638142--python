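"""Derived knowledge over causal-activity models.

Three reasoning services:

* **part-of closure** — *part of* is transitive, so an activity that is part
  of a regulation process that is part of a behavior is itself part of the
  behavior; the closure materializes those implied edges as ``derived``
  assertions.

* **sign composition** — each causal relation carries a sign (+1 for the
  *positive effect*/*positively regulates* lineage, -1 for the negative
  lineage, 0 for the agnostic *causally upstream of (or within)* relations;
  *part of* transmits influence toward the whole without flipping).  The net
  effect of one instance on another is the aggregate over all simple directed
  paths of the per-path sign product.

* **pattern queries** — subsumption-aware subgraph matching ("all
  interneurons whose activity is modulated by peptidergic output from ASI"):
  a pattern node matches any individual whose class is the constraint or one
  of its descendants, a pattern edge any assertion whose relation descends
  from the edge constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import CencamError, OntologyError
from .model import Assertion, CeNCAMModel
from .ontology import CANONICAL_INVERSE, OntologyIndex

PART_OF = "BFO:0000050"
CAUSAL_ROOT = "RO:0002418"

#: default bound on simple-path length; models are small curated graphs, the
#: cap only guards pathological inputs.
DEFAULT_DEPTH_CAP = 12


@dataclass(frozen=True)
class SignResult:
    """Net causal effect of a source instance on a target instance.

    value is one of:

    * ``positive`` / ``negative`` — all decisive paths agree;
    * ``ambiguous`` — both +1 and -1 path products exist (disagreement is
      stronger information than ignorance, so this wins over unknown);
    * ``unknown`` — some path runs through a sign-0 causal edge and there is
      no decisive disagreement;
    * ``none`` — no path at all.

    ``paths`` holds the contributing assertion-id sequences (the empty
    sequence for source == target, whose empty product is +1).
    """

    value: str
    paths: tuple[tuple[str, ...], ...] = ()


def causal_sign(relation: str, index: OntologyIndex | None = None) -> int:
    """Sign of a causal or mereological relation; raises for others."""
    idx = index if index is not None else OntologyIndex({})
    r = idx.relation(relation)
    if r.category == "causal":
        return r.sign
    if r.category == "mereological":
        return 0
    raise OntologyError(
        f"sign undefined for {relation} (category {r.category})"
    )


def part_of_closure(model: CeNCAMModel, apply: bool = True) -> list[Assertion]:
    """Materialize the transitive closure of asserted *part of* edges.

    For every chain a -> ... -> b of length >= 2 a ``derived`` ``a part_of
    b`` assertion is produced.  Asserted edges are never duplicated and
    derived edges are never re-fed into the closure input, so the operation
    is idempotent.  With ``apply=True`` (default) the derived assertions are
    appended to the model; they are returned either way.
    """
    g = nx.DiGraph()
    g.add_nodes_from(model.individuals)
    for a in model.assertions:
        if a.relation == PART_OF and a.provenance == "asserted":
            g.add_edge(a.subject, a.object)
    existing = {(a.subject, a.object) for a in model.assertions
                if a.relation == PART_OF}
    closure = nx.transitive_closure(g, reflexive=False)
    new_pairs = sorted(set(closure.edges()) - existing)
    derived: list[Assertion] = []
    if apply:
        for s, o in new_pairs:
            derived.append(model.assert_edge(s, PART_OF, o, provenance="derived"))
    else:
        for i, (s, o) in enumerate(new_pairs, start=1):
            derived.append(Assertion(f"derived{i}", s, PART_OF, o,
                                     provenance="derived"))
    return derived


def _effect_graph(model: CeNCAMModel, index: OntologyIndex) -> nx.MultiDiGraph:
    """Asserted causal + part_of edges, subject -> object, keyed by
    assertion id, with the edge sign (None for sign-0 causal edges)."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(model.individuals)
    for a in model.assertions:
        if a.provenance != "asserted":
            continue
        r = index.relation(a.relation)
        if r.category == "causal":
            sign = r.sign if r.sign != 0 else None
        elif r.category == "mereological" and a.relation == PART_OF:
            sign = 1  # toward the whole, no flip
        else:
            continue
        g.add_edge(a.subject, a.object, key=a.assertion_id, sign=sign)
    return g


def net_effect(model: CeNCAMModel, source: str, target: str,
               index: OntologyIndex | None = None,
               depth_cap: int = DEFAULT_DEPTH_CAP) -> SignResult:
    """Net sign of *source* on *target* over all simple directed paths.

    Paths run over asserted causal edges and *part of* edges (traversed
    toward the whole).  A path through a sign-0 causal edge contributes
    ``unknown``; otherwise the path contributes the product of its edge
    signs.  ``source == target`` yields ``positive`` via the empty path.
    """
    idx = index if index is not None else model.index
    if idx is None:
        raise CencamError("net_effect needs an ontology index")
    for end in (source, target):
        if end not in model.individuals:
            raise CencamError(f"unknown instance {end!r}")
    if source == target:
        return SignResult("positive", ((),))
    g = _effect_graph(model, idx)
    paths: list[tuple[str, ...]] = []
    values: list[str] = []
    for edge_path in nx.all_simple_edge_paths(g, source, target, cutoff=depth_cap):
        ids = tuple(k for _, _, k in edge_path)
        signs = [g.edges[e]["sign"] for e in edge_path]
        if any(s is None for s in signs):
            values.append("unknown")
        else:
            prod = 1
            for s in signs:
                prod *= s
            values.append("positive" if prod > 0 else "negative")
        paths.append(ids)
    if not values:
        return SignResult("none", ())
    vs = set(values)
    if {"positive", "negative"} <= vs:
        value = "ambiguous"
    elif "unknown" in vs:
        value = "unknown"
    else:
        value = vs.pop()
    return SignResult(value, tuple(paths))


# ---------------------------------------------------------------------------
# Pattern queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternNode:
    var: str
    class_curie: str


@dataclass(frozen=True)
class PatternEdge:
    subject: str
    relation: str
    object: str


@dataclass(frozen=True)
class Pattern:
    """A connected slot graph matched modulo subsumption; ``answer`` names
    the variable whose bindings order the result."""

    nodes: tuple[PatternNode, ...]
    edges: tuple[PatternEdge, ...]
    answer: str

    def __post_init__(self):
        vars_ = {n.var for n in self.nodes}
        if len(vars_) != len(self.nodes):
            raise CencamError("duplicate pattern variable")
        if self.answer not in vars_:
            raise CencamError(f"answer variable {self.answer!r} not in pattern")
        for e in self.edges:
            if e.subject not in vars_ or e.object not in vars_:
                raise CencamError("pattern edge references unknown variable")
        if len(self.nodes) > 1:
            g = nx.Graph()
            g.add_nodes_from(vars_)
            g.add_edges_from((e.subject, e.object) for e in self.edges)
            if not nx.is_connected(g):
                raise CencamError("pattern must be connected")


def query(model: CeNCAMModel, pattern: Pattern,
          index: OntologyIndex | None = None) -> list[dict[str, str]]:
    """All injective bindings of pattern variables to individuals.

    A variable binds an individual whose class is the constraint or one of
    its is_a descendants; a pattern edge is satisfied by any assertion whose
    relation descends from the edge constraint (inverse-stated constraints
    are canonicalized).  Results are sorted by the answer binding, then by
    the full binding tuple; no match yields an empty list.
    """
    idx = index if index is not None else model.index
    if idx is None:
        raise CencamError("query needs an ontology index")

    # normalize inverse-direction edge constraints to the stored direction
    edges = []
    for e in pattern.edges:
        if e.relation in CANONICAL_INVERSE:
            edges.append(PatternEdge(e.object, CANONICAL_INVERSE[e.relation], e.subject))
        else:
            edges.append(e)

    candidates: dict[str, list[str]] = {}
    for n in pattern.nodes:
        cands = [iid for iid in sorted(model.individuals)
                 if idx.is_descendant(model.class_of(iid), n.class_curie)]
        candidates[n.var] = cands
    order = sorted(candidates, key=lambda v: len(candidates[v]))

    by_pair: dict[tuple[str, str], list[str]] = {}
    for a in model.assertions:
        by_pair.setdefault((a.subject, a.object), []).append(a.relation)

    def edge_ok(binding) -> bool:
        for e in edges:
            if e.subject in binding and e.object in binding:
                rels = by_pair.get((binding[e.subject], binding[e.object]), [])
                if not any(idx.relation_descends(r, e.relation) for r in rels):
                    return False
        return True

    results: list[dict[str, str]] = []

    def backtrack(i: int, binding: dict[str, str], used: set[str]):
        if i == len(order):
            results.append(dict(binding))
            return
        var = order[i]
        for iid in candidates[var]:
            if iid in used:
                continue
            binding[var] = iid
            used.add(iid)
            if edge_ok(binding):
                backtrack(i + 1, binding, used)
            used.discard(iid)
            del binding[var]

    backtrack(0, {}, set())
    results.sort(key=lambda b: (b[pattern.answer],
                                tuple(b[v] for v in sorted(b))))
    return results
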