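"""Causal-activity models: instance nodes, typed evidence-bearing assertions,
and the validator encoding the data-model conventions.

A :class:`CeNCAMModel` is a small knowledge graph.  Nodes are *individuals* —
instances of ontology classes (two serotonin mentions stay two nodes, so a
synaptic and an extra-synaptic pool can be distinguished).  Edges are
*assertions*: subject–relation–object triples carrying evidence records.

The validator applies the aspect conventions of the causal-activity data
model: causal relations link molecular functions to molecular functions or
biological processes to biological processes; *part of* builds the
MF -> BP -> behavior composition; *enabled by* ties an activity to its gene;
*occurs in* places activities and processes in cells or cellular components;
*has small molecule activator* connects chemicals to receptor/enzyme
activities; *has quality* attaches temporal qualities to exposures.

Violation codes (severity):

========================  ========  =============================================
code                      severity  meaning
========================  ========  =============================================
BAD_CAUSAL_DOMAIN         error     causal edge outside {MF, BP} x {MF, BP}
CAUSAL_MF_BP              warning   causal edge mixing MF and BP aspects
BAD_PARTOF                error     part_of outside MF->BP / BP->BP
BAD_ENABLED_BY            error     enabled_by not MF->gene
BAD_OCCURS_IN             error     occurs_in not {MF,BP}->{anatomy,CC}
BAD_SMALL_MOL             error     has_small_molecule_activator not MF->chemical
BAD_INPUT_OUTPUT          error     has_input/has_output not {MF,BP}->{chem,gene}
BAD_QUALITY               error     has_quality not exposure->quality
BAD_EVIDENCE_CLASS        error     evidence class is not an ECO evidence term
UNEVIDENCED               warning   asserted edge with no evidence record
SELF_PART                 warning   part_of self-loop
========================  ========  =============================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .curies import curie_local
from .errors import ModelError, SpecializationError
from .ontology import CANONICAL_INVERSE, OntologyIndex, builtin_relations

_MF = "molecular_function"
_BP = "biological_process"
_CC = "cellular_component"


@dataclass(frozen=True)
class Evidence:
    """One evidence record on an assertion (edge-level, as in GO-CAM)."""

    eco_curie: str
    reference: str
    quote: str | None = None


@dataclass(frozen=True)
class Individual:
    """An instance node typed by an ontology class."""

    instance_id: str
    class_curie: str
    display: str | None = None


@dataclass(frozen=True)
class Assertion:
    """A subject-relation-object edge with evidence and provenance."""

    assertion_id: str
    subject: str
    relation: str
    object: str
    evidence: tuple[Evidence, ...] = ()
    provenance: str = "asserted"  # "asserted" | "derived"
    sources: tuple[str, ...] = ()

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject, self.relation, self.object)


@dataclass(frozen=True)
class Violation:
    """One validator finding; ``ref`` is the offending triple or individual."""

    code: str
    severity: str  # "error" | "warning"
    ref: tuple
    message: str


class CeNCAMModel:
    """A causal-activity model of a neural circuit or a single statement.

    Instance ids are deterministic (``<classLocalId>#<ordinal>``) so that
    serializations of the same construction are byte-stable.  The graph need
    not be connected.
    """

    def __init__(self, model_id: str, title: str = "",
                 index: OntologyIndex | None = None, metadata: dict | None = None):
        self.model_id = model_id
        self.title = title
        self.index = index
        self.metadata: dict = dict(metadata or {})
        self.individuals: dict[str, Individual] = {}
        self.assertions: list[Assertion] = []
        self._class_counts: dict[str, int] = {}
        self._triples: set[tuple[str, str, str]] = set()

    # -- construction -------------------------------------------------------

    def add_individual(self, class_curie: str, display: str | None = None) -> str:
        """Add a fresh instance of *class_curie* and return its id."""
        if self.index is not None:
            self.index.term(class_curie)  # raises UnknownTermError
        n = self._class_counts.get(class_curie, 0) + 1
        self._class_counts[class_curie] = n
        instance_id = f"{curie_local(class_curie)}#{n}"
        if instance_id in self.individuals:  # defensive; cannot happen
            raise ModelError(f"duplicate instance id {instance_id}")
        self.individuals[instance_id] = Individual(instance_id, class_curie, display)
        return instance_id

    def assert_edge(self, subject: str, relation: str, object: str,
                    evidence: tuple[Evidence, ...] | list[Evidence] = (),
                    provenance: str = "asserted",
                    sources: tuple[str, ...] = ()) -> Assertion:
        """Append an assertion.

        Inverse relations (*has part*, *enables*, *is small molecule activator
        of*) are canonicalized to the stored direction, swapping subject and
        object; the inverse is answered by query, never stored twice.
        """
        registry = self.index.relations if self.index is not None else builtin_relations()
        if relation in CANONICAL_INVERSE:
            relation = CANONICAL_INVERSE[relation]
            subject, object = object, subject
        if relation not in registry:
            raise ModelError(f"unknown relation {relation!r}")
        for end in (subject, object):
            if end not in self.individuals:
                raise ModelError(f"dangling endpoint {end!r} in model {self.model_id}")
        triple = (subject, relation, object)
        if provenance == "asserted" and triple in self._triples:
            raise ModelError(f"duplicate asserted triple {triple}")
        a = Assertion(
            assertion_id=f"a{len(self.assertions) + 1}",
            subject=subject, relation=relation, object=object,
            evidence=tuple(evidence), provenance=provenance, sources=tuple(sources),
        )
        self.assertions.append(a)
        if provenance == "asserted":
            self._triples.add(triple)
        return a

    # -- views --------------------------------------------------------------

    def class_of(self, instance_id: str) -> str:
        return self.individuals[instance_id].class_curie

    def asserted(self) -> list[Assertion]:
        return [a for a in self.assertions if a.provenance == "asserted"]

    def graph(self) -> nx.MultiDiGraph:
        """Instance-level multidigraph view (node attr ``class_curie``,
        edge attr ``relation``/``provenance``)."""
        g = nx.MultiDiGraph(model_id=self.model_id)
        for iid in sorted(self.individuals):
            ind = self.individuals[iid]
            g.add_node(iid, class_curie=ind.class_curie)
        for a in self.assertions:
            g.add_edge(a.subject, a.object, key=a.assertion_id,
                       relation=a.relation, provenance=a.provenance)
        return g

    def __len__(self) -> int:
        return len(self.individuals)

    # -- serialization (native JSON dialect) --------------------------------

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "title": self.title,
            "metadata": {k: self.metadata[k] for k in sorted(self.metadata)},
            "individuals": [
                {"id": iid, "class": ind.class_curie,
                 **({"display": ind.display} if ind.display else {})}
                for iid, ind in sorted(self.individuals.items())
            ],
            "assertions": [
                {
                    "id": a.assertion_id, "s": a.subject, "rel": a.relation,
                    "o": a.object,
                    "evidence": [
                        {"eco": e.eco_curie, "reference": e.reference,
                         **({"quote": e.quote} if e.quote else {})}
                        for e in a.evidence
                    ],
                    "provenance": a.provenance,
                    **({"sources": list(a.sources)} if a.sources else {}),
                }
                for a in self.assertions
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    @classmethod
    def from_dict(cls, d: dict, index: OntologyIndex | None = None) -> "CeNCAMModel":
        m = cls(d["model_id"], d.get("title", ""), index=index,
                metadata=d.get("metadata", {}))
        for ind in d["individuals"]:
            m.individuals[ind["id"]] = Individual(
                ind["id"], ind["class"], ind.get("display"))
            local, _, num = ind["id"].partition("#")
            if num.isdigit():
                m._class_counts[ind["class"]] = max(
                    m._class_counts.get(ind["class"], 0), int(num))
        for a in d["assertions"]:
            ev = tuple(Evidence(e["eco"], e["reference"], e.get("quote"))
                       for e in a.get("evidence", []))
            asser = Assertion(a["id"], a["s"], a["rel"], a["o"], ev,
                              a.get("provenance", "asserted"),
                              tuple(a.get("sources", ())))
            m.assertions.append(asser)
            if asser.provenance == "asserted":
                m._triples.add(asser.triple)
        return m

    @classmethod
    def from_json(cls, text: str, index: OntologyIndex | None = None) -> "CeNCAMModel":
        return cls.from_dict(json.loads(text), index=index)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_aspects(code, sa, oa, valid_pairs):
    return (sa, oa) in valid_pairs


def validate(model: CeNCAMModel, index: OntologyIndex) -> list[Violation]:
    """Apply the rule table; an empty list means the model conforms.

    Deterministic and order-independent: the violation multiset does not
    depend on assertion order.  Validation is subsumption-aware through the
    relation hierarchy: a rule row matched by a relation is matched by every
    descendant of that relation in the same family.
    """
    out: list[Violation] = []

    def emit(code, severity, ref, message):
        out.append(Violation(code, severity, ref, message))

    for a in model.assertions:
        rel = a.relation
        if rel in CANONICAL_INVERSE:  # defensive: deserialized models
            rel = CANONICAL_INVERSE[rel]
            s_id, o_id = a.object, a.subject
        else:
            s_id, o_id = a.subject, a.object
        sa = index.aspect(model.class_of(s_id))
        oa = index.aspect(model.class_of(o_id))
        ref = (model.class_of(s_id), rel, model.class_of(o_id))
        rtype = index.relation(rel)

        if rtype.category == "mereological":
            if s_id == o_id:
                emit("SELF_PART", "warning", ref,
                     f"part_of self-loop on {s_id}")
            if (sa, oa) not in {(_MF, _BP), (_BP, _BP)}:
                emit("BAD_PARTOF", "error", ref,
                     f"part_of must be MF->BP or BP->BP, got {sa}->{oa}")
        elif rtype.category == "causal":
            if {sa, oa} <= {_MF, _BP}:
                if sa != oa:
                    emit("CAUSAL_MF_BP", "warning", ref,
                         f"causal edge mixes aspects {sa}->{oa}")
            else:
                emit("BAD_CAUSAL_DOMAIN", "error", ref,
                     f"causal edge outside MF/BP aspects: {sa}->{oa}")
        elif rel == "RO:0002333":
            if (sa, oa) != (_MF, "gene"):
                emit("BAD_ENABLED_BY", "error", ref,
                     f"enabled_by must be MF->gene, got {sa}->{oa}")
        elif rel == "BFO:0000066":
            if sa not in (_MF, _BP) or oa not in ("anatomy", _CC):
                emit("BAD_OCCURS_IN", "error", ref,
                     f"occurs_in must be MF/BP->anatomy/CC, got {sa}->{oa}")
        elif rel == "RO:0012001":
            if (sa, oa) != (_MF, "chemical"):
                emit("BAD_SMALL_MOL", "error", ref,
                     f"has_small_molecule_activator must be MF->chemical, got {sa}->{oa}")
        elif rel in ("RO:0002233", "RO:0002234"):
            if sa not in (_MF, _BP) or oa not in ("chemical", "gene"):
                emit("BAD_INPUT_OUTPUT", "error", ref,
                     f"has_input/has_output must be MF/BP->chemical/gene, got {sa}->{oa}")
        elif rel == "RO:0000086":
            if (sa, oa) != ("exposure", "quality"):
                emit("BAD_QUALITY", "error", ref,
                     f"has_quality must be exposure->quality, got {sa}->{oa}")

        for e in a.evidence:
            if e.eco_curie not in index or index.aspect(e.eco_curie) != "evidence":
                emit("BAD_EVIDENCE_CLASS", "error", ref,
                     f"evidence class {e.eco_curie} is not an ECO evidence term")
        if not a.evidence and a.provenance == "asserted":
            emit("UNEVIDENCED", "warning", ref,
                 f"asserted edge {ref} carries no evidence")
    return out


def errors_only(violations: list[Violation]) -> list[Violation]:
    return [v for v in violations if v.severity == "error"]


# ---------------------------------------------------------------------------
# Merge with relation specialization
# ---------------------------------------------------------------------------

def merge(models: list[CeNCAMModel],
          specializations: list[tuple[tuple[str, str, str], str]] = (),
          index: OntologyIndex | None = None,
          model_id: str = "merged", title: str = "") -> CeNCAMModel:
    """Union of models with optional edge specialization.

    Individuals are re-identified (fresh deterministic ids) to avoid
    collisions; assertions keep evidence and record their source model.
    Each specialization is ``((subject_class, relation, object_class),
    new_relation)``: every merged asserted edge matching the class-level
    selector is re-typed to *new_relation*, which must descend from the
    matched relation — compiling statement-level models into a circuit model
    can use more specific relations (e.g. *positively regulates* instead of
    *causally upstream of, positive effect*).
    """
    if index is None:
        index = next((m.index for m in models if m.index is not None), None)
    out = CeNCAMModel(model_id, title, index=index)
    out.metadata["source_models"] = [m.model_id for m in models]

    id_map: dict[tuple[str, str], str] = {}
    for m in models:
        for iid, ind in m.individuals.items():
            new_id = out.add_individual(ind.class_curie, ind.display)
            id_map[(m.model_id, iid)] = new_id
    spec_sources: dict[tuple[tuple[str, str, str], str], set[str]] = {}
    merged: list[tuple[Assertion, str, str, str]] = []
    for m in models:
        for a in m.assertions:
            merged.append((a, m.model_id,
                           id_map[(m.model_id, a.subject)],
                           id_map[(m.model_id, a.object)]))

    registry = (index.relations if index is not None else builtin_relations())
    reg_index = index if index is not None else OntologyIndex({})
    selectors = {tuple(sel): new_rel for sel, new_rel in specializations}

    for a, src, s_new, o_new in merged:
        rel = a.relation
        src_models = (src,)
        for (s_cls, old_rel, o_cls), new_rel in selectors.items():
            model_src = next(m for m in models if m.model_id == src)
            if (model_src.class_of(a.subject) == s_cls and a.relation == old_rel
                    and model_src.class_of(a.object) == o_cls):
                if new_rel not in registry or not reg_index.relation_descends(new_rel, old_rel):
                    raise SpecializationError(
                        f"ILLEGAL_SPECIALIZATION: {new_rel} does not descend from {old_rel}"
                    )
                rel = new_rel
                key = ((s_cls, old_rel, o_cls), new_rel)
                spec_sources.setdefault(key, set()).add(src)
        out.assert_edge(s_new, rel, o_new, evidence=a.evidence,
                        provenance=a.provenance, sources=src_models)
    # specialized edges record every source model that contributed a match
    if spec_sources:
        for i, a in enumerate(out.assertions):
            for ((s_cls, old_rel, o_cls), new_rel), srcs in spec_sources.items():
                if (a.relation == new_rel
                        and out.class_of(a.subject) == s_cls
                        and out.class_of(a.object) == o_cls):
                    out.assertions[i] = Assertion(
                        a.assertion_id, a.subject, a.relation, a.object,
                        a.evidence, a.provenance, tuple(sorted(srcs)))
    return out
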