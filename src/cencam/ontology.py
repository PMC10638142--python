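"""Class and relation hierarchies.

Two hierarchies back every other module:

* **Terms** — ontology classes (GO biological processes and molecular
  functions, WormBase anatomy, ChEBI chemicals, ECO evidence classes, ECTO
  exposures, PATO qualities, WormBase genes, plus package-local ``CeNCAM:``
  proposed classes) connected by ``is_a`` parentage.  Subsumption
  (:meth:`OntologyIndex.is_descendant`) is reflexive and transitive over that
  acyclic graph.

* **Relations** — the typed edges allowed in a causal-activity model: the
  causal family under *causally upstream of or within* (RO:0002418), the
  mereological pair *part of*/*has part*, *enabled by*, *occurs in*, the
  chemical-participation relations, and *has quality*.  The registry is fixed
  (built in, :func:`builtin_relations`) and carries a causal sign per relation
  (+1 activating lineage, -1 inhibiting lineage, 0 neutral).

Terms are loaded from a small OBO flat-file dialect ([Term] stanzas with
``id``/``name``/``namespace``/``is_a``; ``relationship`` and ``xref`` tags are
kept as annotations, everything else is ignored with a debug log line).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import obonet

from .curies import PREFIX_ASPECT, curie_prefix, normalize_curie
from .errors import (
    CycleError,
    DuplicateTermError,
    OntologyError,
    UnknownRelationError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

ASPECTS = frozenset(
    {
        "molecular_function",
        "biological_process",
        "cellular_component",
        "anatomy",
        "chemical",
        "gene",
        "evidence",
        "exposure",
        "quality",
    }
)

#: OBO ``namespace:`` values accepted for GO-style terms map onto themselves;
#: prefix-decided aspects are in :data:`cencam.curies.PREFIX_ASPECT`.
_NAMESPACE_ASPECT = {a: a for a in ASPECTS}

RELATION_CATEGORIES = frozenset(
    {
        "causal",
        "mereological",
        "enablement",
        "location",
        "chemical_participation",
        "quality_attribution",
    }
)


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology class."""

    curie: str
    label: str
    aspect: str
    parents: tuple[str, ...] = ()
    status: str = "existing"  # "existing" | "proposed"
    definition: str | None = None
    #: non-classifying annotations, e.g. {"part_of": ("GO:0018991",)} or
    #: {"xref": ("GO:0046662",)}
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.aspect not in ASPECTS:
            raise OntologyError(f"{self.curie}: unknown aspect {self.aspect!r}")
        if self.status not in ("existing", "proposed"):
            raise OntologyError(f"{self.curie}: unknown status {self.status!r}")


@dataclass(frozen=True)
class RelationType:
    """One registered relation (edge type)."""

    curie: str
    label: str
    parents: tuple[str, ...] = ()
    inverse: str | None = None
    category: str = "causal"
    sign: int = 0

    def __post_init__(self):
        if self.category not in RELATION_CATEGORIES:
            raise OntologyError(f"{self.curie}: unknown category {self.category!r}")
        if self.sign not in (-1, 0, 1):
            raise OntologyError(f"{self.curie}: sign must be -1, 0 or +1")


# ---------------------------------------------------------------------------
# Relation registry
# ---------------------------------------------------------------------------

#: Relations whose asserted direction is canonicalized at assertion time:
#: the stored direction is the value; the key is rewritten as value with
#: subject/object swapped.
CANONICAL_INVERSE = {
    "BFO:0000051": "BFO:0000050",  # has part      -> part of
    "RO:0002327": "RO:0002333",    # enables       -> enabled by
    "RO:0012005": "RO:0012001",    # is sm activator of -> has sm activator
}

#: The causal relations proper (descend from RO:0002418 through the causal
#: category).  part_of also descends from RO:0002418 but is mereological.
CAUSAL_RELATIONS = frozenset(
    {"RO:0002418", "RO:0002411", "RO:0002304", "RO:0002305", "RO:0002213", "RO:0002212"}
)

_RELATION_ROWS = [
    # curie, label, parents, inverse, category, sign
    ("RO:0002418", "causally upstream of or within", (), None, "causal", 0),
    ("RO:0002411", "causally upstream of", ("RO:0002418",), None, "causal", 0),
    ("RO:0002304", "causally upstream of, positive effect", ("RO:0002411",), None, "causal", 1),
    ("RO:0002305", "causally upstream of, negative effect", ("RO:0002411",), None, "causal", -1),
    ("RO:0002213", "positively regulates", ("RO:0002304",), None, "causal", 1),
    ("RO:0002212", "negatively regulates", ("RO:0002305",), None, "causal", -1),
    ("BFO:0000050", "part of", ("RO:0002418",), "BFO:0000051", "mereological", 0),
    ("BFO:0000051", "has part", (), "BFO:0000050", "mereological", 0),
    ("RO:0002333", "enabled by", (), "RO:0002327", "enablement", 0),
    ("RO:0002327", "enables", (), "RO:0002333", "enablement", 0),
    ("BFO:0000066", "occurs in", (), None, "location", 0),
    ("RO:0012001", "has small molecule activator", (), "RO:0012005", "chemical_participation", 0),
    ("RO:0012005", "is small molecule activator of", (), "RO:0012001", "chemical_participation", 0),
    ("RO:0002233", "has input", (), None, "chemical_participation", 0),
    ("RO:0002234", "has output", (), None, "chemical_participation", 0),
    ("RO:0000086", "has quality", (), None, "quality_attribution", 0),
]


def builtin_relations() -> dict[str, RelationType]:
    """The fixed relation registry used by every model."""
    rels = {
        c: RelationType(c, lab, parents, inv, cat, sign)
        for c, lab, parents, inv, cat, sign in _RELATION_ROWS
    }
    # sanity: inverse symmetry and acyclic parentage
    for r in rels.values():
        if r.inverse is not None and rels[r.inverse].inverse != r.curie:
            raise OntologyError(f"inverse-of not symmetric for {r.curie}")
    g = nx.DiGraph((r.curie, p) for r in rels.values() for p in r.parents)
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError("relation hierarchy is cyclic")
    return rels


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


class OntologyIndex:
    """Joint index over the class and relation hierarchies.

    Lookups are total: every CURIE referenced by a model validated against
    this index must resolve here, and unresolved lookups raise rather than
    returning a default.
    """

    def __init__(self, terms: dict[str, OntologyTerm] | None = None,
                 relations: dict[str, RelationType] | None = None):
        self.terms: dict[str, OntologyTerm] = dict(terms or {})
        self.relations: dict[str, RelationType] = (
            dict(relations) if relations is not None else builtin_relations()
        )
        #: is_a targets that did not resolve at load time (reported, kept).
        self.unresolved: list[tuple[str, str]] = []
        self._check_terms()

    # -- lookups ------------------------------------------------------------

    def term(self, curie: str) -> OntologyTerm:
        try:
            return self.terms[curie]
        except KeyError:
            raise UnknownTermError(f"unknown term {curie!r}") from None

    def relation(self, curie: str) -> RelationType:
        try:
            return self.relations[curie]
        except KeyError:
            raise UnknownRelationError(f"unknown relation {curie!r}") from None

    def aspect(self, curie: str) -> str:
        return self.term(curie).aspect

    def __contains__(self, curie: str) -> bool:
        return curie in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    # -- subsumption --------------------------------------------------------

    def is_descendant(self, term: str, ancestor: str) -> bool:
        """Reflexive-transitive is_a reachability: term == ancestor or
        ancestor reachable from term via is_a edges."""
        self.term(ancestor)
        if term == ancestor:
            return True
        seen = set()
        stack = [term]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            for p in self.term(cur).parents:
                if p == ancestor:
                    return True
                stack.append(p)
        return False

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of *term*, excluding term itself."""
        out: set[str] = set()
        stack = list(self.term(term).parents)
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self.term(cur).parents)
        return out

    def relation_descends(self, rel: str, ancestor_rel: str) -> bool:
        """Reflexive-transitive reachability over the relation hierarchy."""
        self.relation(ancestor_rel)
        if rel == ancestor_rel:
            return True
        seen = set()
        stack = [rel]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            for p in self.relation(cur).parents:
                if p == ancestor_rel:
                    return True
                stack.append(p)
        return False

    def label(self, curie: str) -> str:
        if curie in self.terms:
            return self.terms[curie].label
        if curie in self.relations:
            return self.relations[curie].label
        raise UnknownTermError(f"unknown CURIE {curie!r}")

    def term_by_label(self, label: str) -> OntologyTerm | None:
        for t in self.terms.values():
            if t.label == label:
                return t
        return None

    # -- mutation -----------------------------------------------------------

    def add_proposed_class(self, term: OntologyTerm) -> "OntologyIndex":
        """Add a proposed class; idempotent when an identical term exists.

        Proposed terms participate in subsumption exactly like existing ones.
        """
        if term.curie in self.terms:
            old = self.terms[term.curie]
            if (old.label, old.aspect, old.parents) == (term.label, term.aspect, term.parents):
                return self
            raise DuplicateTermError(
                f"term {term.curie} already indexed with different content"
            )
        for p in term.parents:
            if p not in self.terms:
                raise UnknownTermError(
                    f"parent {p!r} of proposed class {term.curie} does not resolve"
                )
        self.terms[term.curie] = term
        self._check_term(term)
        return self

    # -- invariants ---------------------------------------------------------

    def _check_term(self, t: OntologyTerm) -> None:
        for p in t.parents:
            parent = self.terms.get(p)
            if parent is None:
                continue  # recorded in self.unresolved by the loader
            if curie_prefix(p) == curie_prefix(t.curie) and parent.aspect != t.aspect:
                raise OntologyError(
                    f"aspect-crossing is_a within prefix: {t.curie} ({t.aspect}) "
                    f"is_a {p} ({parent.aspect})"
                )

    def _check_terms(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                if p in self.terms:
                    g.add_edge(t.curie, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise CycleError([a for a, _ in cycle] + [cycle[0][0]])
        for t in self.terms.values():
            self._check_term(t)


# ---------------------------------------------------------------------------
# OBO subset loading / writing
# ---------------------------------------------------------------------------

_ID_LINE = re.compile(r"^id:\s*(\S.*?)\s*$", re.MULTILINE)


def _infer_aspect(curie: str, namespace: str | None) -> str:
    prefix = curie_prefix(curie)
    if prefix in PREFIX_ASPECT:
        got = PREFIX_ASPECT[prefix]
        if namespace is not None and _NAMESPACE_ASPECT.get(namespace, got) != got:
            raise OntologyError(
                f"{curie}: namespace {namespace!r} conflicts with prefix aspect {got!r}"
            )
        return got
    # GO and CeNCAM need an explicit namespace
    if namespace is None:
        raise OntologyError(f"{curie}: missing namespace, cannot infer aspect")
    try:
        return _NAMESPACE_ASPECT[namespace]
    except KeyError:
        raise OntologyError(f"{curie}: unknown namespace {namespace!r}") from None


def load_obo_subset(stream, relations: dict[str, RelationType] | None = None) -> OntologyIndex:
    """Parse an OBO flat-file subset into an :class:`OntologyIndex`.

    Accepts a text stream or a string.  Duplicate ids and cyclic is_a
    parentage are errors; is_a targets that do not resolve are reported on
    ``index.unresolved`` (and logged), never silently dropped.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()

    raw_ids = [normalize_curie(m) for m in _ID_LINE.findall(text)]
    seen: set[str] = set()
    for c in raw_ids:
        if c in seen:
            raise DuplicateTermError(f"duplicate id {c} in OBO stream")
        seen.add(c)

    if not text.strip():
        return OntologyIndex({}, relations)
    graph = obonet.read_obo(io.StringIO(text))

    known_tags = {"name", "namespace", "is_a", "relationship", "xref"}
    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            continue  # dangling target materialized by the parser
        curie = normalize_curie(node)
        for tag in data:
            if tag not in known_tags and tag != "def":
                logger.debug("OBO loader: ignoring tag %r on %s", tag, curie)
        parents = tuple(normalize_curie(p) for p in data.get("is_a", []))
        annotations: dict[str, tuple[str, ...]] = {}
        for rel_line in data.get("relationship", []):
            rel_raw, target = rel_line.split(None, 1)
            rel = "BFO:0000050" if rel_raw in ("part_of", "BFO:0000050") else rel_raw
            annotations.setdefault(rel, ())
            annotations[rel] = annotations[rel] + (normalize_curie(target),)
        if "xref" in data:
            annotations["xref"] = tuple(data["xref"])
        definition = None
        if "def" in data:
            definition = data["def"].strip('"').split('" [')[0]
        status = "proposed" if curie_prefix(curie) == "CeNCAM" else "existing"
        terms[curie] = OntologyTerm(
            curie=curie,
            label=data["name"],
            aspect=_infer_aspect(curie, data.get("namespace")),
            parents=parents,
            status=status,
            definition=definition,
            annotations=annotations,
        )

    index = OntologyIndex(terms, relations)
    for t in terms.values():
        for p in t.parents:
            if p not in terms:
                index.unresolved.append((t.curie, p))
                logger.warning("unresolved is_a target %s (parent of %s)", p, t.curie)
    return index


def write_obo_subset(index: OntologyIndex) -> str:
    """Serialize the term hierarchy back to the OBO subset dialect.

    Loading the output again yields the same term set with the same parent
    multiset (lossless for the subset the loader understands).
    """
    out = ["format-version: 1.2", "ontology: cencam-export", ""]
    for curie in sorted(index.terms):
        t = index.terms[curie]
        out.append("[Term]")
        out.append(f"id: {t.curie}")
        out.append(f"name: {t.label}")
        out.append(f"namespace: {t.aspect}")
        if t.definition:
            out.append(f'def: "{t.definition}" []')
        for p in t.parents:
            out.append(f"is_a: {p} ! {index.terms[p].label if p in index.terms else ''}".rstrip())
        for rel, targets in sorted(t.annotations.items()):
            if rel == "xref":
                for x in targets:
                    out.append(f"xref: {x}")
            else:
                for target in targets:
                    out.append(f"relationship: {rel} {target}")
        out.append("")
    return "\n".join(out)
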