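"""Statement-table ingestion, curation statistics, and graph exports.

The curated input of this package is a table of *author statements*: each
row carries a local identifier, a citation key, the statement text, and the
statement's semantic-triple chain written left-to-right in alternating
node/relation columns (``Node 1 | Relation 1 | Node 2 | Relation 2 | ...``).
Rows may repeat a local identifier when one statement yields several entries.

Exports cover the formats circuit-visualization tools consume: SIF, GraphML
and a CX-style JSON (nodes/edges lists with class, aspect, relation, sign and
provenance attributes), plus the native JSON dialect and RDF Turtle.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass, field

import networkx as nx

from .curies import curie_to_iri, normalize_curie, CENCAM_NS
from .errors import TableFormatError, UnknownFormatError, UnknownTermError
from .model import CeNCAMModel, Evidence
from .ontology import OntologyIndex

#: evidence class attached to assertions ingested from statement tables
#: (the tables carry no evidence column; experimental phenotypic evidence is
#: the least committal ECO class the corpus uses).
DEFAULT_TABLE_EVIDENCE = "ECO:0000059"

EXPORT_FORMATS = ("sif", "graphml", "cx_json", "turtle", "native_json")


@dataclass(frozen=True)
class TableDialect:
    """Statement-table dialect: UTF-8, tab-separated, fixed case-insensitive
    headers; the optional Categories column holds ';'-joined labels."""

    categories_column: bool = False


@dataclass(frozen=True)
class StatementRecord:
    """One curated author-statement row."""

    local_id: str
    reference: str
    statement_text: str
    triple_chain: tuple[tuple[str, str, str], ...]
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.local_id:
            raise TableFormatError("empty local identifier")
        for i in range(1, len(self.triple_chain)):
            if self.triple_chain[i][0] != self.triple_chain[i - 1][2]:
                raise TableFormatError(
                    f"{self.local_id}: chain links do not share middle node")


@dataclass(frozen=True)
class CurationStats:
    """Bookkeeping over a statement table: rows are *entries*, distinct local
    identifiers are *unique statements*, distinct references are *papers*."""

    unique_statements: int
    entries: int
    papers: int


def _fixed_headers(dialect: TableDialect) -> list[str]:
    heads = ["Local ID", "Reference", "Author Statement"]
    if dialect.categories_column:
        heads.append("Categories")
    return heads


def read_statement_table(stream, dialect: TableDialect = TableDialect()
                         ) -> list[StatementRecord]:
    """Parse a TSV statement table.

    Trailing empty cells are permitted (chains have variable length); a
    malformed CURIE or an even number of chain cells is an error naming the
    row.  A header-only file yields an empty list.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    rows = list(csv.reader(stream, delimiter="\t"))
    if not rows:
        return []
    header = [h.strip().lower() for h in rows[0]]
    expected = [h.lower() for h in _fixed_headers(dialect)]
    if header[: len(expected)] != expected:
        raise TableFormatError(
            f"bad header: expected {expected!r} leading columns, got {header[:len(expected)]!r}")
    nfixed = len(expected)
    records = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        fixed = [c.strip() for c in row[:nfixed]] + [""] * (nfixed - len(row))
        cells = [c.strip() for c in row[nfixed:]]
        while cells and not cells[-1]:
            cells.pop()
        if any(not c for c in cells):
            raise TableFormatError(f"row {rownum}: empty cell inside the chain")
        if len(cells) < 3 or len(cells) % 2 == 0:
            raise TableFormatError(
                f"row {rownum}: chain needs an odd number (>=3) of "
                f"node/relation cells, got {len(cells)}")
        try:
            curies = [normalize_curie(c) for c in cells]
        except Exception as exc:
            raise TableFormatError(f"row {rownum}: {exc}") from exc
        chain = tuple((curies[i], curies[i + 1], curies[i + 2])
                      for i in range(0, len(curies) - 2, 2))
        cats = ()
        if dialect.categories_column and fixed[3]:
            cats = tuple(c.strip() for c in fixed[3].split(";") if c.strip())
        records.append(StatementRecord(fixed[0], fixed[1], fixed[2], chain, cats))
    return records


def write_statement_table(records: list[StatementRecord],
                          dialect: TableDialect = TableDialect()) -> str:
    """Serialize records back to TSV (inverse of :func:`read_statement_table`).

    Statement text is the only free-text column; embedded tabs/newlines are
    sanitized to spaces on write.
    """
    width = max((2 * len(r.triple_chain) + 1 for r in records), default=1)
    # interleave Node i / Relation i headers up to the chain width
    chain_heads = []
    for i in range(width):
        chain_heads.append(f"Node {i // 2 + 1}" if i % 2 == 0
                           else f"Relation {i // 2 + 1}")
    heads = _fixed_headers(dialect) + chain_heads
    out = ["\t".join(heads)]
    for r in records:
        text = " ".join(r.statement_text.split())
        fixed = [r.local_id, r.reference, text]
        if dialect.categories_column:
            fixed.append("; ".join(r.categories))
        cells = []
        for i, (s, rel, o) in enumerate(r.triple_chain):
            if i == 0:
                cells.append(s)
            cells.extend([rel, o])
        cells += [""] * (width - len(cells))
        out.append("\t".join(fixed + cells))
    return "\n".join(out) + "\n"


def statement_stats(records: list[StatementRecord]) -> CurationStats:
    """Entries = rows; unique statements keyed on local id; papers keyed on
    reference.  Permutation-invariant over rows."""
    return CurationStats(
        unique_statements=len({r.local_id for r in records}),
        entries=len(records),
        papers=len({r.reference for r in records}),
    )


def statements_to_model(records: list[StatementRecord], index: OntologyIndex,
                        model_id: str = "statements", title: str = ""
                        ) -> CeNCAMModel:
    """Build a model from statement rows.

    Each distinct (record, chain position) class occurrence becomes its own
    individual — classes are not merged across records (two serotonin
    mentions stay two nodes unless merged explicitly).  Each chain link
    becomes one assertion evidenced by the record's reference and local id.

    Chains are written left-to-right, but *context* links (occurs in,
    enabled by, the chemical-participation relations, has quality) qualify
    the current process rather than extending the backbone: in
    ``[membrane depolarization] occurs in [uv1] part of [negative regulation
    of egg deposition]`` the *part of* subject is the depolarization process,
    not the cell.  Causal and mereological links advance the backbone.
    """
    missing: dict[str, list[str]] = {}
    for r in records:
        for s, rel, o in r.triple_chain:
            for c in (s, o):
                if c not in index:
                    missing.setdefault(c, []).append(r.local_id)
    if missing:
        detail = "; ".join(f"{c} (records {', '.join(sorted(set(ids)))})"
                           for c, ids in sorted(missing.items()))
        raise UnknownTermError(f"unresolved CURIEs in statement table: {detail}")

    m = CeNCAMModel(model_id, title, index=index)
    backbone_moves = {"causal", "mereological"}
    for r in records:
        ev = (Evidence(DEFAULT_TABLE_EVIDENCE, f"{r.reference}|{r.local_id}"),)
        node_ids = []
        for i, (s, rel, o) in enumerate(r.triple_chain):
            if i == 0:
                node_ids.append(m.add_individual(s))
            node_ids.append(m.add_individual(o))
        backbone = node_ids[0]
        for i, (s, rel, o) in enumerate(r.triple_chain):
            m.assert_edge(backbone, rel, node_ids[i + 1], evidence=ev)
            if index.relation(rel).category in backbone_moves:
                backbone = node_ids[i + 1]
    return m


# ---------------------------------------------------------------------------
# Graph exports
# ---------------------------------------------------------------------------


def _attr_graph(model: CeNCAMModel, index: OntologyIndex | None) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph(model_id=model.model_id, title=model.title)
    for iid in sorted(model.individuals):
        ind = model.individuals[iid]
        cls = ind.class_curie
        attrs = {"class_curie": cls}
        if index is not None and cls in index:
            attrs["label"] = index.label(cls)
            attrs["aspect"] = index.aspect(cls)
        g.add_node(iid, **attrs)
    for a in sorted(model.assertions, key=lambda a: a.assertion_id):
        sign = 0
        if index is not None and a.relation in index.relations:
            r = index.relation(a.relation)
            sign = r.sign if r.category == "causal" else 0
        attrs = {"relation": a.relation, "sign": sign, "provenance": a.provenance}
        if a.evidence:
            attrs["evidence"] = json.dumps(
                [{"eco": e.eco_curie, "reference": e.reference,
                  **({"quote": e.quote} if e.quote else {})} for e in a.evidence])
        g.add_edge(a.subject, a.object, key=a.assertion_id, **attrs)
    return g


def to_sif(model: CeNCAMModel, index: OntologyIndex | None = None) -> str:
    """Simple interaction format: one ``source<TAB>relation<TAB>target`` line
    per assertion, sorted."""
    lines = []
    for a in model.assertions:
        rel = (index.label(a.relation).replace(" ", "_")
               if index is not None and a.relation in index.relations
               else a.relation)
        lines.append(f"{a.subject}\t{rel}\t{a.object}")
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


def to_graphml(model: CeNCAMModel, index: OntologyIndex | None = None) -> str:
    g = _attr_graph(model, index)
    return "\n".join(nx.generate_graphml(g)) + "\n"


def model_from_graphml(text: str, index: OntologyIndex | None = None,
                       model_id: str | None = None) -> CeNCAMModel:
    """Rebuild a model from a GraphML export (inverse of :func:`to_graphml`)."""
    from .model import Individual

    g = nx.parse_graphml(text, force_multigraph=True)
    m = CeNCAMModel(model_id or g.graph.get("model_id", "graphml"),
                    g.graph.get("title", ""), index=index)
    # Individuals are reconstructed directly so the original ids survive.
    for iid in sorted(g.nodes):
        m.individuals[iid] = Individual(iid, g.nodes[iid]["class_curie"])

    def _key_order(e):  # natural order for a1, a2, ... a10
        k = e[2]
        return (0, int(k[1:])) if k[1:].isdigit() else (1, k)

    edges = sorted(g.edges(keys=True), key=_key_order)
    for s, o, k in edges:
        d = g.edges[s, o, k]
        ev = tuple(Evidence(e["eco"], e["reference"], e.get("quote"))
                   for e in json.loads(d["evidence"])) if "evidence" in d else ()
        m.assert_edge(s, d["relation"], o, evidence=ev,
                      provenance=d.get("provenance", "asserted"))
    return m


def to_cx_json(model: CeNCAMModel, index: OntologyIndex | None = None) -> str:
    g = _attr_graph(model, index)
    doc = {
        "model_id": model.model_id,
        "title": model.title,
        "nodes": [{"id": n, **g.nodes[n]} for n in sorted(g.nodes)],
        "edges": [
            {"id": k, "source": s, "target": o, **g.edges[s, o, k]}
            for s, o, k in sorted(g.edges(keys=True), key=lambda e: e[2])
        ],
    }
    return json.dumps(doc, indent=2) + "\n"


def to_turtle(model: CeNCAMModel, index: OntologyIndex | None = None) -> str:
    """RDF Turtle: one named individual per instance (typed to the OBO PURL
    of its class), one triple per assertion (RO/BFO IRI); evidence is reified
    as an rdf:Statement annotated with the ECO PURL and the reference."""
    from rdflib import BNode, Graph, Literal, Namespace, RDF, URIRef

    CEN = Namespace(CENCAM_NS)
    g = Graph()
    g.bind("cencam", CEN)
    g.bind("obo", "http://purl.obolibrary.org/obo/")

    def ind_iri(iid: str) -> URIRef:
        return URIRef(f"{CENCAM_NS}model/{model.model_id}/{iid.replace('#', '_')}")

    for iid in sorted(model.individuals):
        g.add((ind_iri(iid), RDF.type,
               URIRef(curie_to_iri(model.individuals[iid].class_curie))))
    for a in model.assertions:
        s, p, o = ind_iri(a.subject), URIRef(curie_to_iri(a.relation)), ind_iri(a.object)
        g.add((s, p, o))
        for e in a.evidence:
            st = BNode()
            g.add((st, RDF.type, RDF.Statement))
            g.add((st, RDF.subject, s))
            g.add((st, RDF.predicate, p))
            g.add((st, RDF.object, o))
            g.add((st, CEN.evidenceCode, URIRef(curie_to_iri(e.eco_curie))))
            g.add((st, CEN.reference, Literal(e.reference)))
            if e.quote:
                g.add((st, CEN.quote, Literal(e.quote)))
    return g.serialize(format="turtle")


def export_graph(model: CeNCAMModel, format: str,
                 index: OntologyIndex | None = None) -> str:
    """Serialize a model; see :data:`EXPORT_FORMATS`.

    Exports never invent or drop nodes: element counts equal the model's, and
    element order is deterministic (sorted ids), so repeated exports are
    byte-identical.
    """
    if format == "sif":
        return to_sif(model, index)
    if format == "graphml":
        return to_graphml(model, index)
    if format == "cx_json":
        return to_cx_json(model, index)
    if format == "turtle":
        return to_turtle(model, index)
    if format == "native_json":
        return model.to_json()
    raise UnknownFormatError(f"unknown export format {format!r}")
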