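"""Statement-category templates and subsumption-constrained instantiation.

Each experimental-result category that has a circuit shape (ablation,
activation, rescue, the three neuron-to-neuron connection kinds) ships as a
:class:`Template`: a slot graph over *generic* classes and relations.  A
concrete model is produced by binding each slot to the generic class itself
or one of its is_a descendants — the availability of terms is constrained by
parentage — and optionally re-typing edges to more specific relations.

The category vocabulary (the full printed list of neurobiological phenomenon
categories) is shipped alongside; its mapping onto templates is partial and
many-to-one — unmapped categories are first-class vocabulary for tagging
statements, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .errors import BindingError, TemplateError
from .model import CeNCAMModel, Evidence
from .ontology import OntologyIndex

TEMPLATE_NAMES = (
    "neuron_to_behavior_ablation",
    "neuron_to_behavior_activation",
    "input_neuron_behavior_rescue",
    "neuron_to_neuron_agnostic",
    "neuron_to_neuron_synaptic",
    "neuron_to_neuron_extrasynaptic_peptidergic",
)


@dataclass(frozen=True)
class Slot:
    slot_id: str
    generic: str
    required: bool = True


@dataclass(frozen=True)
class TemplateEdge:
    subject: str
    relation: str
    object: str
    #: alternative edge generics (e.g. has_input besides has small molecule
    #: activator on the rescue template's chemical slot)
    alt_relations: tuple[str, ...] = ()


@dataclass(frozen=True)
class Template:
    name: str
    description: str
    slots: tuple[Slot, ...]
    edges: tuple[TemplateEdge, ...]

    def slot(self, slot_id: str) -> Slot:
        for s in self.slots:
            if s.slot_id == slot_id:
                return s
        raise TemplateError(f"template {self.name!r} has no slot {slot_id!r}")


@dataclass(frozen=True)
class CategoryLabel:
    label: str
    section: str
    mapped_template: str | None = None


def _data_text(name: str) -> str:
    return (resources.files("cencam") / "data" / name).read_text()


@lru_cache(maxsize=1)
def _load() -> tuple[tuple[Template, ...], tuple[CategoryLabel, ...]]:
    doc = yaml.safe_load(_data_text("templates.yaml"))
    templates = tuple(
        Template(
            name=t["name"],
            description=t.get("description", "").strip(),
            slots=tuple(Slot(s["id"], s["generic"], s.get("required", True))
                        for s in t["slots"]),
            edges=tuple(TemplateEdge(e["subject"], e["relation"], e["object"],
                                     tuple(e.get("alt_relations", ())))
                        for e in t["edges"]),
        )
        for t in doc["templates"]
    )
    cats = tuple(CategoryLabel(c["label"], c.get("section", ""), c.get("template"))
                 for c in doc["categories"])
    return templates, cats


def builtin_templates() -> list[Template]:
    """The six shipped statement-category templates."""
    return list(_load()[0])


def get_template(name: str) -> Template:
    for t in _load()[0]:
        if t.name == name:
            return t
    raise TemplateError(f"unknown template {name!r}")


def categories() -> list[CategoryLabel]:
    """The full category vocabulary (mapping onto templates is partial)."""
    return list(_load()[1])


def classify(label: str) -> str | None:
    """Template name for a category label, or None for unmapped categories.

    Unknown labels (not in the vocabulary) raise :class:`TemplateError`.
    """
    for c in _load()[1]:
        if c.label == label:
            return c.mapped_template
    raise TemplateError(f"unknown category label {label!r}")


def _default_index() -> OntologyIndex:
    from .fixtures import builtin_ontology  # local import: fixtures uses templates

    return builtin_ontology()


def instantiate(template: Template,
                bindings: dict[str, str],
                edge_overrides: dict[tuple[str, str], str] | None = None,
                index: OntologyIndex | None = None,
                evidence: tuple[Evidence, ...] = (),
                model_id: str | None = None,
                title: str = "") -> CeNCAMModel:
    """Bind slots to classes and produce a validating model.

    Every binding must be the slot generic or one of its is_a descendants
    (else ``BINDING_NOT_SUBSUMED``); every override relation, keyed by
    ``(subject_slot, object_slot)``, must descend from the edge generic or
    one of its listed alternatives.  Optional slots left unbound are dropped
    together with their incident edges; required slots must be bound.
    """
    idx = index if index is not None else _default_index()
    overrides = dict(edge_overrides or {})

    for s in template.slots:
        if s.required and s.slot_id not in bindings:
            raise TemplateError(
                f"required slot {s.slot_id!r} of {template.name!r} is unbound")
    for slot_id, curie in bindings.items():
        s = template.slot(slot_id)
        if not idx.is_descendant(curie, s.generic):
            raise BindingError(slot_id, curie, s.generic)

    model = CeNCAMModel(model_id or f"template:{template.name}",
                        title or template.name, index=idx)
    model.metadata["template"] = template.name
    ids = {slot_id: model.add_individual(curie)
           for slot_id, curie in bindings.items()
           if any(s.slot_id == slot_id for s in template.slots)}

    for e in template.edges:
        if e.subject not in ids or e.object not in ids:
            continue  # incident to an unbound optional slot
        rel = e.relation
        key = (e.subject, e.object)
        if key in overrides:
            rel = overrides.pop(key)
            allowed = (idx.relation_descends(rel, e.relation)
                       or any(idx.relation_descends(rel, alt)
                              for alt in e.alt_relations))
            if not allowed:
                raise TemplateError(
                    f"override {rel!r} does not descend from {e.relation!r} "
                    f"(or alternatives) on edge {key}")
        model.assert_edge(ids[e.subject], rel, ids[e.object], evidence=evidence)
    if overrides:
        raise TemplateError(f"overrides for unknown edges: {sorted(overrides)}")
    return model


def self_instantiate(template: Template,
                     index: OntologyIndex | None = None) -> CeNCAMModel:
    """Instantiate a template with its own generics (all slots bound)."""
    return instantiate(template,
                       {s.slot_id: s.generic for s in template.slots},
                       index=index)
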