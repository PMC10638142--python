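"""Exception hierarchy for cencam.

Every error raised by the library derives from :class:`CencamError` so callers
(and the CLI) can catch one type.  Validation problems inside a model are *not*
exceptions: they are returned as :class:`cencam.model.Violation` records.
"""


class CencamError(Exception):
    """Base class for all cencam errors."""


class CurieError(CencamError):
    """A CURIE is malformed or uses an unregistered prefix."""


class OntologyError(CencamError):
    """Generic ontology construction/lookup problem."""


class DuplicateTermError(OntologyError):
    """The same id appears in more than one [Term] stanza."""


class CycleError(OntologyError):
    """The is_a graph contains a cycle.

    The offending cycle is available as the ``cycle`` attribute.
    """

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cyclic is_a parentage: " + " -> ".join(self.cycle))


class UnknownTermError(OntologyError):
    """A CURIE does not resolve in the ontology index."""


class UnknownRelationError(OntologyError):
    """A relation CURIE does not resolve in the relation registry."""


class ModelError(CencamError):
    """Structural problem while building a model (dangling endpoint etc.)."""


class SpecializationError(ModelError):
    """ILLEGAL_SPECIALIZATION: target relation does not descend from the source."""


class TemplateError(CencamError):
    """Template lookup/instantiation problem."""


class BindingError(TemplateError):
    """BINDING_NOT_SUBSUMED: a slot binding is not a descendant of the generic."""

    def __init__(self, slot_id, curie, generic):
        self.slot_id = slot_id
        self.curie = curie
        self.generic = generic
        super().__init__(
            f"binding {curie!r} for slot {slot_id!r} is not subsumed by {generic!r}"
        )


class TableFormatError(CencamError):
    """Malformed statement table (bad CURIE, odd column parity...)."""


class UnknownFormatError(CencamError):
    """Unknown export format name."""
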