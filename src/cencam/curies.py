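"""CURIE handling: prefix registry, normalization, and IRI expansion.

Identifiers follow the ``PREFIX:LOCALID`` convention of the OBO world
(``GO:0051899``, ``WBbt:0006830``, ``CHEBI:28790``).  The published sources
this package models are not always tidy about it — ids appear with stray
spaces (``GO: 0051899``), thousands separators (``CHEBI: 28,790``), underscore
separators (``RO_0002479``) and truncated local ids (``RO:002304``) — so every
identifier entering the library goes through :func:`normalize_curie`.

Proposed classes that have no id in any public ontology yet use the
package-local ``CeNCAM:`` prefix with snake_case local ids.
"""

from __future__ import annotations

from .errors import CurieError

#: Registered prefixes mapped to the zero-padded width of their numeric local
#: id (None = local id is free-form, not padded).
PREFIXES: dict[str, int | None] = {
    "GO": 7,
    "WBbt": 7,
    "WBGene": 8,
    "CHEBI": None,
    "ECO": 7,
    "ECTO": 7,
    "PATO": 7,
    "RO": 7,
    "BFO": 7,
    "CeNCAM": None,
}

#: Prefixes whose aspect is decided by the prefix alone.  GO and CeNCAM need
#: an explicit namespace; WBGene ids are gene identifiers outright.
PREFIX_ASPECT = {
    "WBbt": "anatomy",
    "CHEBI": "chemical",
    "WBGene": "gene",
    "ECO": "evidence",
    "ECTO": "exposure",
    "PATO": "quality",
}

# Case-insensitive lookup helper (the sources print "ChEBI", "WBBt"...).
_PREFIX_BY_LOWER = {p.lower(): p for p in PREFIXES}

_OBO_PURL = "http://purl.obolibrary.org/obo/"
#: Namespace for package-local proposed classes and for named individuals.
CENCAM_NS = "https://w3id.org/cencam/"


def normalize_curie(raw: str) -> str:
    """Return the canonical ``PREFIX:LOCALID`` form of *raw*.

    Handles separator variants (``:``, ``_``, with or without spaces), strips
    thousands separators from numeric local ids, zero-pads fixed-width local
    ids, and canonicalizes prefix capitalization.  ``WBGene00006600`` (no
    separator) is also accepted.

    Raises
    ------
    CurieError
        If the prefix is not registered or the local id is empty.
    """
    s = raw.strip()
    if not s:
        raise CurieError("empty CURIE")
    prefix = local = None
    for sep in (":", "_"):
        if sep in s:
            prefix, local = s.split(sep, 1)
            break
    if prefix is None:
        # WBGene00006600-style fused id
        for p in PREFIXES:
            if s.lower().startswith(p.lower()) and s[len(p):]:
                prefix, local = s[: len(p)], s[len(p):]
                break
        if prefix is None:
            raise CurieError(f"cannot parse CURIE {raw!r}")
    canon = _PREFIX_BY_LOWER.get(prefix.strip().lower())
    if canon is None:
        raise CurieError(f"unregistered prefix {prefix!r} in CURIE {raw!r}")
    local = local.strip().replace(",", "").replace(" ", "")
    if not local:
        raise CurieError(f"empty local id in CURIE {raw!r}")
    width = PREFIXES[canon]
    if width is not None:
        if not local.isdigit():
            raise CurieError(f"non-numeric local id in CURIE {raw!r}")
        if len(local) > width:
            raise CurieError(f"local id wider than {width} digits in {raw!r}")
        local = local.zfill(width)
    return f"{canon}:{local}"


def curie_prefix(curie: str) -> str:
    return curie.split(":", 1)[0]


def curie_local(curie: str) -> str:
    return curie.split(":", 1)[1]


def curie_to_iri(curie: str) -> str:
    """Expand a CURIE to an IRI (OBO PURL; CeNCAM under the package namespace)."""
    prefix, local = curie.split(":", 1)
    if prefix == "CeNCAM":
        return f"{CENCAM_NS}{local}"
    if prefix == "WBGene":
        return f"{_OBO_PURL}WBGene_{local}"
    return f"{_OBO_PURL}{prefix}_{local}"
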