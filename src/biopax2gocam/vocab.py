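"""Shared CURIE/IRI vocabulary for GO-CAM output graphs.

All identifiers are handled internally as CURIEs (``GO:0047127``,
``UniProt:P01116``, ``REACTO:R-HSA-5693347``) and expanded to full IRIs
only at serialization time, using the fixed prefix map below.
"""

from __future__ import annotations

PREFIXES: dict[str, str] = {
    "GO": "http://purl.obolibrary.org/obo/GO_",
    "CHEBI": "http://purl.obolibrary.org/obo/CHEBI_",
    "RO": "http://purl.obolibrary.org/obo/RO_",
    "BFO": "http://purl.obolibrary.org/obo/BFO_",
    "ECO": "http://purl.obolibrary.org/obo/ECO_",
    "UniProt": "http://identifiers.org/uniprot/",
    "REACTO": "http://purl.obolibrary.org/obo/go/extensions/reacto.owl#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "dc": "http://purl.org/dc/elements/1.1/",
    "lego": "http://geneontology.org/lego/",
    "gocam": "http://model.geneontology.org/",
}

#: base URL for model identifiers (one model per pathway core ID)
MODEL_BASE = PREFIXES["gocam"]

# -- object properties ------------------------------------------------------
ENABLED_BY = "RO:0002333"
HAS_INPUT = "RO:0002233"
HAS_OUTPUT = "RO:0002234"
OCCURS_IN = "BFO:0000066"
PART_OF = "BFO:0000050"
HAS_PART = "BFO:0000051"

# the four causal relations emitted on activity->activity edges
CAUSALLY_UPSTREAM_OF = "RO:0002411"
PROVIDES_INPUT_FOR = "RO:0002413"
DIRECTLY_POSITIVELY_REGULATES = "RO:0002629"
DIRECTLY_NEGATIVELY_REGULATES = "RO:0002630"

# start/end locations of a transported entity
TRANSPORT_START_LOCATION = "RO:0002338"
TRANSPORT_END_LOCATION = "RO:0002339"

CAUSAL_RELATIONS = frozenset(
    {
        CAUSALLY_UPSTREAM_OF,
        PROVIDES_INPUT_FOR,
        DIRECTLY_POSITIVELY_REGULATES,
        DIRECTLY_NEGATIVELY_REGULATES,
    }
)

#: closed vocabulary of relations allowed on edges in an output model
EDGE_RELATIONS = CAUSAL_RELATIONS | frozenset(
    {
        ENABLED_BY,
        HAS_INPUT,
        HAS_OUTPUT,
        OCCURS_IN,
        PART_OF,
        TRANSPORT_START_LOCATION,
        TRANSPORT_END_LOCATION,
    }
)

# -- classes ----------------------------------------------------------------
MF_ROOT = "GO:0003674"  # molecular_function
BP_ROOT = "GO:0008150"  # biological_process
BINDING = "GO:0005488"  # binding
TRANSPORTER_ACTIVITY = "GO:0005215"
INFORMATION_BIOMACROMOLECULE = "CHEBI:33695"
#: generated superclass covering both gene-product-enabled molecular
#: functions and activities whose enabler is unspecified
MOLECULAR_EVENT = "REACTO:molecular_event"

#: default evidence class for automatically asserted statements
#: (computational combinatorial evidence used in automatic assertion)
DEFAULT_ECO = "ECO:0000363"


def expand(curie_or_iri: str) -> str:
    """Expand a CURIE to a full IRI; full IRIs pass through unchanged."""
    if curie_or_iri.startswith("http://") or curie_or_iri.startswith("https://"):
        return curie_or_iri
    prefix, _, local = curie_or_iri.partition(":")
    base = PREFIXES.get(prefix)
    if base is None:
        raise ValueError(f"unknown CURIE prefix in {curie_or_iri!r}")
    return base + local


def contract(iri: str) -> str:
    """Contract a full IRI to a CURIE where a prefix matches (longest wins)."""
    best: tuple[int, str, str] | None = None
    for prefix, base in PREFIXES.items():
        if iri.startswith(base) and (best is None or len(base) > best[0]):
            best = (len(base), prefix, iri[len(base):])
    if best is None:
        return iri
    return f"{best[1]}:{best[2]}"
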