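"""GO-CAM OWL instance-graph serialization (Turtle) and read-back.

A model is an OWL instance graph: typed ``owl:NamedIndividual`` nodes
joined by object properties from a closed relation vocabulary, with
evidence captured as OWL axiom annotations (an ECO-typed evidence
individual and the source reaction's stable identifier as reference).

Output is byte-deterministic: individuals get IRIs minted from the
model IRI and a strictly increasing ordinal, axiom/evidence nodes are
named (no blank nodes), and triples are emitted in sorted order, so
identical inputs and configuration always produce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import rdflib
from rdflib import OWL, RDF, RDFS, URIRef

from . import vocab
from .conversion import ConversionConfig, GoCamModelSkeleton
from .reacto import EntityOntology

Edge = tuple[str, str, str]

_DC_TITLE = "dc:title"
_DC_SOURCE = "dc:source"
_MODELSTATE = "lego:modelstate"
_EVIDENCE_PROP = "lego:evidence"


@dataclass
class GoCamDocument:
    """Flattened view of one model: metadata, typed individuals, edges,
    and per-edge evidence annotations."""

    model_id: str
    title: str = ""
    state: str = "automated"
    comment: str = ""
    individuals: list[tuple[str, str]] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    evidence: dict[Edge, tuple[str, str]] = field(default_factory=dict)


def mint_individual_iri(model_id: str, ordinal: int) -> str:
    """Deterministic individual IRI: model IRI + zero-padded ordinal."""
    return f"{model_id}/{ordinal:06d}"


def skeleton_to_document(
    model: GoCamModelSkeleton, config: Optional[ConversionConfig] = None
) -> GoCamDocument:
    """Expand a model skeleton into the full instance graph.

    Mints individuals for enablers, participants, locations and
    processes (one process individual per distinct process class);
    every asserted edge gets an evidence annotation referencing the
    source reaction.
    """
    config = config or ConversionConfig()
    doc = GoCamDocument(
        model_id=model.model_id,
        title=model.title,
        comment=f"source: {model.provenance}" if model.provenance else "",
    )
    counter = model.next_ordinal

    def mint() -> str:
        nonlocal counter
        iri = mint_individual_iri(model.model_id, counter)
        counter += 1
        return iri

    def add_edge(s: str, p: str, o: str, ref: str) -> None:
        edge = (s, p, o)
        if edge not in doc.evidence:
            doc.edges.append(edge)
            doc.evidence[edge] = (config.eco_class, ref)

    process_nodes: dict[str, str] = {}

    def process_individual(process_class: str) -> str:
        if process_class not in process_nodes:
            iri = mint()
            doc.individuals.append((iri, process_class))
            process_nodes[process_class] = iri
        return process_nodes[process_class]

    for unit in model.activities:
        ref = unit.source_reaction or "regulator-conversion"
        doc.individuals.append((unit.activity_id, unit.function_class))
        if unit.enabler:
            ind = mint()
            doc.individuals.append((ind, unit.enabler))
            add_edge(unit.activity_id, vocab.ENABLED_BY, ind, ref)
            if unit.enabler_location:
                loc_ind = mint()
                doc.individuals.append((loc_ind, unit.enabler_location))
                add_edge(ind, vocab.OCCURS_IN, loc_ind, ref)
        for relation, participants in (
            (vocab.HAS_INPUT, unit.inputs),
            (vocab.HAS_OUTPUT, unit.outputs),
        ):
            for cls, loc in participants:
                ind = mint()
                doc.individuals.append((ind, cls))
                add_edge(unit.activity_id, relation, ind, ref)
                if loc:
                    loc_ind = mint()
                    doc.individuals.append((loc_ind, loc))
                    add_edge(ind, vocab.OCCURS_IN, loc_ind, ref)
        if unit.location:
            loc_ind = mint()
            doc.individuals.append((loc_ind, unit.location))
            add_edge(unit.activity_id, vocab.OCCURS_IN, loc_ind, ref)
        for relation, loc in (
            (vocab.TRANSPORT_START_LOCATION, unit.transport_from),
            (vocab.TRANSPORT_END_LOCATION, unit.transport_to),
        ):
            if loc:
                loc_ind = mint()
                doc.individuals.append((loc_ind, loc))
                add_edge(unit.activity_id, relation, loc_ind, ref)
        add_edge(unit.activity_id, vocab.PART_OF, process_individual(unit.process_class), ref)
    activity_ids = {u.activity_id for u in model.activities}
    for unit in model.activities:
        ref = unit.source_reaction or "regulator-conversion"
        for edge in unit.causal_edges:
            if edge.target not in activity_ids or edge.source not in activity_ids:
                raise ValueError(
                    f"edge references unminted individual: {edge.source} -> {edge.target}"
                )
            add_edge(edge.source, edge.relation, edge.target, ref)
    for sub_id, process_class in model.subpathway_nodes:
        ind = mint()
        doc.individuals.append((ind, process_class))
    return doc


# ---------------------------------------------------------------------------
# Turtle writing


def _term(curie_or_iri: str) -> str:
    if curie_or_iri.startswith("http://") or curie_or_iri.startswith("https://"):
        return f"<{curie_or_iri}>"
    return curie_or_iri  # prefixed name; prefixes declared in the header


def _literal(text: str) -> str:
    escaped = text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")
    return f'"{escaped}"'


def write_gocam(
    model: Union[GoCamModelSkeleton, GoCamDocument],
    config: Optional[ConversionConfig] = None,
) -> bytes:
    """Serialize a model as Turtle with sorted, stable triple ordering."""
    doc = model if isinstance(model, GoCamDocument) else skeleton_to_document(model, config)

    unknown = {p for _s, p, _o in doc.edges if p not in vocab.EDGE_RELATIONS}
    if unknown:
        raise ValueError(f"relations outside the declared vocabulary: {sorted(unknown)}")

    triples: list[tuple[str, str, str]] = []
    m = f"<{doc.model_id}>"
    triples.append((m, "rdf:type", "owl:Ontology"))
    if doc.title:
        triples.append((m, _DC_TITLE, _literal(doc.title)))
    triples.append((m, _MODELSTATE, _literal(doc.state)))
    if doc.comment:
        triples.append((m, "rdfs:comment", _literal(doc.comment)))

    for iri, cls in doc.individuals:
        triples.append((_term(iri), "rdf:type", "owl:NamedIndividual"))
        triples.append((_term(iri), "rdf:type", _term(cls)))

    sorted_edges = sorted(doc.edges)
    for s, p, o in sorted_edges:
        triples.append((_term(s), _term(p), _term(o)))
    for i, edge in enumerate(sorted_edges, start=1):
        s, p, o = edge
        eco, ref = doc.evidence.get(edge, (vocab.DEFAULT_ECO, ""))
        ax = f"<{doc.model_id}/axiom/{i:06d}>"
        ev = f"<{doc.model_id}/evidence/{i:06d}>"
        triples += [
            (ax, "rdf:type", "owl:Axiom"),
            (ax, "owl:annotatedSource", _term(s)),
            (ax, "owl:annotatedProperty", _term(p)),
            (ax, "owl:annotatedTarget", _term(o)),
            (ax, _EVIDENCE_PROP, ev),
            (ev, "rdf:type", "owl:NamedIndividual"),
            (ev, "rdf:type", _term(eco)),
        ]
        if ref:
            triples.append((ev, _DC_SOURCE, _literal(ref)))

    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(vocab.PREFIXES.items())]
    lines.append("")
    for s, p, o in sorted(set(triples)):
        lines.append(f"{s} {p} {o} .")
    lines.append("")
    return "\n".join(lines).encode("utf-8")


# ---------------------------------------------------------------------------
# reading


def read_gocam(data: bytes | str) -> GoCamDocument:
    """Parse a Turtle GO-CAM back into a :class:`GoCamDocument`.

    The result is isomorphic to what :func:`write_gocam` emitted
    (identical individual and edge multisets, evidence preserved).
    """
    g = rdflib.Graph()
    g.parse(data=data, format="turtle")

    model_node = next(g.subjects(RDF.type, OWL.Ontology), None)
    if model_node is None:
        raise ValueError("not a GO-CAM document: no owl:Ontology node")
    dc_title = URIRef(vocab.expand("dc:title"))
    dc_source = URIRef(vocab.expand("dc:source"))
    modelstate = URIRef(vocab.expand("lego:modelstate"))
    evidence_prop = URIRef(vocab.expand("lego:evidence"))

    doc = GoCamDocument(model_id=str(model_node))
    doc.title = str(next(g.objects(model_node, dc_title), ""))
    doc.state = str(next(g.objects(model_node, modelstate), "automated"))
    doc.comment = str(next(g.objects(model_node, RDFS.comment), ""))

    axioms = set(g.subjects(RDF.type, OWL.Axiom))
    evidence_nodes = {o for ax in axioms for o in g.objects(ax, evidence_prop)}

    # individual IRIs stay in full form; only classes/relations contract
    for s in sorted(set(g.subjects(RDF.type, OWL.NamedIndividual)), key=str):
        if s in evidence_nodes:
            continue
        for t in sorted(g.objects(s, RDF.type), key=str):
            if t in (OWL.NamedIndividual,):
                continue
            doc.individuals.append((str(s), vocab.contract(str(t))))

    relation_iris = {vocab.expand(r): r for r in vocab.EDGE_RELATIONS}
    for s, p, o in g:
        rel = relation_iris.get(str(p))
        if rel is None or s in axioms:
            continue
        doc.edges.append((str(s), rel, str(o)))
    doc.edges.sort()
    doc.individuals.sort()

    for ax in axioms:
        s = next(g.objects(ax, OWL.annotatedSource), None)
        p = next(g.objects(ax, OWL.annotatedProperty), None)
        o = next(g.objects(ax, OWL.annotatedTarget), None)
        ev = next(g.objects(ax, evidence_prop), None)
        if None in (s, p, o) or ev is None:
            continue
        eco = ""
        for t in g.objects(ev, RDF.type):
            if t != OWL.NamedIndividual:
                eco = vocab.contract(str(t))
        ref = str(next(g.objects(ev, dc_source), ""))
        edge = (str(s), vocab.contract(str(p)), str(o))
        doc.evidence[edge] = (eco, ref)
    return doc


# ---------------------------------------------------------------------------
# entity-ontology serialization


def write_entity_ontology(ontology: EntityOntology) -> bytes:
    """Serialize the generated entity ontology as Turtle (sorted, stable)."""
    triples: list[tuple[str, str, str]] = []
    for iri in sorted(ontology.classes):
        cls = ontology.classes[iri]
        s = _term(iri)
        triples.append((s, "rdf:type", "owl:Class"))
        if cls.label:
            triples.append((s, "rdfs:label", _literal(cls.label)))
        for sup in cls.superclasses:
            triples.append((s, "rdfs:subClassOf", _term(sup)))
        for rel, part in cls.component_links:
            triples.append((s, _term(rel), _term(part)))
        for x in cls.xrefs:
            triples.append((s, "rdfs:seeAlso", _term(x)))
        if cls.definition:
            triples.append((s, "rdfs:comment", _literal(cls.definition)))
        if cls.union_members is not None:
            # named class carrying its union members as annotations plus
            # an owl:unionOf list for OWL consumers
            for m in cls.union_members:
                triples.append((s, "rdfs:seeAlso", _term(m)))
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(vocab.PREFIXES.items())]
    lines.append("")
    for iri in sorted(ontology.classes):
        cls = ontology.classes[iri]
        if cls.union_members:
            members = " ".join(_term(m) for m in cls.union_members)
            lines.append(f"{_term(iri)} owl:equivalentClass [ rdf:type owl:Class ; owl:unionOf ( {members} ) ] .")
    for s, p, o in sorted(set(triples)):
        lines.append(f"{s} {p} {o} .")
    lines.append("")
    return "\n".join(lines).encode("utf-8")
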