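"""BioPAX Level-3 reading, corpus filtering and reaction classification.

A BioPAX Level-3 document (RDF/XML) is read into a typed in-memory
pathway graph: pathways, biochemical reactions, physical entities
(with complex components and set members resolved recursively),
control relationships, cellular locations and relationship
cross-references.  GO / UniProt / ChEBI cross-references are
normalized to CURIEs with a fixed prefix map.

Reactions are classified into the shape categories that drive the
process-description to activity-flow conversion: *catalyzed*,
*transport*, *binding*, *dissociation*, *black_box* and *other*.
Binding and dissociation are recognized structurally as events with
different numbers of inputs and outputs and no associated catalysis.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import rdflib
from rdflib import RDF, RDFS, Namespace, URIRef

log = logging.getLogger(__name__)

BP3 = Namespace("http://www.biopax.org/release/biopax-level3.owl#")

#: BioPAX class local-name -> PhysicalEntity.kind
_ENTITY_KINDS = {
    "Protein": "protein",
    "SmallMolecule": "small_molecule",
    "Complex": "complex",
    "Dna": "nucleic_acid",
    "DnaRegion": "nucleic_acid",
    "Rna": "nucleic_acid",
    "RnaRegion": "nucleic_acid",
    "PhysicalEntity": "other",
    "SimplePhysicalEntity": "other",
}

_REACTION_CLASSES = {
    "BiochemicalReaction",
    "Transport",
    "TransportWithBiochemicalReaction",
    "ComplexAssembly",
    "Degradation",
    "TemplateReaction",
    "Conversion",
}

_CONTROL_CLASSES = {"Catalysis", "Control", "Modulation", "TemplateReactionRegulation"}

#: xref databases whose presence marks an entity as a drug
_DRUG_DBS = {"drugbank", "iuphar", "guide to pharmacology", "drugcentral"}

_KNOWN_UTILITY_CLASSES = {
    "Pathway", "PathwayStep", "BiochemicalPathwayStep", "Provenance",
    "UnificationXref", "RelationshipXref", "PublicationXref",
    "CellularLocationVocabulary", "SequenceModificationVocabulary",
    "RelationshipTypeVocabulary", "ModificationFeature", "FragmentFeature",
    "SequenceSite", "SequenceInterval", "Stoichiometry", "BindingFeature",
    "ProteinReference", "SmallMoleculeReference", "DnaReference",
    "RnaReference", "DnaRegionReference", "RnaRegionReference",
    "EntityReference", "ChemicalStructure", "Evidence", "Score",
    "ExperimentalForm", "EvidenceCodeVocabulary", "InteractionVocabulary",
    "Drug",
}


class BiopaxParseError(ValueError):
    """Raised for malformed RDF/XML input, naming the failure position."""


class ReactionCategory(str, Enum):
    """Shape category of a conversion event; exactly one per reaction."""

    CATALYZED = "catalyzed"
    TRANSPORT = "transport"
    BINDING = "binding"
    DISSOCIATION = "dissociation"
    BLACK_BOX = "black_box"
    OTHER = "other"


@dataclass
class PhysicalEntity:
    """A pool of molecules: protein, small molecule, complex, set, ...

    One entity is minted per physical-entity x location combination by
    the source database, so each entity carries at most one location.
    """

    local_id: str
    display_name: str = ""
    kind: str = "other"
    reference_xrefs: list[str] = field(default_factory=list)
    location_term: Optional[str] = None
    location_label: Optional[str] = None
    modifications: list[str] = field(default_factory=list)
    components: list["PhysicalEntity"] = field(default_factory=list)
    members: list["PhysicalEntity"] = field(default_factory=list)
    is_drug: bool = False

    def participant_closure(self) -> Iterable["PhysicalEntity"]:
        """This entity plus all components/members, recursively."""
        seen: set[str] = set()
        stack = [self]
        while stack:
            e = stack.pop()
            if e.local_id in seen:
                continue
            seen.add(e.local_id)
            yield e
            stack.extend(e.components)
            stack.extend(e.members)


@dataclass
class Control:
    controller: PhysicalEntity
    controlled: str  # reaction local_id
    control_type: str  # catalysis | activation | inhibition


@dataclass
class Reaction:
    local_id: str
    display_name: str = ""
    inputs: list[PhysicalEntity] = field(default_factory=list)
    outputs: list[PhysicalEntity] = field(default_factory=list)
    controls: list[Control] = field(default_factory=list)
    mf_xrefs: list[str] = field(default_factory=list)
    category: Optional[ReactionCategory] = None
    is_transport: bool = False  # catalyzed reactions may be transport-shaped

    def catalysis_controls(self) -> list[Control]:
        return [c for c in self.controls if c.control_type == "catalysis"]

    def participants(self) -> list[PhysicalEntity]:
        out = list(self.inputs) + list(self.outputs)
        out.extend(c.controller for c in self.catalysis_controls())
        return out


@dataclass
class Pathway:
    local_id: str
    display_name: str = ""
    step_reactions: list[str] = field(default_factory=list)
    next_steps: list[tuple[str, str]] = field(default_factory=list)
    bp_xrefs: list[str] = field(default_factory=list)
    subpathways: list[str] = field(default_factory=list)
    is_disease: bool = False


@dataclass
class PathwayCollection:
    pathways: list[Pathway] = field(default_factory=list)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    entities: dict[str, PhysicalEntity] = field(default_factory=dict)
    source_version: str = ""
    unresolved: list[str] = field(default_factory=list)

    def pathway_by_id(self, local_id: str) -> Optional[Pathway]:
        for p in self.pathways:
            if p.local_id == local_id:
                return p
        return None


@dataclass
class FilterConfig:
    """Corpus filter: disease-branch roots and drug-reaction exclusion."""

    disease_roots: list[str] = field(default_factory=list)
    drug_filter: bool = True


# ---------------------------------------------------------------------------
# parsing


def _local_id(uri: URIRef) -> str:
    s = str(uri)
    if "#" in s:
        return s.rsplit("#", 1)[1]
    return s.rstrip("/").rsplit("/", 1)[-1]


def _normalize_xref(db: str, acc: str) -> Optional[str]:
    """Map a (db, id) cross-reference to a CURIE; None if unrecognized."""
    dbl = db.strip().lower()
    acc = acc.strip()
    if "uniprot" in dbl:
        return f"UniProt:{acc}"
    if "chebi" in dbl:
        return acc if acc.upper().startswith("CHEBI:") else f"CHEBI:{acc}"
    if dbl in {"gene ontology", "go", "gene_ontology"}:
        return acc if acc.upper().startswith("GO:") else f"GO:{acc}"
    return None


class _Parser:
    def __init__(self, graph: rdflib.Graph):
        self.g = graph
        self.collection = PathwayCollection()
        self._entity_cache: dict[URIRef, PhysicalEntity] = {}
        self._types: dict[URIRef, list[str]] = {}
        for s, o in self.g.subject_objects(RDF.type):
            if str(o).startswith(str(BP3)):
                self._types.setdefault(s, []).append(_local_id(o))

    # -- generic helpers ----------------------------------------------------
    def _values(self, s: URIRef, prop: URIRef) -> list:
        return sorted(self.g.objects(s, prop), key=str)

    def _literal(self, s: URIRef, prop: URIRef) -> str:
        for o in self.g.objects(s, prop):
            return str(o)
        return ""

    def _name(self, s: URIRef) -> str:
        return (
            self._literal(s, BP3.displayName)
            or self._literal(s, BP3.name)
            or self._literal(s, BP3.standardName)
        )

    def _xref_curies(self, node: URIRef, xref_classes: set[str]) -> list[str]:
        curies = []
        for x in self._values(node, BP3.xref):
            xtypes = self._types.get(x, [])
            if xref_classes and not (set(xtypes) & xref_classes):
                continue
            curie = _normalize_xref(self._literal(x, BP3.db), self._literal(x, BP3.id))
            if curie:
                curies.append(curie)
        return curies

    def _is_drug_xref(self, node: URIRef) -> bool:
        for x in self._values(node, BP3.xref):
            if self._literal(x, BP3.db).strip().lower() in _DRUG_DBS:
                return True
        return False

    # -- entities -----------------------------------------------------------
    def entity(self, node: URIRef) -> PhysicalEntity:
        if node in self._entity_cache:
            return self._entity_cache[node]
        types = self._types.get(node, [])
        kind = "other"
        for t in types:
            if t in _ENTITY_KINDS:
                kind = _ENTITY_KINDS[t]
                break
        ent = PhysicalEntity(local_id=_local_id(node), display_name=self._name(node), kind=kind)
        self._entity_cache[node] = ent  # placed early: tolerates cycles

        members = self._values(node, BP3.memberPhysicalEntity)
        if members:
            ent.kind = "entity_set"
            ent.members = [self.entity(m) for m in members]
        components = self._values(node, BP3.component)
        if components:
            ent.kind = "complex"
            ent.components = [self.entity(c) for c in components]

        # reference xrefs: via entityReference (unification) plus direct ones
        for ref in self._values(node, BP3.entityReference):
            ent.reference_xrefs.extend(self._xref_curies(ref, {"UnificationXref"}))
            if self._is_drug_xref(ref):
                ent.is_drug = True
        ent.reference_xrefs.extend(self._xref_curies(node, {"UnificationXref"}))
        ent.reference_xrefs = sorted(set(ent.reference_xrefs))

        if "Drug" in types or self._is_drug_xref(node):
            ent.is_drug = True

        for loc in self._values(node, BP3.cellularLocation):
            go = self._xref_curies(loc, {"UnificationXref"})
            ent.location_term = go[0] if go else None
            ent.location_label = self._literal(loc, BP3["term"])
            break  # at most one location per entity

        for feat in self._values(node, BP3.feature):
            if "ModificationFeature" not in self._types.get(feat, []):
                continue
            desc = ""
            for mt in self._values(feat, BP3.modificationType):
                desc = self._literal(mt, BP3["term"])
                break
            for fl in self._values(feat, BP3.featureLocation):
                pos = self._literal(fl, BP3.sequencePosition)
                if pos:
                    desc = f"{desc}@{pos}" if desc else f"@{pos}"
                break
            if desc:
                ent.modifications.append(desc)
        ent.modifications.sort()

        self.collection.entities[ent.local_id] = ent
        for sub in ent.components + ent.members:
            self.collection.entities.setdefault(sub.local_id, sub)
        return ent

    # -- reactions and controls ---------------------------------------------
    def reaction(self, node: URIRef) -> Reaction:
        rid = _local_id(node)
        if rid in self.collection.reactions:
            return self.collection.reactions[rid]
        rxn = Reaction(local_id=rid, display_name=self._name(node))
        self.collection.reactions[rid] = rxn
        rxn.inputs = [self.entity(e) for e in self._values(node, BP3.left)]
        rxn.outputs = [self.entity(e) for e in self._values(node, BP3.right)]
        # template reactions carry their output on bp:product
        rxn.outputs += [self.entity(e) for e in self._values(node, BP3.product)]
        rxn.mf_xrefs = [
            c for c in self._xref_curies(node, {"RelationshipXref"}) if c.startswith("GO:")
        ]
        return rxn

    def control(self, node: URIRef) -> Optional[Control]:
        types = self._types.get(node, [])
        if "Catalysis" in types:
            ctype = "catalysis"
        else:
            raw = self._literal(node, BP3.controlType).upper()
            if raw.startswith("ACTIVATION"):
                ctype = "activation"
            elif raw.startswith("INHIBITION"):
                ctype = "inhibition"
            else:
                ctype = "activation"  # BioPAX default controlType
        controllers = self._values(node, BP3.controller)
        controlled = self._values(node, BP3.controlled)
        if not controllers or not controlled:
            self.collection.unresolved.append(f"control:{_local_id(node)}")
            return None
        target = controlled[0]
        if not (set(self._types.get(target, [])) & _REACTION_CLASSES):
            self.collection.unresolved.append(f"control-target:{_local_id(node)}")
            return None
        ctl = Control(
            controller=self.entity(controllers[0]),
            controlled=_local_id(target),
            control_type=ctype,
        )
        self.reaction(target).controls.append(ctl)
        return ctl

    # -- pathways -----------------------------------------------------------
    def pathway(self, node: URIRef) -> Pathway:
        pw = Pathway(local_id=_local_id(node), display_name=self._name(node))
        pw.bp_xrefs = [
            c for c in self._xref_curies(node, {"RelationshipXref"}) if c.startswith("GO:")
        ]
        for comp in self._values(node, BP3.pathwayComponent):
            ctypes = set(self._types.get(comp, []))
            if "Pathway" in ctypes:
                pw.subpathways.append(_local_id(comp))
            elif ctypes & _REACTION_CLASSES:
                pw.step_reactions.append(_local_id(comp))

        # pathwayOrder -> steps; nextStep links give reaction-reaction pairs
        step_rxns: dict[URIRef, list[str]] = {}
        steps = self._values(node, BP3.pathwayOrder)
        for step in steps:
            rids = []
            for proc in self._values(step, BP3.stepProcess):
                if set(self._types.get(proc, [])) & _REACTION_CLASSES:
                    rids.append(_local_id(proc))
            step_rxns[step] = rids
        for step in steps:
            for nxt in self._values(step, BP3.nextStep):
                down_rids = step_rxns.get(nxt)
                if down_rids is None:
                    down_rids = []
                    for proc in self._values(nxt, BP3.stepProcess):
                        if set(self._types.get(proc, [])) & _REACTION_CLASSES:
                            down_rids.append(_local_id(proc))
                for up in step_rxns[step]:
                    for down in down_rids:
                        pw.next_steps.append((up, down))
        return pw


def parse_biopax(document: bytes | str | io.IOBase) -> PathwayCollection:
    """Read one BioPAX Level-3 RDF/XML document into a :class:`PathwayCollection`.

    Raises :class:`BiopaxParseError` on malformed XML, naming the
    position reported by the XML parser.  Instances of unknown BioPAX
    classes are skipped with a warning and recorded in the collection's
    unresolved-reference registry.
    """
    g = rdflib.Graph()
    try:
        if isinstance(document, (bytes, str)):
            g.parse(data=document, format="xml")
        else:
            g.parse(file=document, format="xml")
    except Exception as exc:  # SAXParseException carries line/column
        line = getattr(exc, "getLineNumber", lambda: None)()
        col = getattr(exc, "getColumnNumber", lambda: None)()
        pos = f" at line {line}, column {col}" if line is not None else ""
        raise BiopaxParseError(f"malformed BioPAX RDF/XML{pos}: {exc}") from exc

    p = _Parser(g)
    coll = p.collection

    for s in sorted(p._types, key=str):
        types = set(p._types[s])
        if types & _REACTION_CLASSES:
            p.reaction(s)
        elif set(_ENTITY_KINDS) & types:
            p.entity(s)
        elif not (types & _CONTROL_CLASSES) and not (types & _KNOWN_UTILITY_CLASSES):
            log.warning("skipping instance of unknown BioPAX class: %s %s", s, types)
            coll.unresolved.append(f"unknown-class:{_local_id(s)}")
    for s in sorted(p._types, key=str):
        if set(p._types[s]) & _CONTROL_CLASSES:
            p.control(s)
    for s in sorted(p._types, key=str):
        if "Pathway" in p._types[s]:
            coll.pathways.append(p.pathway(s))
    for s in sorted(p._types, key=str):
        if "Provenance" in p._types[s]:
            name = p._name(s)
            if name:
                coll.source_version = name

    # registry of dangling step references (recorded, never silently dropped)
    known = set(coll.reactions)
    for pw in coll.pathways:
        for up, down in pw.next_steps:
            for end in (up, down):
                if end not in known:
                    coll.unresolved.append(f"dangling-step:{pw.local_id}:{end}")

    log.info(
        "parsed %d pathways, %d reactions, %d entities (%d unresolved refs)",
        len(coll.pathways), len(coll.reactions), len(coll.entities), len(coll.unresolved),
    )
    return coll


# ---------------------------------------------------------------------------
# filtering


def _disease_closure(collection: PathwayCollection, roots: list[str]) -> set[str]:
    by_id = {p.local_id: p for p in collection.pathways}
    seen: set[str] = set()
    stack = [r for r in roots if r in by_id]
    for r in roots:
        if r not in by_id:
            log.warning("disease root %s not found; filter is a no-op for it", r)
    while stack:
        pid = stack.pop()
        if pid in seen:
            continue
        seen.add(pid)
        stack.extend(by_id[pid].subpathways if pid in by_id else [])
    return seen


def _involves_drug(reaction: Reaction) -> bool:
    for part in reaction.inputs + reaction.outputs + [c.controller for c in reaction.controls]:
        if any(e.is_drug for e in part.participant_closure()):
            return True
    return False


def filter_collection(collection: PathwayCollection, config: FilterConfig) -> PathwayCollection:
    """Return a new collection without disease-branch pathways and drug reactions.

    Disease membership is the subpathway closure of the configured root
    pathway identifiers.  A reaction is drug-involving when any
    participant or controller (including nested set members and complex
    components) is flagged as a drug.  Reactions left orphaned by
    pathway removal are dropped as well; all removals are logged.
    """
    disease = _disease_closure(collection, config.disease_roots)
    drug_rxns = (
        {rid for rid, r in collection.reactions.items() if _involves_drug(r)}
        if config.drug_filter
        else set()
    )

    kept_pathways = []
    for pw in collection.pathways:
        if pw.local_id in disease:
            continue
        new = Pathway(
            local_id=pw.local_id,
            display_name=pw.display_name,
            step_reactions=[r for r in pw.step_reactions if r not in drug_rxns],
            next_steps=list(pw.next_steps),
            bp_xrefs=list(pw.bp_xrefs),
            subpathways=[s for s in pw.subpathways if s not in disease],
            is_disease=False,
        )
        kept_pathways.append(new)

    referenced = {r for pw in kept_pathways for r in pw.step_reactions}
    kept_reactions = {
        rid: rxn
        for rid, rxn in collection.reactions.items()
        if rid not in drug_rxns and (not collection.pathways or rid in referenced)
    }

    entities: dict[str, PhysicalEntity] = {}
    for rxn in kept_reactions.values():
        for part in rxn.participants():
            for e in part.participant_closure():
                entities[e.local_id] = e
    for ctl_rxn in kept_reactions.values():
        for c in ctl_rxn.controls:
            for e in c.controller.participant_closure():
                entities[e.local_id] = e

    log.info(
        "filter: removed %d disease pathways, %d drug reactions; kept %d pathways, %d reactions",
        len(disease), len(drug_rxns), len(kept_pathways), len(kept_reactions),
    )
    return PathwayCollection(
        pathways=kept_pathways,
        reactions=kept_reactions,
        entities=entities,
        source_version=collection.source_version,
        unresolved=list(collection.unresolved),
    )


# ---------------------------------------------------------------------------
# classification


def _transport_shaped(reaction: Reaction) -> bool:
    """True when an input and an output share a reference xref but differ in location."""
    for i in reaction.inputs:
        for o in reaction.outputs:
            shared = set(i.reference_xrefs) & set(o.reference_xrefs)
            if shared and i.location_term != o.location_term:
                return True
    return False


def classify_reaction(reaction: Reaction) -> ReactionCategory:
    """Assign the shape category of a reaction (total, deterministic).

    Ordered rules: catalysis present -> catalyzed (transport-flagged when
    an input and output share a reference but differ in location); no
    catalysis and an empty side -> black_box; more inputs than outputs
    with a complex output -> binding; more outputs than inputs with a
    complex input -> dissociation; equal counts with differing locations
    -> transport; anything else -> other.
    """
    has_catalysis = bool(reaction.catalysis_controls())
    if has_catalysis:
        reaction.is_transport = _transport_shaped(reaction)
        reaction.category = ReactionCategory.CATALYZED
        return reaction.category

    n_in, n_out = len(reaction.inputs), len(reaction.outputs)
    if n_in == 0 or n_out == 0:
        cat = ReactionCategory.BLACK_BOX
    elif n_in > n_out and any(e.kind == "complex" for e in reaction.outputs):
        cat = ReactionCategory.BINDING
    elif n_out > n_in and any(e.kind == "complex" for e in reaction.inputs):
        cat = ReactionCategory.DISSOCIATION
    elif n_in == n_out and {e.location_term for e in reaction.inputs} != {
        e.location_term for e in reaction.outputs
    }:
        cat = ReactionCategory.TRANSPORT
    else:
        cat = ReactionCategory.OTHER
    reaction.is_transport = cat is ReactionCategory.TRANSPORT
    reaction.category = cat
    return cat


def classify_all(collection: PathwayCollection) -> None:
    for rxn in collection.reactions.values():
        classify_reaction(rxn)
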