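"""Entity-ontology construction for pathway physical entities.

GO-CAM individuals must be typed with classes from imported
ontologies, but pathway databases use many entities that have no
standard-ontology class: complexes, interchangeable entity *sets*,
covalently modified proteoforms, and location-specific copies of the
same molecule.  This module builds a generated entity ontology with
one class per unmapped entity:

* small molecules with a ChEBI cross-reference map to the ChEBI class
  directly — no new class is minted;
* unmodified proteins get one class per UniProt accession,
  cross-referenced to the accession and rooted under the ChEBI
  'information biomacromolecule' class;
* proteoforms become subclasses of the canonical protein's class, with
  the modification descriptors recorded in the definition;
* complexes become named classes with has-part links to their
  component classes;
* entity sets become union classes (logical OR over the recursively
  flattened members) — any member of the set can act in a reaction.

Location never contributes to class identity: the cytosolic and
nuclear copies of a molecule share one class, and location is modeled
on the activity/participant instance instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import vocab
from .biopax_model import PathwayCollection, PhysicalEntity

log = logging.getLogger(__name__)


@dataclass
class OntologyClass:
    iri: str
    label: str = ""
    superclasses: list[str] = field(default_factory=list)
    union_members: Optional[list[str]] = None  # present iff the class is a set union
    component_links: list[tuple[str, str]] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    definition: str = ""


@dataclass
class EntityOntology:
    classes: dict[str, OntologyClass] = field(default_factory=dict)
    entity_to_class: dict[str, str] = field(default_factory=dict)
    provenance: str = ""
    _key_to_iri: dict[tuple, str] = field(default_factory=dict)

    def add(self, cls: OntologyClass) -> OntologyClass:
        return self.classes.setdefault(cls.iri, cls)


def _structural_roots(ontology: EntityOntology) -> None:
    ontology.add(
        OntologyClass(
            iri=vocab.INFORMATION_BIOMACROMOLECULE,
            label="information biomacromolecule",
        )
    )
    ontology.add(
        OntologyClass(
            iri=vocab.MOLECULAR_EVENT,
            label="molecular event",
            definition=(
                "A molecular-level event; superclass of both gene-product-enabled "
                "molecular functions and activities whose enabler is unspecified."
            ),
        )
    )


def _first_with_prefix(xrefs: list[str], prefix: str) -> Optional[str]:
    for x in xrefs:
        if x.startswith(prefix):
            return x
    return None


def _mint(entity: PhysicalEntity) -> str:
    # deterministic: derived from the source entity's stable identifier
    return f"REACTO:{entity.local_id}"


def _identity_key(entity: PhysicalEntity, ontology: EntityOntology) -> tuple:
    """Location-free identity of an entity, used to share classes.

    Two located copies of the same molecule, or two entities with the
    same accession and identical modification sets, share one class.
    """
    mods = tuple(sorted(entity.modifications))
    acc = _first_with_prefix(entity.reference_xrefs, "UniProt:")
    if acc:
        return ("gp", acc, mods)
    if entity.kind == "complex":
        comp = tuple(sorted(class_for_entity(c, ontology) for c in entity.components))
        return ("complex", entity.display_name, comp)
    if entity.reference_xrefs:
        return ("xref", tuple(sorted(entity.reference_xrefs)), mods)
    if entity.display_name:
        return ("name", entity.kind, entity.display_name, mods)
    return ("id", entity.local_id)


def class_for_entity(entity: PhysicalEntity, ontology: EntityOntology) -> str:
    """Return (minting if necessary) the class IRI for a physical entity."""
    cached = ontology.entity_to_class.get(entity.local_id)
    if cached:
        return cached

    if entity.kind == "entity_set":
        return union_for_set(entity, ontology)

    chebi = _first_with_prefix(entity.reference_xrefs, "CHEBI:")
    if entity.kind == "small_molecule" and chebi:
        # map to the ChEBI class itself; never duplicate an existing class
        ontology.add(OntologyClass(iri=chebi, label=entity.display_name))
        ontology.entity_to_class[entity.local_id] = chebi
        return chebi

    key = _identity_key(entity, ontology)
    iri = ontology._key_to_iri.get(key)
    if iri:
        ontology.entity_to_class[entity.local_id] = iri
        return iri

    iri = _mint(entity)
    label = entity.display_name or entity.local_id
    if not entity.display_name and not entity.reference_xrefs:
        log.warning("entity %s has no name and no xrefs; minting opaque class", entity.local_id)

    cls = OntologyClass(iri=iri, label=label)
    acc = _first_with_prefix(entity.reference_xrefs, "UniProt:")
    if entity.kind == "complex":
        for comp in entity.components:
            cls.component_links.append((vocab.HAS_PART, class_for_entity(comp, ontology)))
        cls.component_links.sort()
        cls.superclasses = [vocab.INFORMATION_BIOMACROMOLECULE]
        cls.definition = f"Complex of: {', '.join(c.display_name or c.local_id for c in entity.components)}"
    elif acc and entity.modifications:
        # proteoform: subclass of the canonical protein's class
        canonical = PhysicalEntity(
            local_id=f"{entity.local_id}-canonical",
            display_name=acc.split(":", 1)[1],
            kind="protein",
            reference_xrefs=[acc],
        )
        parent_key = ("gp", acc, ())
        parent_iri = ontology._key_to_iri.get(parent_key)
        if parent_iri is None:
            parent_iri = class_for_entity(canonical, ontology)
        cls.superclasses = [parent_iri]
        cls.definition = "Modified form: " + "; ".join(sorted(entity.modifications))
    elif acc:
        cls.xrefs = [acc]
        cls.superclasses = [vocab.INFORMATION_BIOMACROMOLECULE]
    else:
        if entity.kind in {"protein", "nucleic_acid"}:
            cls.superclasses = [vocab.INFORMATION_BIOMACROMOLECULE]
        cls.xrefs = sorted(entity.reference_xrefs)

    ontology.add(cls)
    ontology._key_to_iri[key] = iri
    ontology.entity_to_class[entity.local_id] = iri
    return iri


def _flatten_members(entity: PhysicalEntity) -> list[PhysicalEntity]:
    """Leaf members of a set, with nested sets flattened into the union."""
    leaves: list[PhysicalEntity] = []
    for m in entity.members:
        if m.kind == "entity_set":
            leaves.extend(_flatten_members(m))
        else:
            leaves.append(m)
    return leaves


def union_for_set(set_entity: PhysicalEntity, ontology: EntityOntology) -> str:
    """Class for an entity set: union (logical OR) of all leaf member classes."""
    if set_entity.kind != "entity_set" or not set_entity.members:
        raise ValueError(f"{set_entity.local_id} is not a non-empty entity set")
    cached = ontology.entity_to_class.get(set_entity.local_id)
    if cached:
        return cached
    leaves = _flatten_members(set_entity)
    member_iris = sorted({class_for_entity(m, ontology) for m in leaves})
    key = ("set", tuple(member_iris))
    iri = ontology._key_to_iri.get(key)
    if iri is None:
        iri = _mint(set_entity)
        ontology.add(
            OntologyClass(
                iri=iri,
                label=set_entity.display_name or set_entity.local_id,
                union_members=member_iris,
                definition="Union (any member can act): " + ", ".join(member_iris),
            )
        )
        ontology._key_to_iri[key] = iri
    ontology.entity_to_class[set_entity.local_id] = iri
    return iri


def build_entity_ontology(collection: PathwayCollection) -> EntityOntology:
    """Build the entity ontology covering every entity reachable from
    the retained reactions of a (filtered) collection."""
    ontology = EntityOntology(provenance=collection.source_version)
    _structural_roots(ontology)
    reachable: dict[str, PhysicalEntity] = {}
    for rid in sorted(collection.reactions):
        rxn = collection.reactions[rid]
        parts = rxn.inputs + rxn.outputs + [c.controller for c in rxn.controls]
        for part in parts:
            for e in part.participant_closure():
                reachable.setdefault(e.local_id, e)
    for eid in sorted(reachable):
        class_for_entity(reachable[eid], ontology)
    return ontology
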