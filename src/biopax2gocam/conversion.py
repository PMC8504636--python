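"""Reaction-to-activity conversion: process description to activity flow.

Every retained reaction is converted into exactly one GO-CAM activity
unit (totality is the contract).  A complete activity unit specifies
the molecular function, the enabling entity, inputs/outputs, a single
cellular location, membership in a biological process, and at least
one causal connection.  Reactions that cannot supply an attribute
still convert — the gap is recorded and reported by the audit module:

* no molecular-function cross-reference -> the generated
  ``molecular event`` class (a superclass of both gene-product-enabled
  functions and events with unspecified enablers);
* no catalysis -> no enabler (binding/dissociation and black-box
  shorthand events);
* participants in several locations -> no single activity location,
  but every participant keeps its own location annotation, so no
  information is lost; transport-shaped reactions additionally record
  start and end locations of the moved entity;
* parent pathway without a biological-process cross-reference -> the
  activity is part of the root biological-process term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import vocab
from .biopax_model import (
    PathwayCollection,
    Pathway,
    Reaction,
    ReactionCategory,
    classify_reaction,
)
from .reacto import EntityOntology, class_for_entity

log = logging.getLogger(__name__)


@dataclass
class ConversionConfig:
    """Knobs of the conversion pipeline.

    infer_transport_mf: when enabled, transport-shaped reactions with no
        molecular-function cross-reference get a generic transporter-
        activity class instead of ``molecular event``.  Off by default:
        the conservative default assigns only what the source asserts.
    eco_class: evidence class attached to every asserted edge.
    binding_term: function class used for regulator-derived binding
        activity nodes.
    """

    infer_transport_mf: bool = False
    eco_class: str = vocab.DEFAULT_ECO
    binding_term: str = vocab.BINDING


@dataclass
class CausalEdge:
    source: str  # activity_id
    target: str  # activity_id
    relation: str
    basis: str  # output_is_input | output_is_catalyst | regulation_pos | regulation_neg | step_only
    origin: str = "step"  # step | regulator


@dataclass
class ActivityUnit:
    activity_id: str
    function_class: str
    enabler: Optional[str] = None
    enabler_location: Optional[str] = None
    inputs: list[tuple[str, Optional[str]]] = field(default_factory=list)
    outputs: list[tuple[str, Optional[str]]] = field(default_factory=list)
    location: Optional[str] = None
    transport_from: Optional[str] = None
    transport_to: Optional[str] = None
    process_class: str = vocab.BP_ROOT
    causal_edges: list[CausalEdge] = field(default_factory=list)
    source_reaction: Optional[str] = None
    category: Optional[ReactionCategory] = None
    complex_enabler: bool = False  # audit flag: enabled by a complex class


@dataclass
class GoCamModelSkeleton:
    model_id: str
    title: str
    activities: list[ActivityUnit] = field(default_factory=list)
    subpathway_nodes: list[tuple[str, str]] = field(default_factory=list)
    provenance: str = ""
    source_pathway: str = ""
    n_dropped_links: int = 0
    regulated_pairs: set = field(default_factory=set)
    next_ordinal: int = 1

    def unit_for_reaction(self, reaction_id: str) -> Optional[ActivityUnit]:
        for u in self.activities:
            if u.source_reaction == reaction_id:
                return u
        return None


def core_id(local_id: str) -> str:
    """Strip a release suffix from a stable identifier (R-HSA-123.2 -> R-HSA-123)."""
    head, dot, tail = local_id.rpartition(".")
    if dot and tail.isdigit():
        return head
    return local_id


def assign_molecular_function(
    reaction: Reaction, config: ConversionConfig | None = None
) -> str:
    """Molecular-function class of a reaction's activity.

    First GO MF cross-reference wins; with none, the generated
    ``molecular event`` class is used (optionally a generic transporter
    activity for transport-shaped reactions when inference is enabled).
    """
    if reaction.mf_xrefs:
        if len(reaction.mf_xrefs) > 1:
            log.warning(
                "reaction %s has %d MF xrefs; using first (%s)",
                reaction.local_id, len(reaction.mf_xrefs), reaction.mf_xrefs[0],
            )
        return reaction.mf_xrefs[0]
    if (
        config is not None
        and config.infer_transport_mf
        and (reaction.is_transport or reaction.category is ReactionCategory.TRANSPORT)
    ):
        return vocab.TRANSPORTER_ACTIVITY
    return vocab.MOLECULAR_EVENT


def determine_enabler(reaction: Reaction, ontology: EntityOntology) -> Optional[str]:
    """Class of the enabling entity: the catalysis controller, if any.

    A controller that is an entity set enables as the set's union class
    (any member can act); a complex controller enables as the complex
    class.  Binding, dissociation and black-box events without
    catalysis have no enabler.
    """
    catalyses = reaction.catalysis_controls()
    if not catalyses:
        return None
    if len(catalyses) > 1:
        log.warning(
            "reaction %s has %d catalysis controls; using first", reaction.local_id, len(catalyses)
        )
    return class_for_entity(catalyses[0].controller, ontology)


def infer_location(reaction: Reaction) -> Optional[str]:
    """Single activity location, when all participants agree on one.

    The location of a reaction spans all participant locations; an
    activity unit may carry only a single location, so a uniform
    participant location is promoted and anything else yields none
    (participant-level locations are preserved on the unit).
    """
    locations = {p.location_term for p in reaction.participants()}
    if len(locations) == 1:
        (only,) = locations
        return only
    return None


def _transport_endpoints(reaction: Reaction) -> tuple[Optional[str], Optional[str]]:
    """Start/end locations of the transported entity (matched by shared reference)."""
    for i in reaction.inputs:
        for o in reaction.outputs:
            if (
                set(i.reference_xrefs) & set(o.reference_xrefs)
                and i.location_term != o.location_term
            ):
                return i.location_term, o.location_term
    starts = [e.location_term for e in reaction.inputs if e.location_term]
    ends = [e.location_term for e in reaction.outputs if e.location_term]
    return (starts[0] if starts else None, ends[0] if ends else None)


def assign_process(reaction: Reaction, parent: Pathway) -> str:
    """Biological process of the containing pathway; root BP when unannotated.

    Only the immediate parent pathway is consulted — a reaction inherits
    the annotation gap when its own pathway lacks a process term.
    """
    if parent.bp_xrefs:
        return parent.bp_xrefs[0]
    return vocab.BP_ROOT


def reaction_to_activity(
    reaction: Reaction,
    parent: Pathway,
    ontology: EntityOntology,
    config: ConversionConfig | None = None,
) -> ActivityUnit:
    """Convert one reaction into one activity unit (total: never fails)."""
    if reaction.category is None:
        classify_reaction(reaction)
    unit = ActivityUnit(
        activity_id="",  # minted when the unit joins a model
        function_class=assign_molecular_function(reaction, config),
        enabler=determine_enabler(reaction, ontology),
        location=infer_location(reaction),
        process_class=assign_process(reaction, parent),
        source_reaction=reaction.local_id,
        category=reaction.category,
    )
    unit.inputs = [
        (class_for_entity(e, ontology), e.location_term) for e in reaction.inputs
    ]
    unit.outputs = [
        (class_for_entity(e, ontology), e.location_term) for e in reaction.outputs
    ]
    if reaction.is_transport or reaction.category is ReactionCategory.TRANSPORT:
        unit.transport_from, unit.transport_to = _transport_endpoints(reaction)
    catalyses = reaction.catalysis_controls()
    if catalyses:
        # controller-level location is preserved even when the unit has
        # no single location, so no location information is lost
        unit.enabler_location = catalyses[0].controller.location_term
        if catalyses[0].controller.kind == "complex":
            unit.complex_enabler = True
    return unit


def convert_pathway(
    pathway: Pathway,
    collection: PathwayCollection,
    ontology: EntityOntology,
    config: ConversionConfig | None = None,
) -> GoCamModelSkeleton:
    """Build the model skeleton for one pathway.

    One activity unit per retained step reaction; one process node per
    subpathway; a pathway containing only subpathways is represented by
    its process nodes alone.  Model identifiers follow the
    ``http://model.geneontology.org/<pathway-core-id>`` convention.
    """
    config = config or ConversionConfig()
    model = GoCamModelSkeleton(
        model_id=vocab.MODEL_BASE + core_id(pathway.local_id),
        title=pathway.display_name,
        provenance=collection.source_version,
        source_pathway=pathway.local_id,
    )
    for rid in pathway.step_reactions:
        rxn = collection.reactions.get(rid)
        if rxn is None:
            continue
        unit = reaction_to_activity(rxn, pathway, ontology, config)
        unit.activity_id = f"{model.model_id}/{model.next_ordinal:06d}"
        model.next_ordinal += 1
        model.activities.append(unit)
    for sub_id in pathway.subpathways:
        sub = collection.pathway_by_id(sub_id)
        process = sub.bp_xrefs[0] if (sub and sub.bp_xrefs) else vocab.BP_ROOT
        model.subpathway_nodes.append((sub_id, process))
    if not model.activities and not model.subpathway_nodes:
        log.warning("pathway %s has zero retained steps; empty model", pathway.local_id)
    return model
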