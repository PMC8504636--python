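"""Causal-relation inference between activity units.

Pathway step links (the source format's next-step relation) record
that one reaction follows another; the conversion gives each such link
a meaning, choosing one of four causal relations:

* an output of the upstream activity is a noncatalytic *activator* of
  the downstream reaction -> directly positively regulates (RO:0002629)
* an output is a noncatalytic *inhibitor* -> directly negatively
  regulates (RO:0002630)
* an output is an input or the catalyst of the downstream reaction ->
  directly provides input for (RO:0002413)
* otherwise -> causally upstream of (RO:0002411)

Regulation takes precedence over provides-input when both bases hold
(the more specific assertion wins).  Entities are matched by class
after location stripping, and a set's union class matches whenever any
member matches.  Noncatalytic entity regulators that are not already
captured as step edges become explicit binding activity nodes with a
regulation edge to the controlled activity.
"""

from __future__ import annotations

import logging
from typing import Optional

from . import vocab
from .biopax_model import Control, PathwayCollection, Pathway, Reaction
from .conversion import (
    ActivityUnit,
    CausalEdge,
    ConversionConfig,
    GoCamModelSkeleton,
)
from .reacto import EntityOntology, class_for_entity

log = logging.getLogger(__name__)


def _leaf_classes(iri: str, ontology: EntityOntology) -> frozenset[str]:
    cls = ontology.classes.get(iri)
    if cls is not None and cls.union_members:
        out: set[str] = set()
        for m in cls.union_members:
            out |= _leaf_classes(m, ontology)
        return frozenset(out)
    return frozenset({iri})


def classes_match(a: str, b: str, ontology: EntityOntology) -> bool:
    """Class identity with union (set) expansion: any shared leaf matches."""
    if a == b:
        return True
    return bool(_leaf_classes(a, ontology) & _leaf_classes(b, ontology))


def _noncatalytic_controller_classes(
    reaction: Reaction, ontology: EntityOntology, control_type: str
) -> list[str]:
    return [
        class_for_entity(c.controller, ontology)
        for c in reaction.controls
        if c.control_type == control_type
    ]


def infer_causal_relation(
    upstream: ActivityUnit,
    downstream: ActivityUnit,
    collection: PathwayCollection,
    ontology: EntityOntology,
) -> CausalEdge:
    """Choose the causal relation for one recorded step link.

    Decision order: positive regulation, negative regulation,
    provides-input (output is an input or the catalyst downstream),
    default causally-upstream-of.
    """
    down_rxn = collection.reactions[downstream.source_reaction]
    out_classes = [c for c, _loc in upstream.outputs]

    for basis, ctype, relation in (
        ("regulation_pos", "activation", vocab.DIRECTLY_POSITIVELY_REGULATES),
        ("regulation_neg", "inhibition", vocab.DIRECTLY_NEGATIVELY_REGULATES),
    ):
        for ctl_cls in _noncatalytic_controller_classes(down_rxn, ontology, ctype):
            if any(classes_match(o, ctl_cls, ontology) for o in out_classes):
                return CausalEdge(
                    source=upstream.activity_id,
                    target=downstream.activity_id,
                    relation=relation,
                    basis=basis,
                )

    down_inputs = [c for c, _loc in downstream.inputs]
    if any(
        classes_match(o, i, ontology) for o in out_classes for i in down_inputs
    ):
        basis = "output_is_input"
    elif downstream.enabler is not None and any(
        classes_match(o, downstream.enabler, ontology) for o in out_classes
    ):
        basis = "output_is_catalyst"
    else:
        return CausalEdge(
            source=upstream.activity_id,
            target=downstream.activity_id,
            relation=vocab.CAUSALLY_UPSTREAM_OF,
            basis="step_only",
        )
    return CausalEdge(
        source=upstream.activity_id,
        target=downstream.activity_id,
        relation=vocab.PROVIDES_INPUT_FOR,
        basis=basis,
    )


def link_pathway_steps(
    model: GoCamModelSkeleton,
    pathway: Pathway,
    collection: PathwayCollection,
    ontology: EntityOntology,
) -> GoCamModelSkeleton:
    """Convert every resolvable step link of a pathway into one causal edge.

    Links whose ends were filtered out (disease pathways, drug
    reactions) or fall outside this model are dropped and counted —
    dropped links are reported, never silently lost.
    """
    for up_id, down_id in pathway.next_steps:
        up = model.unit_for_reaction(up_id)
        down = model.unit_for_reaction(down_id)
        if up is None or down is None or down.source_reaction not in collection.reactions:
            model.n_dropped_links += 1
            log.info("dropped step link %s -> %s (end filtered out)", up_id, down_id)
            continue
        edge = infer_causal_relation(up, down, collection, ontology)
        up.causal_edges.append(edge)
        if edge.basis.startswith("regulation"):
            # remember which (reaction, controller-output) regulations are
            # already expressed as step edges, so the binding-node pass
            # does not duplicate them
            for ctype in ("activation", "inhibition"):
                down_rxn = collection.reactions[down.source_reaction]
                for ctl_cls in _noncatalytic_controller_classes(down_rxn, ontology, ctype):
                    if any(
                        classes_match(o, ctl_cls, ontology) for o, _l in up.outputs
                    ):
                        model.regulated_pairs.add((down.source_reaction, ctl_cls))
    return model


def regulator_to_binding(
    model: GoCamModelSkeleton,
    control: Control,
    ontology: EntityOntology,
    config: Optional[ConversionConfig] = None,
) -> GoCamModelSkeleton:
    """Convert one noncatalytic entity regulator into a binding activity node.

    The new node is a binding activity enabled by the controller's
    class, with a positive- or negative-regulation edge to the
    controlled reaction's activity.  A no-op when the controlled
    reaction is not in the model (filtered out) or the regulation is
    already expressed as a step edge.
    """
    config = config or ConversionConfig()
    if control.control_type not in {"activation", "inhibition"}:
        return model
    target = model.unit_for_reaction(control.controlled)
    if target is None:
        log.info("regulator on %s skipped: reaction not in model", control.controlled)
        return model
    ctl_cls = class_for_entity(control.controller, ontology)
    if (control.controlled, ctl_cls) in model.regulated_pairs:
        return model
    relation = (
        vocab.DIRECTLY_POSITIVELY_REGULATES
        if control.control_type == "activation"
        else vocab.DIRECTLY_NEGATIVELY_REGULATES
    )
    node = ActivityUnit(
        activity_id=f"{model.model_id}/{model.next_ordinal:06d}",
        function_class=config.binding_term,
        enabler=ctl_cls,
        location=control.controller.location_term,
        process_class=target.process_class,
        source_reaction=None,
    )
    model.next_ordinal += 1
    node.causal_edges.append(
        CausalEdge(
            source=node.activity_id,
            target=target.activity_id,
            relation=relation,
            basis="regulation_pos" if control.control_type == "activation" else "regulation_neg",
            origin="regulator",
        )
    )
    model.activities.append(node)
    model.regulated_pairs.add((control.controlled, ctl_cls))
    return model


def attach_regulators(
    model: GoCamModelSkeleton,
    collection: PathwayCollection,
    ontology: EntityOntology,
    config: Optional[ConversionConfig] = None,
) -> GoCamModelSkeleton:
    """Run the binding-node conversion for every noncatalytic control
    on the model's retained reactions (deterministic order)."""
    for unit in list(model.activities):
        if unit.source_reaction is None:
            continue
        rxn = collection.reactions.get(unit.source_reaction)
        if rxn is None:
            continue
        for control in rxn.controls:
            regulator_to_binding(model, control, ontology, config)
    return model
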