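"""Reaction-to-activity conversion and model-skeleton assembly."""

import copy

import biopax2gocam as bg
from biopax2gocam import vocab
from biopax2gocam.biopax_model import Pathway, PathwayCollection, classify_reaction
from biopax2gocam.conversion import (
    ConversionConfig,
    assign_molecular_function,
    assign_process,
    convert_pathway,
    core_id,
    determine_enabler,
    infer_location,
    reaction_to_activity,
)
from biopax2gocam.reacto import build_entity_ontology


class TestMolecularFunction:
    def test_crym_mf_from_xref(self, crym_collection):
        rxn = crym_collection.reactions["R-HSA-5693347"]
        assert assign_molecular_function(rxn) == "GO:0047127"

    def test_black_box_falls_to_molecular_event(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["black_box"])
        rxn = coll.reactions["R-TST-BBX01"]
        classify_reaction(rxn)
        assert assign_molecular_function(rxn) == vocab.MOLECULAR_EVENT

    def test_unannotated_non_black_box_falls_through(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["multi_location_transport"])
        rxn = coll.reactions["R-TST-TRN01"]
        classify_reaction(rxn)
        assert assign_molecular_function(rxn) == vocab.MOLECULAR_EVENT

    def test_transport_inference_flag(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["multi_location_transport"])
        rxn = coll.reactions["R-TST-TRN01"]
        classify_reaction(rxn)
        cfg = ConversionConfig(infer_transport_mf=True)
        assert assign_molecular_function(rxn, cfg) == vocab.TRANSPORTER_ACTIVITY


class TestEnabler:
    def test_crym_enabled_by_protein_class(self, crym_collection):
        onto = build_entity_ontology(crym_collection)
        rxn = crym_collection.reactions["R-HSA-5693347"]
        assert determine_enabler(rxn, onto) == onto.entity_to_class["protein_crym"]

    def test_binding_without_catalysis_has_no_enabler(self, corpus):
        document, ledger = corpus
        coll = bg.parse_biopax(document)
        onto = build_entity_ontology(coll)
        rid = next(r for r, m in ledger["reactions"].items() if m["category"] == "binding")
        assert determine_enabler(coll.reactions[rid], onto) is None

    def test_set_catalyst_enables_as_union_class(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["set_catalyst"])
        onto = build_entity_ontology(coll)
        rxn = coll.reactions["R-TST-SET01"]
        iri = determine_enabler(rxn, onto)
        cls = onto.classes[iri]
        (ctl,) = rxn.catalysis_controls()
        expected = {onto.entity_to_class[m.local_id] for m in ctl.controller.members}
        assert set(cls.union_members) == expected


class TestLocation:
    def test_uniform_participants_promote_location(self, crym_collection):
        rxn = crym_collection.reactions["R-HSA-5693347"]
        assert infer_location(rxn) == "GO:0005782"

    def test_spanning_locations_preserved_per_participant(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["multi_location_transport"])
        rxn = coll.reactions["R-TST-TRN01"]
        assert infer_location(rxn) is None
        assert [e.location_term for e in rxn.inputs] == ["GO:0005576"]
        assert [e.location_term for e in rxn.outputs] == ["GO:0005829"]

    def test_no_locations_at_all(self):
        from biopax2gocam.biopax_model import PhysicalEntity, Reaction

        rxn = Reaction(
            local_id="r",
            inputs=[PhysicalEntity(local_id="a")],
            outputs=[PhysicalEntity(local_id="b")],
        )
        assert infer_location(rxn) is None

    def test_transport_endpoints_extracted(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["multi_location_transport"])
        onto = build_entity_ontology(coll)
        rxn = coll.reactions["R-TST-TRN01"]
        classify_reaction(rxn)
        unit = reaction_to_activity(rxn, coll.pathways[0], onto)
        assert unit.transport_from == "GO:0005576"
        assert unit.transport_to == "GO:0005829"


class TestProcess:
    def test_parent_bp_xref(self, crym_collection):
        pw = crym_collection.pathways[0]
        rxn = crym_collection.reactions["R-HSA-5693347"]
        assert assign_process(rxn, pw) == "GO:0006554"

    def test_unannotated_parent_gives_root(self, crym_collection):
        rxn = crym_collection.reactions["R-HSA-5693347"]
        bare = Pathway(local_id="p", display_name="bare")
        assert assign_process(rxn, bare) == vocab.BP_ROOT

    def test_no_upward_search_past_immediate_parent(self, crym_collection):
        """A subpathway lacking a process term does not inherit the
        grandparent's annotation — the curation gap is reported as-is."""
        rxn = crym_collection.reactions["R-HSA-5693347"]
        child = Pathway(local_id="child", bp_xrefs=[])
        grandparent = Pathway(local_id="gp", bp_xrefs=["GO:0006554"],
                              subpathways=["child"])
        assert grandparent.bp_xrefs  # annotation exists one level up
        assert assign_process(rxn, child) == vocab.BP_ROOT


class TestActivityUnits:
    def test_crym_unit_is_fully_specified(self, crym_result):
        (model,) = crym_result.models
        unit = model.unit_for_reaction("R-HSA-5693347")
        assert unit.function_class == "GO:0047127"
        assert unit.enabler == crym_result.ontology.entity_to_class["protein_crym"]
        assert len(unit.inputs) == 3 and len(unit.outputs) == 2
        assert unit.location == "GO:0005782"
        assert unit.process_class == "GO:0006554"

    def test_black_box_unit_shape(self, edge_suite):
        result = bg.convert_document(edge_suite["black_box"])
        (model,) = result.models
        (unit,) = model.activities
        assert unit.function_class == vocab.MOLECULAR_EVENT
        assert unit.enabler is None
        assert unit.inputs == []

    def test_totality_one_unit_per_retained_reaction(self, corpus_result):
        units = [
            u for m in corpus_result.models for u in m.activities if u.source_reaction
        ]
        assert len(units) == len(corpus_result.collection.reactions)
        assert len({u.source_reaction for u in units}) == len(units)

    def test_catalysis_implies_mf_and_enabler(self, corpus_result):
        from biopax2gocam.biopax_model import ReactionCategory

        for m in corpus_result.models:
            for u in m.activities:
                if u.source_reaction is None:
                    continue
                if u.category in (ReactionCategory.CATALYZED, ReactionCategory.TRANSPORT):
                    assert u.function_class != vocab.MOLECULAR_EVENT
                    assert u.enabler is not None

    def test_location_multiset_is_conserved(self, corpus_result):
        """Participant locations before conversion equal the locations
        recoverable from the unit (per-participant + enabler)."""
        for m in corpus_result.models:
            for u in m.activities:
                if u.source_reaction is None:
                    continue
                rxn = corpus_result.collection.reactions[u.source_reaction]
                before = sorted(p.location_term or "-" for p in rxn.participants())
                after = [loc or "-" for _cls, loc in u.inputs + u.outputs]
                if u.enabler is not None:
                    after.append(u.enabler_location or "-")
                assert before == sorted(after)


class TestModelSkeletons:
    def test_crym_model_two_linked_units(self, crym_result):
        (model,) = crym_result.models
        assert model.model_id == "http://model.geneontology.org/R-HSA-71064"
        assert len(model.activities) == 2

    def test_subpathway_only_pathway_single_node(self):
        sub = Pathway(local_id="R-TST-SUB", bp_xrefs=["GO:0006954"])
        parent = Pathway(local_id="R-TST-PARENT", display_name="container",
                         subpathways=["R-TST-SUB"])
        coll = PathwayCollection(pathways=[parent, sub])
        onto = build_entity_ontology(coll)
        model = convert_pathway(parent, coll, onto)
        assert model.activities == []
        assert model.subpathway_nodes == [("R-TST-SUB", "GO:0006954")]

    def test_core_id_strips_release_suffix(self):
        assert core_id("R-HSA-71064.2") == "R-HSA-71064"
        assert core_id("R-HSA-71064") == "R-HSA-71064"

    def test_repeat_conversion_identical(self, crym_bytes):
        a = bg.convert_document(crym_bytes)
        b = bg.convert_document(crym_bytes)
        assert a.models == b.models
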