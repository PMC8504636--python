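"""Causal-relation inference and regulator-to-binding-node conversion."""

from collections import Counter

import biopax2gocam as bg
from biopax2gocam import vocab
from biopax2gocam.biopax_model import (
    Control,
    Pathway,
    PathwayCollection,
    PhysicalEntity,
    Reaction,
    classify_all,
)
from biopax2gocam.causal import (
    attach_regulators,
    infer_causal_relation,
    link_pathway_steps,
)
from biopax2gocam.conversion import convert_pathway
from biopax2gocam.reacto import build_entity_ontology


def _two_step_collection(*, shared_output_is="input", regulation=None):
    """Hand-built two-reaction chain with a controllable overlap basis."""
    x = PhysicalEntity(local_id="ent_x", display_name="X", kind="protein",
                       reference_xrefs=["UniProt:P10001"])
    a = PhysicalEntity(local_id="ent_a", display_name="A", kind="protein",
                       reference_xrefs=["UniProt:P10002"])
    b = PhysicalEntity(local_id="ent_b", display_name="B", kind="protein",
                       reference_xrefs=["UniProt:P10003"])
    enz = PhysicalEntity(local_id="ent_e", display_name="E", kind="protein",
                         reference_xrefs=["UniProt:P10004"])
    r1 = Reaction(local_id="r1", inputs=[a], outputs=[x])
    r2_inputs = [x] if shared_output_is == "input" else [b]
    r2 = Reaction(local_id="r2", inputs=r2_inputs, outputs=[b])
    if shared_output_is == "catalyst":
        r2.controls.append(Control(controller=x, controlled="r2",
                                   control_type="catalysis"))
    else:
        r2.controls.append(Control(controller=enz, controlled="r2",
                                   control_type="catalysis"))
    if regulation:
        r2.controls.append(Control(controller=x, controlled="r2",
                                   control_type=regulation))
    pw = Pathway(local_id="pw", step_reactions=["r1", "r2"],
                 next_steps=[("r1", "r2")])
    coll = PathwayCollection(pathways=[pw], reactions={"r1": r1, "r2": r2})
    classify_all(coll)
    return coll


def _convert(coll):
    onto = build_entity_ontology(coll)
    model = convert_pathway(coll.pathways[0], coll, onto)
    link_pathway_steps(model, coll.pathways[0], coll, onto)
    return model, onto


class TestRelationChoice:
    def test_crym_pair_provides_input_for(self, crym_result):
        (model,) = crym_result.models
        up = model.unit_for_reaction("R-HSA-5693347")
        (edge,) = up.causal_edges
        assert edge.relation == vocab.PROVIDES_INPUT_FOR
        assert edge.basis == "output_is_input"

    def test_output_as_downstream_catalyst(self):
        model, _ = _convert(_two_step_collection(shared_output_is="catalyst"))
        (edge,) = model.unit_for_reaction("r1").causal_edges
        assert edge.relation == vocab.PROVIDES_INPUT_FOR
        assert edge.basis == "output_is_catalyst"

    def test_zero_overlap_defaults_to_causally_upstream(self):
        model, _ = _convert(_two_step_collection(shared_output_is="none"))
        (edge,) = model.unit_for_reaction("r1").causal_edges
        assert edge.relation == vocab.CAUSALLY_UPSTREAM_OF

    def test_planted_activator_gives_positive_regulation(self):
        coll = _two_step_collection(shared_output_is="none", regulation="activation")
        model, _ = _convert(coll)
        (edge,) = model.unit_for_reaction("r1").causal_edges
        assert edge.relation == vocab.DIRECTLY_POSITIVELY_REGULATES

    def test_regulation_takes_precedence_over_provides_input(self):
        """When the upstream output is both an input and an activator of
        the downstream reaction, the more specific regulation wins."""
        coll = _two_step_collection(shared_output_is="input", regulation="activation")
        model, _ = _convert(coll)
        (edge,) = model.unit_for_reaction("r1").causal_edges
        assert edge.relation == vocab.DIRECTLY_POSITIVELY_REGULATES

    def test_edge_direction_follows_step_link(self):
        model, _ = _convert(_two_step_collection())
        (edge,) = model.unit_for_reaction("r1").causal_edges
        assert edge.source == model.unit_for_reaction("r1").activity_id
        assert edge.target == model.unit_for_reaction("r2").activity_id

    def test_set_union_matches_any_member(self):
        """An upstream output matches a downstream set input whenever it
        matches any member of the set."""
        x = PhysicalEntity(local_id="ent_x", kind="protein",
                           reference_xrefs=["UniProt:P10001"])
        y = PhysicalEntity(local_id="ent_y", kind="protein",
                           reference_xrefs=["UniProt:P10005"])
        the_set = PhysicalEntity(local_id="set_xy", kind="entity_set",
                                 members=[x, y])
        a = PhysicalEntity(local_id="ent_a", kind="protein",
                           reference_xrefs=["UniProt:P10002"])
        b = PhysicalEntity(local_id="ent_b", kind="protein",
                           reference_xrefs=["UniProt:P10003"])
        r1 = Reaction(local_id="r1", inputs=[a], outputs=[x])
        r2 = Reaction(local_id="r2", inputs=[the_set], outputs=[b])
        pw = Pathway(local_id="pw", step_reactions=["r1", "r2"],
                     next_steps=[("r1", "r2")])
        coll = PathwayCollection(pathways=[pw], reactions={"r1": r1, "r2": r2})
        classify_all(coll)
        model, _ = _convert(coll)
        (edge,) = model.unit_for_reaction("r1").causal_edges
        assert edge.relation == vocab.PROVIDES_INPUT_FOR


class TestStepLinking:
    def test_pathway_without_steps_has_no_edges(self, edge_suite):
        result = bg.convert_document(edge_suite["black_box"])
        (model,) = result.models
        assert all(not u.causal_edges for u in model.activities)

    def test_relation_counts_match_planted_bases(self, corpus, corpus_result):
        _, ledger = corpus
        retained = set(ledger["expected"]["retained_reactions"])
        # adjacency oracle: recount planted bases over surviving pairs
        oracle = Counter(
            p["relation"] for p in ledger["chain_pairs"]
            if p["up"] in retained and p["down"] in retained
        )
        observed = Counter(
            e.relation
            for m in corpus_result.models
            for u in m.activities
            for e in u.causal_edges
            if e.origin == "step"
        )
        assert observed == oracle

    def test_partition_identity(self, corpus, corpus_result):
        """(edges of the 4 types) + dropped links = step links of the
        retained pathways; every edge carries exactly one relation."""
        _, ledger = corpus
        summary = corpus_result.audit()
        assert summary.n_step_links == ledger["expected"]["n_step_links_retained"]
        assert summary.n_dropped_links == ledger["expected"]["n_dropped_links"]
        for m in corpus_result.models:
            for u in m.activities:
                for e in u.causal_edges:
                    assert e.relation in vocab.CAUSAL_RELATIONS

    def test_dangling_link_dropped_and_counted(self, edge_suite):
        result = bg.convert_document(
            edge_suite["dangling_step_link"], filter_config=bg.FilterConfig()
        )
        (model,) = result.models
        assert model.n_dropped_links == 1
        assert all(not u.causal_edges for u in model.activities)


class TestRegulatorNodes:
    def test_inhibitor_becomes_binding_node(self, edge_suite):
        result = bg.convert_document(edge_suite["noncatalytic_inhibitor"])
        (model,) = result.models
        binding_nodes = [u for u in model.activities if u.source_reaction is None]
        assert len(binding_nodes) == 1
        (node,) = binding_nodes
        assert node.function_class == vocab.BINDING
        assert node.enabler is not None
        (edge,) = node.causal_edges
        assert edge.relation == vocab.DIRECTLY_NEGATIVELY_REGULATES
        target = model.unit_for_reaction("R-TST-INH01")
        assert edge.target == target.activity_id

    def test_model_without_regulators_unchanged(self, crym_bytes):
        result = bg.convert_document(crym_bytes)
        (model,) = result.models
        assert all(u.source_reaction is not None for u in model.activities)

    def test_planted_regulator_count(self, corpus, corpus_result):
        _, ledger = corpus
        n_nodes = sum(
            1 for m in corpus_result.models for u in m.activities
            if u.source_reaction is None
        )
        assert n_nodes == ledger["expected"]["n_regulator_nodes"]

    def test_step_expressed_regulation_not_duplicated(self):
        """A regulation already captured as a step edge does not get a
        second, redundant binding node."""
        coll = _two_step_collection(shared_output_is="none", regulation="activation")
        onto = build_entity_ontology(coll)
        model = convert_pathway(coll.pathways[0], coll, onto)
        link_pathway_steps(model, coll.pathways[0], coll, onto)
        attach_regulators(model, coll, onto)
        assert sum(1 for u in model.activities if u.source_reaction is None) == 0
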