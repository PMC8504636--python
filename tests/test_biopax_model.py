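"""BioPAX parsing, corpus filtering and reaction classification."""

import itertools

import pytest

import biopax2gocam as bg
from biopax2gocam.biopax_model import (
    Control,
    PhysicalEntity,
    Reaction,
    ReactionCategory,
    classify_reaction,
)
from biopax2gocam.fixtures import FixtureSpec, make_random_pathway_corpus

EMPTY_DOC = b"""<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
 xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"
 xml:base="http://biopax.test/empty">
<bp:Provenance rdf:about="#provenance">
  <bp:displayName rdf:datatype="http://www.w3.org/2001/XMLSchema#string">v-test</bp:displayName>
</bp:Provenance>
</rdf:RDF>
"""


class TestParsing:
    def test_crym_reaction_participants(self, crym_collection):
        """The worked-example reaction has 3 inputs, 2 outputs, catalysis
        by CRYM, a molecular-function xref and a peroxisomal location."""
        rxn = crym_collection.reactions["R-HSA-5693347"]
        assert sorted(e.display_name for e in rxn.inputs) == ["NADPH", "P2C", "hydron"]
        assert sorted(e.display_name for e in rxn.outputs) == ["NADP+", "PPCA"]
        assert rxn.mf_xrefs == ["GO:0047127"]
        (cat,) = rxn.catalysis_controls()
        assert cat.controller.display_name == "CRYM"
        assert cat.controller.reference_xrefs == ["UniProt:Q14894"]
        assert {e.location_term for e in rxn.participants()} == {"GO:0005782"}

    def test_crym_pathway_links(self, crym_collection):
        (pw,) = crym_collection.pathways
        assert pw.local_id == "R-HSA-71064"
        assert pw.bp_xrefs == ["GO:0006554"]
        assert pw.next_steps == [("R-HSA-5693347", "R-TST-000002")]

    def test_empty_document(self):
        coll = bg.parse_biopax(EMPTY_DOC)
        assert coll.pathways == [] and coll.reactions == {} and coll.entities == {}
        assert coll.source_version == "v-test"

    def test_counts_match_generator_ledger(self):
        document, ledger = make_random_pathway_corpus(FixtureSpec(seed=3))
        coll = bg.parse_biopax(document)
        assert len(coll.reactions) == ledger["n_reactions"]
        assert len(coll.entities) == ledger["n_entities"]

    def test_malformed_xml_names_position(self):
        with pytest.raises(bg.BiopaxParseError, match="line"):
            bg.parse_biopax(b"<rdf:RDF <<< not xml")

    def test_parse_is_deterministic(self, crym_bytes):
        a = bg.parse_biopax(crym_bytes)
        b = bg.parse_biopax(crym_bytes)
        assert a == b

    def test_set_and_complex_membership(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["set_catalyst"])
        (ctl,) = coll.reactions["R-TST-SET01"].catalysis_controls()
        assert ctl.controller.kind == "entity_set"
        assert len(ctl.controller.members) == 3
        coll = bg.parse_biopax(edge_suite["complex_enabler"])
        (ctl,) = coll.reactions["R-TST-CPX01"].catalysis_controls()
        assert ctl.controller.kind == "complex"
        assert len(ctl.controller.components) == 2

    def test_proteoform_modifications(self, edge_suite):
        coll = bg.parse_biopax(edge_suite["proteoform"])
        (form,) = coll.reactions["R-TST-PFM01"].inputs
        assert form.modifications == ["S-palmitoyl-L-cysteine@186"]


class TestFiltering:
    def test_disease_branch_removed(self, corpus):
        document, ledger = corpus
        coll = bg.parse_biopax(document)
        filtered = bg.filter_collection(
            coll, bg.FilterConfig(disease_roots=["R-TST-DISEASE"])
        )
        kept = {p.local_id for p in filtered.pathways}
        for pid, meta in ledger["pathways"].items():
            assert (pid in kept) == (not meta["disease"])
        assert "R-TST-DISEASE" not in kept

    def test_drug_reactions_removed_pathway_retained(self, corpus):
        document, ledger = corpus
        coll = bg.parse_biopax(document)
        filtered = bg.filter_collection(
            coll, bg.FilterConfig(disease_roots=["R-TST-DISEASE"])
        )
        drug_rids = {r for r, m in ledger["reactions"].items() if m["drug"]}
        assert drug_rids, "fixture must plant drug reactions"
        assert not drug_rids & set(filtered.reactions)
        # pathways containing those reactions survive
        for rid in drug_rids:
            pid = ledger["reactions"][rid]["pathway"]
            assert any(p.local_id == pid for p in filtered.pathways)

    def test_retained_set_equals_planted_flags(self, corpus):
        document, ledger = corpus
        filtered = bg.filter_collection(
            bg.parse_biopax(document), bg.FilterConfig(disease_roots=["R-TST-DISEASE"])
        )
        expected = {
            rid
            for rid, m in ledger["reactions"].items()
            if not m["drug"] and not m["disease"]
        }
        assert set(filtered.reactions) == expected

    def test_missing_disease_root_is_noop(self, crym_collection):
        filtered = bg.filter_collection(
            crym_collection, bg.FilterConfig(disease_roots=["R-NOPE-1"])
        )
        assert len(filtered.pathways) == len(crym_collection.pathways)


def _oracle_category(n_in, n_out, catalysis, complex_in, complex_out, locs_differ):
    """Independently coded truth table for reaction classification."""
    if catalysis:
        return "catalyzed"
    if n_in == 0 or n_out == 0:
        return "black_box"
    if n_in > n_out and complex_out:
        return "binding"
    if n_out > n_in and complex_in:
        return "dissociation"
    if n_in == n_out and locs_differ:
        return "transport"
    return "other"


def _build_reaction(n_in, n_out, catalysis, complex_in, complex_out, locs_differ):
    def entity(i, side, kind="small_molecule", loc="GO:0005829"):
        e = PhysicalEntity(local_id=f"e{side}{i}", kind=kind, location_term=loc)
        if kind == "complex":
            e.components = [PhysicalEntity(local_id=f"c{side}{i}", kind="protein")]
        return e

    out_loc = "GO:0005576" if locs_differ else "GO:0005829"
    inputs = [entity(i, "i") for i in range(n_in)]
    outputs = [entity(i, "o", loc=out_loc) for i in range(n_out)]
    if complex_in and inputs:
        inputs[0] = entity(0, "i", kind="complex")
    if complex_out and outputs:
        outputs[0] = entity(0, "o", kind="complex", loc=out_loc)
    rxn = Reaction(local_id="r", inputs=inputs, outputs=outputs)
    if catalysis:
        rxn.controls.append(
            Control(
                controller=PhysicalEntity(local_id="enz", kind="protein"),
                controlled="r",
                control_type="catalysis",
            )
        )
    return rxn


class TestClassification:
    @pytest.mark.parametrize(
        "n_in,n_out,catalysis,complex_in,complex_out,locs_differ",
        list(
            itertools.product(
                range(4), range(4), [False, True], [False, True], [False, True],
                [False, True],
            )
        ),
    )
    def test_matches_truth_table_oracle(
        self, n_in, n_out, catalysis, complex_in, complex_out, locs_differ
    ):
        rxn = _build_reaction(n_in, n_out, catalysis, complex_in, complex_out, locs_differ)
        expected = _oracle_category(
            n_in, n_out, catalysis, complex_in and n_in > 0, complex_out and n_out > 0,
            locs_differ,
        )
        assert classify_reaction(rxn).value == expected

    def test_crym_reaction_is_catalyzed(self, crym_collection):
        rxn = crym_collection.reactions["R-HSA-5693347"]
        assert classify_reaction(rxn) is ReactionCategory.CATALYZED

    def test_census_equals_planted_categories(self, corpus):
        document, ledger = corpus
        coll = bg.parse_biopax(document)
        for rid, meta in ledger["reactions"].items():
            assert classify_reaction(coll.reactions[rid]).value == meta["category"]
            assert coll.reactions[rid].is_transport == meta["transport_flag"]

    def test_classification_is_deterministic(self, crym_collection):
        rxn = crym_collection.reactions["R-TST-000002"]
        assert classify_reaction(rxn) == classify_reaction(rxn)

    def test_catalyzed_transport_keeps_catalyzed_category(self, corpus):
        """Transporter-catalyzed translocations stay catalyzed, with the
        transport flag set so start/end locations are still extracted."""
        document, ledger = corpus
        coll = bg.parse_biopax(document)
        flagged = [r for r, m in ledger["reactions"].items() if m["transport_flag"]]
        assert flagged
        for rid in flagged:
            assert classify_reaction(coll.reactions[rid]) is ReactionCategory.CATALYZED
            assert coll.reactions[rid].is_transport
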