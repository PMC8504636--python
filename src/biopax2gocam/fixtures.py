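"""Synthetic BioPAX Level-3 documents for testing every pipeline stage.

Three generators are provided:

* :func:`make_crym_fixture` — the worked example: the lysine-catabolism
  pathway fragment in which the CRYM enzyme reduces P2C to PPCA
  (3 inputs, 2 outputs, catalysis, molecular-function and process
  cross-references, all participants in the peroxisomal matrix),
  followed by a downstream reaction consuming PPCA.
* :func:`make_random_pathway_corpus` — a seeded corpus with planted
  reaction categories, entity sets/complexes/proteoforms, noncatalytic
  controls, annotation gaps and disease/drug flags, together with a
  machine-readable ledger of every planted truth.  The ledger is the
  oracle that conversion output is compared against in tests.
* :func:`make_edge_case_suite` — one minimal document per tricky
  construct (set catalyst, nested set, complex enabler, proteoform,
  multi-location transport, black box, noncatalytic inhibitor,
  dangling step link).

Documents are emitted as RDF/XML bytes and are byte-identical for
identical specs and seeds.  Fixture identifiers live in a reserved
``R-TST-`` namespace, except the worked example, which reuses the
source database's published stable IDs for traceability.  Small
molecules named in the worked example carry their real ChEBI CURIEs
(hydron CHEBI:15378, NADPH CHEBI:16474, NADP+ CHEBI:18009); the other
compound and protein accessions in fixtures are synthetic test CURIEs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

# shared fixture locations
CYTOSOL = ("GO:0005829", "cytosol")
EXTRACELLULAR = ("GO:0005576", "extracellular region")
PEROXISOMAL_MATRIX = ("GO:0005782", "peroxisomal matrix")

_RELATIONS = {
    "output_is_input": "RO:0002413",
    "output_is_catalyst": "RO:0002413",
    "regulation_pos": "RO:0002629",
    "regulation_neg": "RO:0002630",
    "step_only": "RO:0002411",
}


class _Doc:
    """Minimal ordered RDF/XML emitter for BioPAX Level-3 fixtures."""

    BASE = "http://biopax.test/fixture"

    def __init__(self) -> None:
        self.parts: list[str] = []
        self._seen: set[str] = set()
        self.n_entities = 0

    def element(self, tag: str, rid: str, props: list[tuple[str, str, str]]) -> str:
        if rid in self._seen:
            return rid
        self._seen.add(rid)
        lines = [f'<bp:{tag} rdf:about="#{escape(rid)}">']
        for name, kind, value in props:
            if kind == "lit":
                lines.append(
                    f'  <bp:{name} rdf:datatype='
                    f'"http://www.w3.org/2001/XMLSchema#string">{escape(value)}</bp:{name}>'
                )
            else:
                lines.append(f'  <bp:{name} rdf:resource="#{escape(value)}"/>')
        lines.append(f"</bp:{tag}>")
        self.parts.append("\n".join(lines))
        return rid

    # -- utility nodes ------------------------------------------------------
    def xref(self, kind: str, db: str, acc: str) -> str:
        rid = f"xref_{db}_{acc}".replace(":", "_").replace(" ", "_")
        return self.element(kind, rid, [("db", "lit", db), ("id", "lit", acc)])

    def location(self, go_id: str, label: str) -> str:
        x = self.xref("UnificationXref", "GENE ONTOLOGY", go_id)
        rid = "loc_" + go_id.replace(":", "_")
        return self.element(
            "CellularLocationVocabulary", rid, [("term", "lit", label), ("xref", "res", x)]
        )

    # -- physical entities --------------------------------------------------
    def protein(
        self,
        rid: str,
        name: str,
        uniprot: str | None = None,
        loc: tuple[str, str] | None = None,
        modifications: list[tuple[str, int]] | None = None,
        drug: bool = False,
    ) -> str:
        props: list[tuple[str, str, str]] = [("displayName", "lit", name)]
        if uniprot:
            ref = self.element(
                "ProteinReference",
                f"ref_{rid}",
                [("xref", "res", self.xref("UnificationXref", "UniProt", uniprot))],
            )
            props.append(("entityReference", "res", ref))
        if loc:
            props.append(("cellularLocation", "res", self.location(*loc)))
        for term, pos in modifications or []:
            voc = self.element(
                "SequenceModificationVocabulary",
                f"modvoc_{term}".replace(" ", "_"),
                [("term", "lit", term)],
            )
            site = self.element(
                "SequenceSite", f"site_{rid}_{pos}", [("sequencePosition", "lit", str(pos))]
            )
            feat = self.element(
                "ModificationFeature",
                f"feat_{rid}_{term}_{pos}".replace(" ", "_"),
                [("modificationType", "res", voc), ("featureLocation", "res", site)],
            )
            props.append(("feature", "res", feat))
        if drug:
            props.append(("xref", "res", self.xref("RelationshipXref", "IUPHAR", "T0001")))
        self.n_entities += 1
        return self.element("Protein", rid, props)

    def small_molecule(
        self, rid: str, name: str, chebi: str, loc: tuple[str, str] | None = None,
        drug: bool = False,
    ) -> str:
        ref = self.element(
            "SmallMoleculeReference",
            f"ref_{rid}",
            [("xref", "res", self.xref("UnificationXref", "ChEBI", chebi))],
        )
        props = [("displayName", "lit", name), ("entityReference", "res", ref)]
        if loc:
            props.append(("cellularLocation", "res", self.location(*loc)))
        if drug:
            props.append(("xref", "res", self.xref("RelationshipXref", "IUPHAR", "T0001")))
        self.n_entities += 1
        return self.element("SmallMolecule", rid, props)

    def complex(
        self, rid: str, name: str, components: list[str], loc: tuple[str, str] | None = None
    ) -> str:
        props = [("displayName", "lit", name)]
        props += [("component", "res", c) for c in components]
        if loc:
            props.append(("cellularLocation", "res", self.location(*loc)))
        self.n_entities += 1
        return self.element("Complex", rid, props)

    def entity_set(
        self, rid: str, name: str, members: list[str], loc: tuple[str, str] | None = None
    ) -> str:
        props = [("displayName", "lit", name)]
        props += [("memberPhysicalEntity", "res", m) for m in members]
        if loc:
            props.append(("cellularLocation", "res", self.location(*loc)))
        self.n_entities += 1
        return self.element("Protein", rid, props)

    # -- processes ----------------------------------------------------------
    def reaction(
        self,
        rid: str,
        name: str,
        left: list[str],
        right: list[str],
        mf_xref: str | None = None,
    ) -> str:
        props: list[tuple[str, str, str]] = [("displayName", "lit", name)]
        props += [("left", "res", e) for e in left]
        props += [("right", "res", e) for e in right]
        if mf_xref:
            props.append(
                ("xref", "res", self.xref("RelationshipXref", "GENE ONTOLOGY", mf_xref))
            )
        return self.element("BiochemicalReaction", rid, props)

    def catalysis(self, rid: str, controller: str, controlled: str) -> str:
        return self.element(
            "Catalysis",
            rid,
            [("controller", "res", controller), ("controlled", "res", controlled),
             ("controlType", "lit", "ACTIVATION")],
        )

    def control(self, rid: str, controller: str, controlled: str, ctype: str) -> str:
        return self.element(
            "Control",
            rid,
            [("controller", "res", controller), ("controlled", "res", controlled),
             ("controlType", "lit", ctype.upper())],
        )

    def pathway(
        self,
        rid: str,
        name: str,
        reactions: list[str],
        chain: list[tuple[str, str]] | None = None,
        bp_xref: str | None = None,
        subpathways: list[str] | None = None,
    ) -> str:
        """Pathway with components, per-reaction steps, and next-step links.

        ``chain`` pairs may reference reaction ids that are not
        components of this pathway (used to plant dangling links)."""
        props: list[tuple[str, str, str]] = [("displayName", "lit", name)]
        props += [("pathwayComponent", "res", r) for r in reactions]
        props += [("pathwayComponent", "res", s) for s in subpathways or []]
        step_ids: dict[str, str] = {}
        chain = chain or []
        stepped = list(reactions) + [r for pair in chain for r in pair]
        for r in dict.fromkeys(stepped):
            step_ids[r] = f"step_{rid}_{r}"
        next_of: dict[str, list[str]] = {}
        for up, down in chain:
            next_of.setdefault(up, []).append(down)
        for r, sid in step_ids.items():
            sprops: list[tuple[str, str, str]] = [("stepProcess", "res", r)]
            for down in next_of.get(r, []):
                sprops.append(("nextStep", "res", step_ids[down]))
            self.element("BiochemicalPathwayStep", sid, sprops)
            props.append(("pathwayOrder", "res", sid))
        if bp_xref:
            props.append(
                ("xref", "res", self.xref("RelationshipXref", "GENE ONTOLOGY", bp_xref))
            )
        return self.element("Pathway", rid, props)

    def provenance(self, version: str) -> None:
        self.element("Provenance", "provenance", [("displayName", "lit", version)])

    def to_bytes(self) -> bytes:
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
            ' xmlns:owl="http://www.w3.org/2002/07/owl#"\n'
            ' xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"\n'
            f" xml:base={quoteattr(self.BASE)}>\n"
            '<owl:Ontology rdf:about="">\n'
            '  <owl:imports rdf:resource="http://www.biopax.org/release/biopax-level3.owl#"/>\n'
            "</owl:Ontology>"
        )
        return ("\n".join([head] + self.parts + ["</rdf:RDF>"]) + "\n").encode("utf-8")


# ---------------------------------------------------------------------------
# worked example


def make_crym_fixture() -> bytes:
    """The two-reaction lysine-catabolism fragment of the worked example.

    Reaction R-HSA-5693347 'CRYM reduces P2C to PPCA': catalysis by
    CRYM, inputs hydron/P2C/NADPH, outputs NADP+/PPCA, molecular
    function GO:0047127, every participant in the peroxisomal matrix
    (GO:0005782); a downstream catalyzed reaction consumes PPCA and is
    reached by a step link.  Pathway R-HSA-71064 carries the lysine
    catabolic process cross-reference GO:0006554.  P2C/PPCA/P6C CURIEs
    and the downstream enzyme accession are synthetic test identifiers.
    """
    d = _Doc()
    d.provenance("fixture-corpus-v73-style")
    loc = PEROXISOMAL_MATRIX
    hydron = d.small_molecule("sm_hydron", "hydron", "CHEBI:15378", loc)
    p2c = d.small_molecule("sm_p2c", "P2C", "CHEBI:9900001", loc)
    nadph = d.small_molecule("sm_nadph", "NADPH", "CHEBI:16474", loc)
    nadp = d.small_molecule("sm_nadp", "NADP+", "CHEBI:18009", loc)
    ppca = d.small_molecule("sm_ppca", "PPCA", "CHEBI:9900002", loc)
    p6c = d.small_molecule("sm_p6c", "P6C", "CHEBI:9900003", loc)
    crym = d.protein("protein_crym", "CRYM", "Q14894", loc)
    oxidase = d.protein("protein_oxidase", "L-pipecolate oxidase", "P99901", loc)

    r1 = d.reaction(
        "R-HSA-5693347", "CRYM reduces P2C to PPCA",
        left=[hydron, p2c, nadph], right=[nadp, ppca], mf_xref="GO:0047127",
    )
    d.catalysis("catalysis_crym", crym, r1)
    r2 = d.reaction(
        "R-TST-000002", "PPCA oxidation (downstream step)",
        left=[ppca], right=[p6c], mf_xref="GO:0050031",
    )
    d.catalysis("catalysis_oxidase", oxidase, r2)
    d.pathway(
        "R-HSA-71064", "Lysine catabolism",
        reactions=[r1, r2], chain=[(r1, r2)], bp_xref="GO:0006554",
    )
    return d.to_bytes()


# ---------------------------------------------------------------------------
# random corpus


@dataclass
class FixtureSpec:
    """Shape of a synthetic corpus; the seed fully determines the bytes.

    Per-pathway reaction mix plus corpus-wide counts of special
    constructs.  The default fractions emulate a partially annotated
    corpus in which catalyzed reactions dominate, a substantial
    minority of reactions are binding events, and molecular-function,
    process and uniform-location annotation are each present for only
    part of the corpus.
    """

    n_pathways: int = 4
    n_catalyzed: int = 5
    n_transport: int = 1
    n_binding: int = 2
    n_dissociation: int = 1
    n_black_box: int = 1
    n_sets: int = 1
    n_complexes: int = 1
    n_proteoforms: int = 1
    n_noncatalytic_controls: int = 2
    activation_fraction: float = 0.5
    frac_mf_xref: float = 1.0
    frac_bp_xref: float = 0.5
    frac_uniform_location: float = 0.6
    n_disease_pathways: int = 0
    n_drug_reactions: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_pathways, self.n_catalyzed, self.n_transport, self.n_binding,
            self.n_dissociation, self.n_black_box, self.n_sets, self.n_complexes,
            self.n_proteoforms, self.n_noncatalytic_controls,
            self.n_disease_pathways, self.n_drug_reactions,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all fixture counts must be >= 0")
        for frac in (
            self.activation_fraction, self.frac_mf_xref, self.frac_bp_xref,
            self.frac_uniform_location,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.reactions_per_pathway == 0 and self.n_pathways > 0:
            raise ValueError("per-pathway reaction mix is empty")

    @property
    def reactions_per_pathway(self) -> int:
        return (
            self.n_catalyzed + self.n_transport + self.n_binding
            + self.n_dissociation + self.n_black_box
        )


class _CorpusBuilder:
    def __init__(self, spec: FixtureSpec):
        spec.validate()
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.doc = _Doc()
        self.doc.provenance(f"fixture-corpus-seed-{spec.seed}")
        self.counter = 0
        self.ledger: dict = {
            "seed": spec.seed,
            "pathways": {},
            "reactions": {},
            "chain_pairs": [],
            "standalone_controls": [],
            "special": {"sets": [], "complexes": [], "proteoforms": []},
        }
        self.special_budget = {
            "set": spec.n_sets, "complex": spec.n_complexes, "proteoform": spec.n_proteoforms,
        }
        self._patches: dict[str, list[tuple[str, str]]] = {}

    def _next(self, prefix: str) -> str:
        self.counter += 1
        return f"{prefix}{self.counter:05d}"

    def _new_protein(self, loc, mods=None, drug=False) -> str:
        rid = self._next("R-TST-P")
        return self.doc.protein(rid, f"protein {rid}", f"PT{self.counter:05d}", loc,
                                modifications=mods, drug=drug)

    def _new_small_molecule(self, loc, drug=False, chebi=None) -> str:
        rid = self._next("R-TST-S")
        chebi = chebi or f"CHEBI:9{self.counter:06d}"
        return self.doc.small_molecule(rid, f"compound {rid}", chebi, loc, drug=drug)

    # -- one reaction per category ------------------------------------------
    def _make_reaction(self, rid: str, category: str, uniform: bool, mf: str | None):
        d = self.doc
        loc_a = CYTOSOL
        loc_b = EXTRACELLULAR
        enzyme = None
        if category == "catalyzed":
            in_loc = loc_a if uniform else loc_b
            inputs = [self._new_small_molecule(in_loc), self._new_small_molecule(loc_a)]
            outputs = [self._new_small_molecule(loc_a)]
            kind = None
            for k in ("set", "complex", "proteoform"):
                if self.special_budget[k] > 0:
                    self.special_budget[k] -= 1
                    kind = k
                    break
            if kind == "set":
                members = [self._new_protein(loc_a) for _ in range(3)]
                enzyme = self.doc.entity_set(
                    self._next("R-TST-E"), "enzyme set", members, loc_a
                )
                self.ledger["special"]["sets"].append({"set": enzyme, "members": members})
            elif kind == "complex":
                comps = [self._new_protein(loc_a) for _ in range(2)]
                enzyme = self.doc.complex(self._next("R-TST-E"), "enzyme complex", comps, loc_a)
                self.ledger["special"]["complexes"].append({"complex": enzyme, "components": comps})
            elif kind == "proteoform":
                enzyme = self._new_protein(loc_a, mods=[("O-phospho-L-serine", 42)])
                self.ledger["special"]["proteoforms"].append(enzyme)
            else:
                enzyme = self._new_protein(loc_a)
            d.reaction(rid, f"reaction {rid}", inputs, outputs, mf_xref=mf)
            d.catalysis(f"cat_{rid}", enzyme, rid)
        elif category == "transport":
            # transporter-catalyzed translocation: same reference entity on
            # both sides, differing locations, enabled by a transporter
            chebi = f"CHEBI:9{self.counter + 1:06d}"
            inputs = [self._new_small_molecule(loc_b, chebi=chebi)]
            outputs = [self._new_small_molecule(loc_a, chebi=chebi)]
            transporter = self._new_protein(loc_a)
            d.reaction(rid, f"transport {rid}", inputs, outputs, mf_xref=mf)
            d.catalysis(f"cat_{rid}", transporter, rid)
        elif category == "binding":
            loc = loc_a if uniform else None
            p1 = self._new_protein(loc)
            p2 = self._new_protein(loc if uniform else loc_b)
            cpx = self.doc.complex(self._next("R-TST-C"), f"complex {rid}", [p1, p2], loc)
            inputs, outputs = [p1, p2], [cpx]
            d.reaction(rid, f"binding {rid}", inputs, outputs, mf_xref=None)
        elif category == "dissociation":
            loc = loc_a if uniform else None
            p1 = self._new_protein(loc)
            p2 = self._new_protein(loc if uniform else loc_b)
            cpx = self.doc.complex(self._next("R-TST-C"), f"complex {rid}", [p1, p2], loc)
            inputs, outputs = [cpx], [p1, p2]
            d.reaction(rid, f"dissociation {rid}", inputs, outputs, mf_xref=None)
        else:  # black_box
            outputs = [self._new_protein(loc_a if uniform else None)]
            inputs = []
            d.reaction(rid, f"black box {rid}", inputs, outputs, mf_xref=None)
        return inputs, outputs

    # -- corpus assembly ----------------------------------------------------
    def build(self) -> tuple[bytes, dict]:
        spec = self.spec
        all_rids_ordered: list[str] = []
        pathway_specs = [(f"R-TST-PW{i:03d}", False) for i in range(spec.n_pathways)]
        pathway_specs += [
            (f"R-TST-DPW{i:03d}", True) for i in range(spec.n_disease_pathways)
        ]
        drug_remaining = spec.n_drug_reactions

        for pid, disease in pathway_specs:
            bp = f"GO:91{len(self.ledger['pathways']):05d}" if (
                self.rng.random() < spec.frac_bp_xref
            ) else None
            categories = (
                ["catalyzed"] * spec.n_catalyzed
                + ["transport"] * spec.n_transport
                + ["binding"] * spec.n_binding
                + ["dissociation"] * spec.n_dissociation
                + ["black_box"] * spec.n_black_box
            )
            self.rng.shuffle(categories)
            rids, io_map = [], {}
            for category in categories:
                rid = self._next("R-TST-RX")
                uniform = (
                    category in {"catalyzed", "binding", "dissociation", "black_box"}
                    and self.rng.random() < spec.frac_uniform_location
                )
                mf = (
                    f"GO:80{self.counter:05d}"
                    if category in {"catalyzed", "transport"}
                    and self.rng.random() < spec.frac_mf_xref
                    else None
                )
                inputs, outputs = self._make_reaction(rid, category, uniform, mf)
                io_map[rid] = (inputs, outputs)
                rids.append(rid)
                # transporter-catalyzed translocations classify as catalyzed
                # with the transport flag set
                self.ledger["reactions"][rid] = {
                    "category": "catalyzed" if category == "transport" else category,
                    "transport_flag": category == "transport",
                    "pathway": pid,
                    "mf_xref": mf,
                    "uniform_location": uniform,
                    "drug": False,
                    "disease": disease,
                }
            # chain consecutive reactions; plant the causal basis of each pair
            chain = []
            for up, down in zip(rids, rids[1:]):
                down_cat = self.ledger["reactions"][down]["category"]
                up_rec = self.ledger["reactions"][up]
                # the shared entity joins the downstream participant pool, so
                # it must sit in the uniform location to keep planted
                # location truths intact
                up_out_in_cytosol = up_rec["category"] in {"catalyzed", "transport"} or (
                    up_rec["uniform_location"]
                )
                options = ["step_only", "regulation_pos", "regulation_neg"]
                if down_cat in {"catalyzed", "binding"} and up_out_in_cytosol:
                    options += ["output_is_input", "output_is_input"]
                basis = self.rng.choice(options) if io_map[up][1] else "step_only"
                if basis == "output_is_input":
                    shared = io_map[up][1][0]
                    # re-emit the downstream reaction is impossible (elements
                    # are write-once), so the shared entity is appended via a
                    # second pass: record and patch below
                    self._patches.setdefault(down, []).append(("left", shared))
                elif basis.startswith("regulation"):
                    ctype = "activation" if basis == "regulation_pos" else "inhibition"
                    controller = io_map[up][1][0] if io_map[up][1] else None
                    if controller is None:
                        basis = "step_only"
                    else:
                        self.doc.control(f"ctl_{up}_{down}", controller, down, ctype)
                chain.append((up, down))
                self.ledger["chain_pairs"].append(
                    {"up": up, "down": down, "basis": basis, "relation": _RELATIONS[basis]}
                )
            self.doc.pathway(pid, f"pathway {pid}", rids, chain=chain, bp_xref=bp)
            self.ledger["pathways"][pid] = {
                "bp_xref": bp, "reactions": rids, "disease": disease,
            }
            all_rids_ordered.extend(rids)

        if spec.n_disease_pathways:
            self.doc.pathway(
                "R-TST-DISEASE", "disease branch root", [],
                subpathways=[pid for pid, dz in pathway_specs if dz],
            )

        # drug planting: extra drug-flagged input on chain-internal reactions
        drug_candidates = [
            rid for rid in all_rids_ordered
            if not self.ledger["reactions"][rid]["disease"]
            and self.ledger["reactions"][rid]["category"] == "catalyzed"
        ]
        for rid in drug_candidates[:drug_remaining]:
            drug_entity = self._new_small_molecule(CYTOSOL, drug=True)
            self._patches.setdefault(rid, []).append(("left", drug_entity))
            self.ledger["reactions"][rid]["drug"] = True
            # an off-location extra participant would break uniformity, so
            # drug entities are planted in the uniform location (cytosol)

        # standalone noncatalytic regulators (become binding activity nodes)
        targets = [
            rid for rid in all_rids_ordered if not self.ledger["reactions"][rid]["disease"]
        ]
        for i in range(min(spec.n_noncatalytic_controls, len(targets))):
            rid = self.rng.choice(targets)
            ctype = (
                "activation" if self.rng.random() < spec.activation_fraction else "inhibition"
            )
            controller = self._new_protein(CYTOSOL)
            self.doc.control(f"ctl_standalone_{i}", controller, rid, ctype)
            self.ledger["standalone_controls"].append({"reaction": rid, "type": ctype})

        self._apply_patches()
        self.ledger["n_entities"] = self.doc.n_entities
        self.ledger["n_reactions"] = len(self.ledger["reactions"])
        self.ledger["n_pathways"] = len(self.ledger["pathways"]) + (
            1 if spec.n_disease_pathways else 0
        )
        self._expected()
        return self.doc.to_bytes(), self.ledger

    def _apply_patches(self) -> None:
        """Append planted participants to already-emitted reactions.

        Elements are write-once strings, so planted shared/drug inputs
        are spliced into the reaction's XML block before emission ends.
        """
        for rid, additions in self._patches.items():
            for i, part in enumerate(self.doc.parts):
                if f'rdf:about="#{rid}"' in part and part.startswith("<bp:BiochemicalReaction"):
                    extra = "\n".join(
                        f'  <bp:{prop} rdf:resource="#{eid}"/>' for prop, eid in additions
                    )
                    self.doc.parts[i] = part.replace(
                        f"</bp:BiochemicalReaction>", extra + "\n</bp:BiochemicalReaction>"
                    )
                    break

    def _expected(self) -> None:
        """Planted-truth expectations for the filtered, converted corpus."""
        led = self.ledger
        retained = [
            rid for rid, r in led["reactions"].items() if not r["disease"] and not r["drug"]
        ]
        retained_set = set(retained)
        surviving_pairs = [
            p for p in led["chain_pairs"]
            if p["up"] in retained_set and p["down"] in retained_set
        ]
        dropped = [
            p for p in led["chain_pairs"]
            if not led["reactions"][p["up"]]["disease"]
            and (p["up"] not in retained_set or p["down"] not in retained_set)
        ]
        relation_counts: dict[str, int] = {}
        for p in surviving_pairs:
            relation_counts[p["relation"]] = relation_counts.get(p["relation"], 0) + 1
        connected = {p["up"] for p in surviving_pairs} | {p["down"] for p in surviving_pairs}
        complete = []
        for rid in retained:
            r = led["reactions"][rid]
            parent_bp = led["pathways"][r["pathway"]]["bp_xref"]
            if (
                r["category"] == "catalyzed"
                and r["mf_xref"]
                and r["uniform_location"]
                and parent_bp
                and rid in connected
            ):
                complete.append(rid)
        category_counts: dict[str, int] = {}
        for rid in retained:
            c = led["reactions"][rid]["category"]
            category_counts[c] = category_counts.get(c, 0) + 1
        led["expected"] = {
            "retained_reactions": sorted(retained),
            "n_retained": len(retained),
            "relation_counts": relation_counts,
            "n_step_links_retained": len(surviving_pairs) + len(dropped),
            "n_dropped_links": len(dropped),
            "complete": sorted(complete),
            "n_complete": len(complete),
            "category_counts": category_counts,
            # standalone regulators on retained reactions, plus chain-planted
            # regulations whose step edge was dropped (the control itself
            # survives the filter and is faithfully converted to a binding node)
            "n_regulator_nodes": sum(
                1 for c in led["standalone_controls"] if c["reaction"] in retained_set
            )
            + sum(
                1
                for p in led["chain_pairs"]
                if p["basis"].startswith("regulation")
                and p["down"] in retained_set
                and p["up"] not in retained_set
            ),
        }


def make_random_pathway_corpus(spec: FixtureSpec) -> tuple[bytes, dict]:
    """Generate a corpus realizing ``spec`` plus its planted-truth ledger."""
    return _CorpusBuilder(spec).build()


# ---------------------------------------------------------------------------
# edge cases


def make_edge_case_suite() -> dict[str, bytes]:
    """One minimal document per edge case, keyed by case name."""
    suite: dict[str, bytes] = {}

    d = _Doc()
    members = [d.protein(f"p_set_{i}", f"kinase-{i}", f"PS000{i}", CYTOSOL) for i in range(3)]
    s = d.entity_set("set_catalyst", "kinase set", members)
    a = d.small_molecule("sm_a", "substrate A", "CHEBI:9910001", CYTOSOL)
    b = d.small_molecule("sm_b", "product B", "CHEBI:9910002", CYTOSOL)
    r = d.reaction("R-TST-SET01", "set-catalyzed step", [a], [b], mf_xref="GO:8000001")
    d.catalysis("cat_set", s, r)
    d.pathway("R-TST-PWSET", "set pathway", [r])
    suite["set_catalyst"] = d.to_bytes()

    d = _Doc()
    leaves = [d.protein(f"p_leaf_{i}", f"leaf-{i}", f"PL000{i}", CYTOSOL) for i in range(3)]
    inner = d.entity_set("inner_set", "inner set", leaves[:2])
    outer = d.entity_set("outer_set", "outer set", [inner, leaves[2]])
    a = d.small_molecule("sm_a", "substrate A", "CHEBI:9910003", CYTOSOL)
    b = d.small_molecule("sm_b", "product B", "CHEBI:9910004", CYTOSOL)
    r = d.reaction("R-TST-NST01", "nested-set step", [a], [b])
    d.catalysis("cat_nested", outer, r)
    d.pathway("R-TST-PWNST", "nested-set pathway", [r])
    suite["nested_set"] = d.to_bytes()

    d = _Doc()
    comps = [d.protein(f"p_sub_{i}", f"subunit-{i}", f"PC000{i}", CYTOSOL) for i in range(2)]
    cpx = d.complex("cpx_enzyme", "holoenzyme", comps, CYTOSOL)
    a = d.small_molecule("sm_a", "substrate A", "CHEBI:9910005", CYTOSOL)
    b = d.small_molecule("sm_b", "product B", "CHEBI:9910006", CYTOSOL)
    r = d.reaction("R-TST-CPX01", "complex-catalyzed step", [a], [b], mf_xref="GO:8000002")
    d.catalysis("cat_cpx", cpx, r)
    d.pathway("R-TST-PWCPX", "complex pathway", [r])
    suite["complex_enabler"] = d.to_bytes()

    d = _Doc()
    canon = d.protein("p_canon", "KRAS", "PK0001", CYTOSOL)
    form = d.protein(
        "p_form", "palmitoylated KRAS", "PK0001", CYTOSOL,
        modifications=[("S-palmitoyl-L-cysteine", 186)],
    )
    b = d.small_molecule("sm_b", "product B", "CHEBI:9910007", CYTOSOL)
    r = d.reaction("R-TST-PFM01", "proteoform step", [form], [b])
    d.catalysis("cat_pfm", canon, r)
    d.pathway("R-TST-PWPFM", "proteoform pathway", [r])
    suite["proteoform"] = d.to_bytes()

    d = _Doc()
    out_e = d.small_molecule("sm_x_out", "solute (extracellular)", "CHEBI:9910008",
                             EXTRACELLULAR)
    in_c = d.small_molecule("sm_x_in", "solute (cytosolic)", "CHEBI:9910008", CYTOSOL)
    r = d.reaction("R-TST-TRN01", "solute uptake", [out_e], [in_c])
    d.pathway("R-TST-PWTRN", "transport pathway", [r])
    suite["multi_location_transport"] = d.to_bytes()

    d = _Doc()
    prod = d.protein("p_prod", "nascent protein", "PB0001", CYTOSOL)
    r = d.reaction("R-TST-BBX01", "gene transcription (shorthand)", [], [prod])
    d.pathway("R-TST-PWBBX", "black-box pathway", [r])
    suite["black_box"] = d.to_bytes()

    d = _Doc()
    enz = d.protein("p_enz", "enzyme", "PI0001", CYTOSOL)
    inh = d.protein("p_inh", "inhibitor E", "PI0002", CYTOSOL)
    a = d.small_molecule("sm_a", "substrate A", "CHEBI:9910009", CYTOSOL)
    b = d.small_molecule("sm_b", "product B", "CHEBI:9910010", CYTOSOL)
    r = d.reaction("R-TST-INH01", "inhibited step", [a], [b], mf_xref="GO:8000003")
    d.catalysis("cat_inh", enz, r)
    d.control("ctl_inh", inh, r, "inhibition")
    d.pathway("R-TST-PWINH", "inhibitor pathway", [r])
    suite["noncatalytic_inhibitor"] = d.to_bytes()

    d = _Doc()
    enz = d.protein("p_enz", "enzyme", "PD0001", CYTOSOL)
    a = d.small_molecule("sm_a", "substrate A", "CHEBI:9910011", CYTOSOL)
    b = d.small_molecule("sm_b", "product B", "CHEBI:9910012", CYTOSOL)
    drug = d.small_molecule("sm_drug", "inhibitor drug", "CHEBI:9910013", CYTOSOL, drug=True)
    c = d.small_molecule("sm_c", "product C", "CHEBI:9910014", CYTOSOL)
    r1 = d.reaction("R-TST-DGL01", "upstream step", [a], [b], mf_xref="GO:8000004")
    d.catalysis("cat_dgl", enz, r1)
    r2 = d.reaction("R-TST-DGL02", "drug-involving step", [b, drug], [c])
    d.pathway("R-TST-PWDGL", "dangling-link pathway", [r1, r2], chain=[(r1, r2)])
    suite["dangling_step_link"] = d.to_bytes()

    return suite
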