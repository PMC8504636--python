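# Methods

## The conversion model

The package treats a pathway document as a typed graph of reactions
(conversions of molecular pools), physical entities, control
relationships and step links, and maps it to an activity-flow model
under three premises:

1. every conversion event corresponds to one molecular activity
   (conversion is total: a reaction that lacks attributes still
   converts, and the gaps are audited rather than papered over);
2. the attributes of a fully annotated reaction — function, enabler,
   participants, location, process, causal context — map one-to-one
   onto the attributes of a complete activity unit;
3. the meaning of a step link between two reactions can be decided
   from entity overlap: an upstream output acting as a noncatalytic
   regulator downstream implies direct regulation, an output consumed
   or used as catalyst downstream implies `directly provides input
   for`, and everything else is the weakest assertion, `causally
   upstream of`.

### Reaction classification

Categories are assigned by ordered structural rules: any catalysis
control makes a reaction *catalyzed* (flagged as transport when an
input and output share a reference identifier but differ in location);
with no catalysis, an empty participant side is a *black box*
(shorthand events such as "gene transcription"), more inputs than
outputs with a complex product is *binding*, the mirror image is
*dissociation*, equal counts with differing locations is *transport*,
and anything else is *other*. The classifier is a total, deterministic
function of the reaction's structure; stoichiometry is ignored (the
export's stoichiometric annotations do not change the side counts the
rules read).

A transporter-catalyzed translocation is deliberately kept in the
*catalyzed* category with a transport flag, so that the enabler is
retained **and** the start/end locations of the moved entity are still
extracted (`RO:0002338`/`RO:0002339`).

### Entity classes

Class identity is location-free: the cytosolic and nuclear copies of a
molecule share one class, because the source database mints a separate
entity per entity-location pair while the target representation puts
location on instances. Identity keys are, in order of preference, the
UniProt accession plus the (sorted) modification-descriptor set, the
sorted reference-xref set, the display name. Consequences:

* small molecules with a ChEBI xref map to the ChEBI class itself —
  no class is ever minted when a usable standard class exists;
* two entities with the same accession and identical modifications
  share one proteoform class, a subclass of the canonical protein's
  class (prevents class explosion; the modifications are recorded in
  the definition text);
* complexes become named classes with `has part` (BFO:0000051) links
  to component classes rather than full OWL intersection expressions —
  downstream consumers use named classes, and the logical detail lives
  in the definition;
* entity sets become named union classes over their recursively
  flattened leaf members ("any member can act"); nested sets flatten
  because a member-of-a-member can also act.

Minted IRIs are derived from the source entity's stable identifier
(`REACTO:<id>` of the first entity that minted the key), never random,
so repeated runs give byte-identical output.

### Causal-relation inference

When several bases hold for one step link, precedence is regulation >
provides-input > causally-upstream: regulation is the more specific
assertion. Entity overlap is computed on location-stripped classes
(location-minted copies of one molecule must match) and a union class
matches when any leaf member matches. Edges always follow the step
direction. Step links whose ends were filtered away (disease
pathways, drug reactions) are dropped and counted, never silently
lost.

Noncatalytic entity regulators that are *not* already expressed as a
regulation step edge become explicit binding activity nodes: a new
activity typed with the root GO binding class (configurable), enabled
by the regulator's class, with a positive- or negative-regulation edge
to the controlled activity. The step-edge check prevents asserting the
same regulation twice.

### Completeness audit

A unit is complete when all five testable attributes are present:
real molecular function (not the generated *molecular event* class),
enabler, single location, specific biological process (not the root
term), and at least one causal edge — counted in either direction,
since a terminal activity with only incoming edges is causally
connected. Inputs/outputs are not part of the test: shorthand events
legitimately omit them. Incomplete units are reported by their exact
missing-attribute subset (powerset representation), so any Venn-style
region of the missing-information breakdown is recoverable.

## Serialization

Models are OWL instance graphs in Turtle. Individuals get IRIs minted
from the model IRI plus a strictly increasing zero-padded ordinal;
axiom and evidence nodes are named (no blank nodes); triples are
emitted in sorted order. Identical input and configuration therefore
produce byte-identical files, and write→read→write is a fixed point.
Evidence is attached per asserted edge by OWL axiom annotation, with a
single configurable evidence class (default ECO:0000363, computational
combinatorial evidence used in automatic assertion) and the source
reaction's stable identifier as reference. Model IRIs follow
`http://model.geneontology.org/<pathway-core-id>` with release
suffixes stripped, one `.ttl` file per pathway; a pathway containing
only subpathways is represented by bare process nodes.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `FilterConfig.disease_roots` | `[]` | pathway ids whose subpathway closure is removed |
| `FilterConfig.drug_filter` | on | remove reactions with any drug participant (drug = Drug-class entity or drug-vocabulary xref) |
| `ConversionConfig.infer_transport_mf` | off | give unannotated transport-shaped reactions a generic transporter-activity function; off keeps defaults conservative — only source-asserted functions are used |
| `ConversionConfig.eco_class` | `ECO:0000363` | evidence class on automatic assertions |
| `ConversionConfig.binding_term` | `GO:0005488` | function class of regulator-derived binding nodes |

Molecular functions come only from the reaction's relationship
cross-references (first in document order wins, with a warning on
conflict — no GO-depth heuristics); processes come only from the
immediate parent pathway, so a reaction inherits the annotation gap
when its own pathway lacks a process term (no upward search).
A complex catalysis controller always enables as the complex class,
with an audit flag: automation cannot decide whether an activity is an
emergent property of the complex or attributable to one subunit.

## The synthetic corpus generator

Real corpus exports cannot ship with the package, so every stage is
exercised on generated documents that emulate the source structures:
catalyzed reactions (always carrying a molecular-function
cross-reference, as catalysis annotations do in the emulated corpus),
transporter-catalyzed translocations, binding/dissociation events
(complex assembly with no catalysis), black-box shorthand events,
entity sets, complexes, proteoforms, noncatalytic regulators, pathway
chains with planted causal bases, and disease/drug planting for the
filters. Defaults: 4 pathways x 10 reactions (5 catalyzed / 1
transport / 2 binding / 1 dissociation / 1 black box), process
annotation on half the pathways, uniform participant location for 60%
of the locatable reactions — a partially annotated corpus in which
most units are incomplete for location, process or enabler reasons,
as in real curated content. The generator emits a ledger of every
planted truth (categories, bases, gaps, flags), and tests compare
pipeline output against that construction-time record.

What the generator does **not** emulate: realistic pathway size
distributions, cross-pathway step links, multi-compartment complexes,
stoichiometry, and the long tail of entity kinds (RNA regions,
fragment features). Passing tests therefore demonstrate the
correctness of the conversion rules on representative structures, not
performance claims about any specific database release.

Test and acceptance runs use corpora of 40–220 reactions; the
pipeline is linear in document size, and these sizes exercise every
rule path while keeping the suite fast.

## Numerical and degenerate-input choices

* Ties: first-in-document order (sorted by identifier) everywhere a
  choice is forced — multiple MF xrefs, multiple catalysis controls.
* Degenerate inputs: empty documents produce empty collections;
  pathways with zero retained steps produce empty models with a
  warning; an empty entity set is an invariant violation and raises.
* Unknown BioPAX classes are skipped with a warning and recorded in
  an unresolved-reference registry; dangling step references are
  recorded at parse time and counted as dropped links at conversion
  time.
* Malformed XML raises a parse error naming the line/column reported
  by the XML parser.

## Known limitations

* No OWL reasoning: generated classes are not reclassified against
  GO/ChEBI, and the reasoning-based deepening of shallow annotations
  is out of scope.
* No cross-model causal links: causal edges connect activities within
  one pathway's model only.
* Proteoform classes are not aligned to Protein Ontology identifiers.
* Binding/dissociation events keep their participants as equals; no
  attempt is made to promote a primary enabler from reaction names.
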