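# biopax2gocam

Convert BioPAX Level-3 pathway documents (process-description style,
as exported by pathway knowledgebases such as Reactome) into GO-CAM
causal activity models (activity-flow style OWL instance graphs,
serialized as Turtle).

## The problem

Pathway databases describe biology as *process descriptions*: each
reaction is a transformation of input molecular pools into output
pools, optionally catalyzed or regulated by other entities. The Gene
Ontology's causal activity models (GO-CAMs) describe the same biology
as *activity flow*: gene-product activities (instances of GO molecular
function classes) joined by causal relations from the Relation
Ontology. This package performs the conversion between the two
representations, for bioinformaticians who want standard GO
annotations and causally linked activity networks out of curated
BioPAX pathway content.

Each retained reaction becomes exactly one **activity unit** with the
attributes

* molecular function (`rdf:type` on the activity individual),
* enabling entity (`enabled_by`, RO:0002333) — the catalysis
  controller's class,
* inputs and outputs (`has_input` RO:0002233 / `has_output`
  RO:0002234) with per-participant locations,
* a single cellular location (`occurs_in`, BFO:0000066), when all
  participants agree on one,
* membership in a biological process (`part_of`, BFO:0000050),
* causal edges to other activities.

Each pathway step link is given one of four causal relations, decided
from entity overlap between the linked reactions:

| condition (upstream output is …) | relation |
|---|---|
| a noncatalytic activator of the downstream reaction | `directly positively regulates` (RO:0002629) |
| a noncatalytic inhibitor | `directly negatively regulates` (RO:0002630) |
| an input or the catalyst of the downstream reaction | `directly provides input for` (RO:0002413) |
| none of the above | `causally upstream of` (RO:0002411) |

Entities with no class in standard ontologies — complexes, entity
sets, covalently modified proteoforms, location-specific copies — get
classes in a generated entity ontology: sets become unions (any member
can act), proteoforms become subclasses of the canonical protein's
class, and gene-product classes are rooted under ChEBI's *information
biomacromolecule* (CHEBI:33695). Activities that cannot be tied to an
annotated molecular function are typed with a generated *molecular
event* class, and a completeness audit reports, per activity unit,
which of the five attributes (MF, enabler, location, causal link,
specific process) are missing.

## Worked example

The bundled worked-example fixture contains the lysine-catabolism
fragment in which the CRYM enzyme reduces P2C to PPCA (3 inputs, 2
outputs, catalysis, all participants in the peroxisomal matrix),
followed by a downstream reaction consuming PPCA:

```python
import biopax2gocam as bg
from biopax2gocam.fixtures import make_crym_fixture

result = bg.convert_document(make_crym_fixture())
print(result.audit().as_dict())
```

prints

```
{'n_reactions': 2, 'n_complete': 2, 'n_incomplete': 0, 'n_root_bp': 0,
 'n_binding': 0, 'n_dissociation': 0, 'n_dropped_links': 0,
 'n_regulator_nodes': 0, 'relation_counts': {'RO:0002413': 1},
 'missing_category_counts': {}}
```

Both reactions convert to *complete* activity units, and the step link
between them becomes a single `directly provides input for`
(RO:0002413) edge, because the upstream output PPCA is an input of the
downstream reaction. In the serialized model
(`http://model.geneontology.org/R-HSA-71064`), the CRYM activity
individual is typed with its molecular function and carries one edge
per attribute:

```
<…/R-HSA-71064/000001> rdf:type GO:0047127 .        # thiomorpholine-carboxylate dehydrogenase activity
<…/R-HSA-71064/000001> RO:0002333 <…/000003> .      # enabled by CRYM
<…/R-HSA-71064/000001> RO:0002233 <…/000005> .      # has input (x3: hydron, P2C, NADPH)
<…/R-HSA-71064/000001> RO:0002234 <…/000011> .      # has output (x2: NADP+, PPCA)
<…/R-HSA-71064/000001> BFO:0000066 <…/000015> .     # occurs in GO:0005782 (peroxisomal matrix)
<…/R-HSA-71064/000001> BFO:0000050 <…/000016> .     # part of GO:0006554 (lysine catabolic process)
<…/R-HSA-71064/000001> RO:0002413 <…/000002> .      # directly provides input for the next activity
```

The same pipeline runs from the shell:

```sh
biopax2gocam fixtures crym -o fixtures/
biopax2gocam convert fixtures/crym.owl -o models/
# -> models/R-HSA-71064.ttl, models/reacto.ttl, audit TSV/JSON reports
biopax2gocam audit models/R-HSA-71064.ttl
```

`convert` accepts `--disease-root` (removes the subpathway closure of
the given pathway ids) and `--no-drug-filter`; by default reactions
with any drug participant are excluded.

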