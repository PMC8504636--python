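"""End-to-end conversion pipeline: BioPAX bytes in, models + audit out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .audit import AuditSummary, audit_collection
from .biopax_model import (
    FilterConfig,
    PathwayCollection,
    classify_all,
    filter_collection,
    parse_biopax,
)
from .causal import attach_regulators, link_pathway_steps
from .conversion import ConversionConfig, GoCamModelSkeleton, convert_pathway
from .reacto import EntityOntology, build_entity_ontology


@dataclass
class ConversionResult:
    collection: PathwayCollection
    ontology: EntityOntology
    models: list[GoCamModelSkeleton]

    def audit(self) -> AuditSummary:
        return audit_collection(self.models)


def convert_collection(
    collection: PathwayCollection,
    config: Optional[ConversionConfig] = None,
    filter_config: Optional[FilterConfig] = None,
) -> ConversionResult:
    """Filter, classify, build the entity ontology, convert every
    pathway to a model, link step edges and attach regulator nodes."""
    config = config or ConversionConfig()
    if filter_config is not None:
        collection = filter_collection(collection, filter_config)
    classify_all(collection)
    ontology = build_entity_ontology(collection)
    models = []
    for pathway in collection.pathways:
        model = convert_pathway(pathway, collection, ontology, config)
        link_pathway_steps(model, pathway, collection, ontology)
        attach_regulators(model, collection, ontology, config)
        models.append(model)
    return ConversionResult(collection=collection, ontology=ontology, models=models)


def convert_document(
    document: bytes | str,
    config: Optional[ConversionConfig] = None,
    filter_config: Optional[FilterConfig] = None,
) -> ConversionResult:
    """Parse one BioPAX Level-3 document and convert it end to end."""
    return convert_collection(parse_biopax(document), config, filter_config)
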