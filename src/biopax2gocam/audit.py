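"""Completeness audit of converted activity units.

A complete activity unit specifies a real molecular function (not the
generated ``molecular event`` fallback), an enabling entity, a single
cellular location, membership in a specific biological process (not
the root term) and at least one causal connection.  Inputs and outputs
may legitimately be absent (shorthand black-box events), so they do
not enter the completeness test.

The audit reports the missing-attribute category of every incomplete
unit (the powerset representation: any Venn-style region of the
missing-information diagram is recoverable), the per-relation census
of converted step links, and the count of dropped (unconvertible)
links.  Auditing is read-only and never mutates models.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import vocab
from .biopax_model import ReactionCategory
from .conversion import ActivityUnit, GoCamModelSkeleton

#: attribute labels used in category keys, in display order
_ATTRS = ("MF", "Enabler", "Loc", "Causal", "BP")


@dataclass
class CompletenessRecord:
    activity_id: str
    has_mf: bool
    has_enabler: bool
    has_location: bool
    has_causal: bool
    has_specific_bp: bool

    @property
    def complete(self) -> bool:
        return (
            self.has_mf
            and self.has_enabler
            and self.has_location
            and self.has_causal
            and self.has_specific_bp
        )

    @property
    def category_key(self) -> tuple[str, ...]:
        missing = []
        for label, ok in zip(
            _ATTRS,
            (self.has_mf, self.has_enabler, self.has_location, self.has_causal,
             self.has_specific_bp),
        ):
            if not ok:
                missing.append(label)
        return tuple(missing)


@dataclass
class AuditSummary:
    n_reactions: int = 0
    n_complete: int = 0
    n_incomplete: int = 0
    missing_category_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    n_root_bp: int = 0
    relation_counts: dict[str, int] = field(default_factory=dict)
    n_dropped_links: int = 0
    n_binding: int = 0
    n_dissociation: int = 0
    n_regulator_nodes: int = 0

    @property
    def n_step_links(self) -> int:
        return sum(self.relation_counts.values()) + self.n_dropped_links

    def missing_attribute_counts(self) -> dict[str, int]:
        """Marginal count per missing attribute (sums over categories)."""
        out = {a: 0 for a in _ATTRS}
        for key, n in self.missing_category_counts.items():
            for a in key:
                out[a] += n
        return out

    def category_table(self) -> pd.DataFrame:
        rows = [
            {"missing": "+".join(key) if key else "(complete)", "count": n}
            for key, n in sorted(self.missing_category_counts.items())
        ]
        rows.insert(0, {"missing": "(complete)", "count": self.n_complete})
        return pd.DataFrame(rows, columns=["missing", "count"])

    def as_dict(self) -> dict:
        return {
            "n_reactions": self.n_reactions,
            "n_complete": self.n_complete,
            "n_incomplete": self.n_incomplete,
            "n_root_bp": self.n_root_bp,
            "n_binding": self.n_binding,
            "n_dissociation": self.n_dissociation,
            "n_dropped_links": self.n_dropped_links,
            "n_regulator_nodes": self.n_regulator_nodes,
            "relation_counts": dict(self.relation_counts),
            "missing_category_counts": {
                "+".join(k) or "none": v for k, v in self.missing_category_counts.items()
            },
        }


def audit_activity(unit: ActivityUnit, has_incoming: bool = False) -> CompletenessRecord:
    """Completeness record for one unit.

    ``has_incoming`` marks units with at least one incoming causal
    edge; causal connectivity counts edges in either direction, since a
    terminal activity with only incoming edges is causally connected.
    """
    return CompletenessRecord(
        activity_id=unit.activity_id,
        has_mf=unit.function_class != vocab.MOLECULAR_EVENT,
        has_enabler=unit.enabler is not None,
        has_location=unit.location is not None,
        has_causal=bool(unit.causal_edges) or has_incoming,
        has_specific_bp=unit.process_class != vocab.BP_ROOT,
    )


def audit_model(model: GoCamModelSkeleton) -> list[CompletenessRecord]:
    """Records for the reaction-derived units of one model (read-only)."""
    incoming = {e.target for u in model.activities for e in u.causal_edges}
    return [
        audit_activity(u, has_incoming=u.activity_id in incoming)
        for u in model.activities
        if u.source_reaction is not None
    ]


def audit_collection(models: Iterable[GoCamModelSkeleton]) -> AuditSummary:
    """Corpus-level census over converted, causally linked models."""
    summary = AuditSummary()
    relation_counter: Counter[str] = Counter()
    category_counter: Counter[tuple[str, ...]] = Counter()
    for model in models:
        records = audit_model(model)
        summary.n_reactions += len(records)
        for rec in records:
            if rec.complete:
                summary.n_complete += 1
            else:
                summary.n_incomplete += 1
                category_counter[rec.category_key] += 1
            if not rec.has_specific_bp:
                summary.n_root_bp += 1
        for unit in model.activities:
            if unit.source_reaction is None:
                summary.n_regulator_nodes += 1
                continue
            if unit.category is ReactionCategory.BINDING:
                summary.n_binding += 1
            elif unit.category is ReactionCategory.DISSOCIATION:
                summary.n_dissociation += 1
            for edge in unit.causal_edges:
                if edge.origin == "step":
                    relation_counter[edge.relation] += 1
        summary.n_dropped_links += model.n_dropped_links
    summary.relation_counts = dict(relation_counter)
    summary.missing_category_counts = dict(category_counter)
    return summary


def per_model_table(models: Iterable[GoCamModelSkeleton]) -> pd.DataFrame:
    rows = []
    for model in models:
        records = audit_model(model)
        rows.append(
            {
                "model_id": model.model_id,
                "title": model.title,
                "n_activities": len(records),
                "n_complete": sum(1 for r in records if r.complete),
                "n_dropped_links": model.n_dropped_links,
            }
        )
    return pd.DataFrame(
        rows, columns=["model_id", "title", "n_activities", "n_complete", "n_dropped_links"]
    )
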