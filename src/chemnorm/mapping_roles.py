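"""MeSH↔lexicon mapping derivation/comparison and role rollups.

Because the upstream tagger normalizes chemical mentions to MeSH while this
pipeline normalizes the same mentions to the ontology, every mention that
carries both identifiers witnesses a context-based MeSH→entity mapping.
Comparing those derived pairs against a reference mapping (e.g. a BioPortal
export) classifies each mention as:

* ``matched`` — derived entity is in the reference set for its MeSH id;
* ``derived_only`` — our pipeline linked it but the reference has no pair
  for that MeSH id (new coverage);
* ``reference_only`` — the reference has a pair but our pipeline abstained;
* ``conflict`` — both exist and disagree, annotated when one side is the
  other's ``is_a`` ancestor (the frequent more-specific/less-specific case);
* ``neither`` — no derived entity and no reference pair.

Role rollups classify each normalized entity under configured parent role
terms (pharmaceutical, metabolite, nutrient, ...) by following ``has_role``
and closing upward over ``is_a`` within the role hierarchy; an entity
counts at most once per parent role regardless of how many role paths reach
it.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .disambiguator import NONE, NormalizationResult
from .lexicon import Lexicon

__all__ = [
    "MeshChebiMapping",
    "MappingComparison",
    "RoleSummary",
    "derive_mapping",
    "read_reference_mapping",
    "compare_mappings",
    "rollup_roles",
]

CATEGORIES = ("matched", "derived_only", "reference_only", "neither", "conflict")


@dataclass
class MeshChebiMapping:
    """mesh_id → set of entity ids, with per-pair provenance and multiplicity."""

    pairs: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    multiplicity: Counter = field(default_factory=Counter)

    def add(self, mesh_id: str, entity_id: str, provenance: str = "derived") -> None:
        self.pairs.setdefault(mesh_id, set()).add(entity_id)
        self.provenance[(mesh_id, entity_id)] = provenance
        self.multiplicity[(mesh_id, entity_id)] += 1

    def get(self, mesh_id: str) -> set[str]:
        return self.pairs.get(mesh_id, set())


@dataclass
class MappingComparison:
    """Per-mention categories, their counts/fractions, and conflict detail."""

    categories: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    conflicts: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"counts": self.counts, "fractions": self.fractions,
                 "conflicts": self.conflicts},
                indent=2, sort_keys=True,
            )
        )


def derive_mapping(results: Iterable[NormalizationResult]) -> MeshChebiMapping:
    """Collect MeSH→entity pairs from mentions carrying both identifiers."""
    mapping = MeshChebiMapping()
    for r in results:
        if r.mention.mesh_id and r.entity_id != NONE:
            mapping.add(r.mention.mesh_id, r.entity_id, "derived")
    return mapping


def read_reference_mapping(path: str | Path) -> MeshChebiMapping:
    """Read a reference mapping from 2-column TSV (mesh_id, entity_id)."""
    mapping = MeshChebiMapping()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"reference mapping row needs 2 columns: {row!r}")
            mapping.add(row[0], row[1], "reference")
    return mapping


def compare_mappings(
    results: Sequence[NormalizationResult],
    reference: MeshChebiMapping,
    lexicon: Lexicon,
) -> MappingComparison:
    """Categorize every mention against the reference mapping.

    One-to-many reference sets are resolved by prioritizing a match: a
    mention is ``matched`` when its derived entity is *any* member of the
    reference set. Conflicts carry an ancestor annotation computed over
    ``is_a`` edges only.
    """
    comparison = MappingComparison()
    for r in results:
        mesh = r.mention.mesh_id
        derived = r.entity_id if r.entity_id != NONE else None
        ref_set = reference.get(mesh) if mesh else set()
        if derived and ref_set:
            if derived in ref_set:
                cat = "matched"
            else:
                cat = "conflict"
                ancestors_of_derived = lexicon.is_a_ancestors(derived)
                annotation = "unrelated"
                if ref_set & ancestors_of_derived:
                    annotation = "derived_more_specific"
                elif any(derived in lexicon.is_a_ancestors(ref) for ref in ref_set):
                    annotation = "reference_more_specific"
                comparison.conflicts.append(
                    {
                        "doc_id": r.mention.doc_id,
                        "mesh_id": mesh,
                        "derived": derived,
                        "reference": sorted(ref_set),
                        "annotation": annotation,
                    }
                )
        elif derived and not ref_set:
            cat = "derived_only"
        elif not derived and ref_set:
            cat = "reference_only"
        else:
            cat = "neither"
        comparison.categories.append(cat)
    n = len(comparison.categories)
    comparison.counts = {c: comparison.categories.count(c) for c in CATEGORIES}
    comparison.fractions = {c: (k / n if n else 0.0) for c, k in comparison.counts.items()}
    return comparison


@dataclass
class RoleSummary:
    """Counts per role id plus the rollup to configured parent roles."""

    parent_roles: list[str]
    mention_counts: Counter = field(default_factory=Counter)  # role_id → mentions
    entity_sets: dict[str, set[str]] = field(default_factory=dict)  # role_id → entities
    unclassified_mentions: int = 0
    n_mentions: int = 0  # non-NONE results considered

    def distinct_entities(self, role_id: str) -> int:
        return len(self.entity_sets.get(role_id, set()))

    def fraction(self, role_id: str) -> float:
        return self.mention_counts[role_id] / self.n_mentions if self.n_mentions else 0.0

    def treemap_frame(self, lexicon: Lexicon) -> pd.DataFrame:
        """Treemap-ready table: parent_role, role, mention count."""
        rows = []
        for parent in self.parent_roles:
            for role_id, entities in sorted(self.entity_sets.items()):
                if role_id == parent:
                    continue
                if parent in lexicon.role_closure([role_id]):
                    rows.append(
                        {"parent_role": parent, "role": role_id,
                         "count": self.mention_counts[role_id]}
                    )
        return pd.DataFrame(rows, columns=["parent_role", "role", "count"])


def rollup_roles(
    results: Iterable[NormalizationResult],
    lexicon: Lexicon,
    parent_roles: Sequence[str],
) -> RoleSummary:
    """Roll normalized mentions up to parent role terms.

    For each non-``NONE`` result: collect the entity's ``has_role`` targets,
    close upward over ``is_a`` within the role hierarchy, and count the
    mention under every role in the closure (so each configured parent sees
    it at most once). Mentions whose entity has no role relation land in the
    unclassified bucket.
    """
    for p in parent_roles:
        if p not in lexicon:
            raise ValueError(f"unknown parent role id: {p}")
    summary = RoleSummary(parent_roles=list(parent_roles))
    for r in results:
        if r.entity_id == NONE:
            continue
        summary.n_mentions += 1
        ent = lexicon.entities.get(r.entity_id)
        roles = [t for t in (ent.roles if ent else []) if t in lexicon]
        if not roles:
            summary.unclassified_mentions += 1
            continue
        closure = lexicon.role_closure(roles)
        for role_id in closure:
            summary.mention_counts[role_id] += 1
            summary.entity_sets.setdefault(role_id, set()).add(r.entity_id)
    return summary
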