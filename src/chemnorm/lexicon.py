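"""Ontology/lexicon ingestion and tiered synonym indices.

The lexicon is a ChEBI-style ontology: entities with a recommended name,
typed synonyms, a curation status (C = curated, E = exists uncurated), a
star rating (3 = curator-annotated, 2 = third-party), ``is_a`` hierarchy,
``has_role`` relations, and free-text definitions. Only entities with
status C/E and 2 or 3 stars are retained for matching — the rest are
submitted/deleted/obsolete records that should never receive mentions.

Two input dialects are accepted:

* standard OBO 1.4 ``[Term]`` stanzas (``subset: 3_STAR`` carries the star
  rating, an optional non-standard ``status:`` tag carries the status;
  absent tags default to C / 3 so vanilla public OBO exports load whole);
* a 6/7-column TSV fallback
  ``id, name, synonyms, status, stars, relations[, definition]`` where
  synonyms are pipe-joined ``surface`` or ``surface~TYPE`` items and
  relations are pipe-joined ``label TARGET_ID`` items.

External (PubChem-style) synonyms arrive as two 2-column TSVs: CID→synonym
and CID→entity links. Synonyms with "inconsistent structure" are dropped:
empty strings, strings with no alphabetic character, and bare registry
numbers (digit groups joined by hyphens).
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .textnorm import NormalizationConfig, DEFAULT_CONFIG, relaxed_key

__all__ = [
    "LexiconEntity",
    "Lexicon",
    "SynonymIndex",
    "ExternalSynonymTable",
    "FilterConfig",
    "LoadReport",
    "load_lexicon",
    "load_external_synonyms",
    "filter_external_synonyms",
    "build_synonym_indices",
    "TIER_ORDER",
]

RETAINED_STATUSES = frozenset({"C", "E"})
RETAINED_STARS = frozenset({2, 3})

#: Index tiers in the order the hierarchical matcher probes them.
TIER_ORDER = (
    "EXACT_NAME",
    "EXACT_SYNONYM",
    "RELAXED_NAME_SYNONYM",
    "EXACT_PUBCHEM",
    "RELAXED_PUBCHEM",
)

_REGISTRY_NUMBER_RE = re.compile(r"^\d+(?:-\d+)+$")


@dataclass
class LexiconEntity:
    entity_id: str
    name: str
    synonyms: list[tuple[str, str]] = field(default_factory=list)  # (surface, type tag)
    status: str = "C"
    stars: int = 3
    definition: str | None = None
    relations: list[tuple[str, str]] = field(default_factory=list)  # (label, target id)
    roles: list[str] = field(default_factory=list)  # has_role targets

    def is_a_parents(self) -> list[str]:
        return [t for label, t in self.relations if label == "is_a"]


@dataclass
class FilterConfig:
    """Which records and synonyms survive ingestion."""

    statuses: frozenset[str] = RETAINED_STATUSES
    stars: frozenset[int] = RETAINED_STARS
    drop_inconsistent_synonyms: bool = True


@dataclass
class LoadReport:
    """Counts of retained/dropped records per filter rule."""

    retained: int = 0
    dropped_status: int = 0
    dropped_stars: int = 0
    dropped_unknown_status: int = 0
    dropped_malformed: int = 0
    dangling_relation_targets: int = 0
    synonyms_dropped: Counter = field(default_factory=Counter)
    unlinked_cids: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained": self.retained,
            "dropped_status": self.dropped_status,
            "dropped_stars": self.dropped_stars,
            "dropped_unknown_status": self.dropped_unknown_status,
            "dropped_malformed": self.dropped_malformed,
            "dangling_relation_targets": self.dangling_relation_targets,
            "synonyms_dropped": dict(self.synonyms_dropped),
            "unlinked_cids": self.unlinked_cids,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


class Lexicon:
    """Retained entities plus the role hierarchy derived from ``is_a`` edges.

    ``role_hierarchy`` maps each role entity (any ``has_role`` target found
    in the lexicon) to its direct ``is_a`` parents, restricted to ids present
    in the lexicon; dangling targets stay listed in entity relations but are
    excluded here so downstream rollups never walk off the known graph.
    """

    def __init__(self, entities: Iterable[LexiconEntity], report: LoadReport | None = None):
        self.entities: dict[str, LexiconEntity] = {}
        for ent in entities:
            if ent.entity_id in self.entities:
                raise ValueError(f"duplicate entity id {ent.entity_id}")
            if not ent.name:
                raise ValueError(f"entity {ent.entity_id} has empty name")
            self.entities[ent.entity_id] = ent
        self.report = report or LoadReport(retained=len(self.entities))
        self.dangling_targets: set[str] = set()
        for ent in self.entities.values():
            for _, target in ent.relations:
                if target not in self.entities:
                    self.dangling_targets.add(target)
        self.report.dangling_relation_targets = len(self.dangling_targets)
        self.role_hierarchy: dict[str, set[str]] = self._build_role_hierarchy()

    def __len__(self) -> int:
        return len(self.entities)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entities

    def __getitem__(self, entity_id: str) -> LexiconEntity:
        return self.entities[entity_id]

    def name_of(self, entity_id: str) -> str:
        return self.entities[entity_id].name

    def _build_role_hierarchy(self) -> dict[str, set[str]]:
        role_ids = {r for ent in self.entities.values() for r in ent.roles if r in self.entities}
        hierarchy: dict[str, set[str]] = {}
        frontier = list(role_ids)
        while frontier:
            rid = frontier.pop()
            if rid in hierarchy:
                continue
            parents = {p for p in self.entities[rid].is_a_parents() if p in self.entities}
            hierarchy[rid] = parents
            frontier.extend(parents)
        return hierarchy

    def is_a_ancestors(self, entity_id: str) -> set[str]:
        """All transitive ``is_a`` ancestors of an entity (excluding itself)."""
        seen: set[str] = set()
        frontier = [entity_id]
        while frontier:
            eid = frontier.pop()
            ent = self.entities.get(eid)
            if ent is None:
                continue
            for parent in ent.is_a_parents():
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    def role_closure(self, role_ids: Iterable[str]) -> set[str]:
        """Close a set of role ids upward over ``is_a`` within the role graph."""
        seen: set[str] = set()
        frontier = [r for r in role_ids]
        while frontier:
            rid = frontier.pop()
            if rid in seen:
                continue
            seen.add(rid)
            frontier.extend(self.role_hierarchy.get(rid, ()))
        return seen


@dataclass
class ExternalSynonymTable:
    """PubChem-style synonyms: CID → surface list, CID → linked entity ids."""

    cid_synonyms: dict[str, list[str]] = field(default_factory=dict)
    cid_to_entity: dict[str, set[str]] = field(default_factory=dict)


def filter_external_synonyms(raw: Sequence[str]) -> list[str]:
    """Drop external synonyms with inconsistent structure.

    Removed: empty strings, strings containing no alphabetic character, and
    bare registry numbers (``72956-09-3``-style digit-hyphen groups).
    Everything else — including long systematic names — is retained.
    """
    out = []
    for s in raw:
        if not s or not s.strip():
            continue
        if not any(c.isalpha() for c in s):
            continue
        if _REGISTRY_NUMBER_RE.match(s.strip()):
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Parsing


class OboParseError(ValueError):
    pass


def _parse_obo(path: Path, report: LoadReport, filt: FilterConfig) -> list[LexiconEntity]:
    entities: list[LexiconEntity] = []
    current: dict | None = None
    in_term = False

    def flush():
        nonlocal current
        if current is None:
            return
        _maybe_keep(current, entities, report, filt)
        current = None

    syn_re = re.compile(r'^"(?P<surf>(?:[^"\\]|\\.)*)"\s*(?:(?P<scope>\w+))?\s*(?:(?P<type>\w+))?')
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                if in_term:
                    current = {"synonyms": [], "relations": [], "status": "C", "stars": 3}
                continue
            if not in_term or current is None:
                continue
            if ":" not in line:
                raise OboParseError(f"{path}:{lineno}: malformed tag line {line!r}")
            tag, _, value = line.partition(":")
            value = value.split(" !")[0].strip()
            tag = tag.strip()
            if tag == "id":
                current["id"] = value
            elif tag == "name":
                current["name"] = value
            elif tag == "def":
                m = re.match(r'^"((?:[^"\\]|\\.)*)"', value)
                if m:
                    current["definition"] = m.group(1).replace('\\"', '"')
            elif tag == "synonym":
                m = syn_re.match(value)
                if not m:
                    raise OboParseError(f"{path}:{lineno}: malformed synonym {value!r}")
                surf = m.group("surf").replace('\\"', '"')
                stype = m.group("type") or m.group("scope") or "EXACT"
                current["synonyms"].append((surf, stype))
            elif tag == "is_a":
                current["relations"].append(("is_a", value))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(f"{path}:{lineno}: malformed relationship {value!r}")
                current["relations"].append((parts[0], parts[1]))
            elif tag == "subset":
                m = re.match(r"^(\d)_STAR", value)
                if m:
                    current["stars"] = int(m.group(1))
            elif tag == "status":  # non-standard convenience tag
                current["status"] = value
            elif tag == "is_obsolete" and value == "true":
                current["status"] = "O"
            # all other tags (xref, property_value, ...) are ignored
    flush()
    return entities


def _maybe_keep(rec: dict, entities: list, report: LoadReport, filt: FilterConfig) -> None:
    if "id" not in rec or "name" not in rec or not rec["name"]:
        report.dropped_malformed += 1
        return
    status = rec.get("status", "C")
    if status not in filt.statuses:
        # S/D/O/F are the known submitted/deleted/obsolete/checked codes;
        # anything else is an unknown code — dropped and counted, never fatal.
        if status in {"S", "D", "O", "F"}:
            report.dropped_status += 1
        else:
            report.dropped_unknown_status += 1
        return
    stars = int(rec.get("stars", 3))
    if stars not in filt.stars:
        report.dropped_stars += 1
        return
    relations = list(rec["relations"])
    roles = [t for label, t in relations if label == "has_role"]
    entities.append(
        LexiconEntity(
            entity_id=rec["id"],
            name=rec["name"],
            synonyms=list(rec["synonyms"]),
            status=status,
            stars=stars,
            definition=rec.get("definition"),
            relations=relations,
            roles=roles,
        )
    )
    report.retained += 1


def _parse_tsv(path: Path, report: LoadReport, filt: FilterConfig) -> list[LexiconEntity]:
    entities: list[LexiconEntity] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 6:
                raise OboParseError(f"{path}:{lineno}: expected ≥6 TSV columns, got {len(row)}")
            eid, name, syn_field, status, stars_field, rel_field = row[:6]
            definition = row[6] if len(row) > 6 and row[6] else None
            synonyms = []
            for item in filter(None, syn_field.split("|")):
                surf, _, stype = item.partition("~")
                synonyms.append((surf, stype or "EXACT"))
            relations = []
            for item in filter(None, rel_field.split("|")):
                parts = item.split(" ", 1)
                if len(parts) != 2:
                    raise OboParseError(f"{path}:{lineno}: malformed relation {item!r}")
                relations.append((parts[0], parts[1].strip()))
            try:
                stars = int(stars_field)
            except ValueError as exc:
                raise OboParseError(f"{path}:{lineno}: bad stars {stars_field!r}") from exc
            rec = {
                "id": eid,
                "name": name,
                "synonyms": synonyms,
                "relations": relations,
                "status": status,
                "stars": stars,
            }
            if definition:
                rec["definition"] = definition
            _maybe_keep(rec, entities, report, filt)
    return entities


def load_lexicon(
    source: str | Path,
    filter_config: FilterConfig | None = None,
) -> Lexicon:
    """Load and filter an ontology from OBO 1.4 or the TSV fallback dialect.

    Retains only entities whose status is in ``filter_config.statuses``
    (default C/E) and whose star rating is in ``filter_config.stars``
    (default {2, 3}). The attached :class:`LoadReport` counts what each rule
    dropped; dangling relation targets are kept in ``relations`` but recorded.
    """
    path = Path(source)
    filt = filter_config or FilterConfig()
    report = LoadReport()
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.open(encoding="utf-8").read(4096)
    if path.suffix == ".obo" or "[Term]" in head:
        entities = _parse_obo(path, report, filt)
    else:
        entities = _parse_tsv(path, report, filt)
    return Lexicon(entities, report)


def load_external_synonyms(
    synonyms_path: str | Path,
    links_path: str | Path,
    filter_config: FilterConfig | None = None,
    report: LoadReport | None = None,
) -> ExternalSynonymTable:
    """Read CID→synonym and CID→entity 2-column TSVs into one table."""
    filt = filter_config or FilterConfig()
    table = ExternalSynonymTable()
    with open(synonyms_path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            table.cid_synonyms.setdefault(row[0], []).append(row[1])
    if filt.drop_inconsistent_synonyms:
        for cid, syns in table.cid_synonyms.items():
            kept = filter_external_synonyms(syns)
            if report is not None:
                report.synonyms_dropped["inconsistent_structure"] += len(syns) - len(kept)
            table.cid_synonyms[cid] = kept
    with open(links_path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            table.cid_to_entity.setdefault(row[0], set()).add(row[1])
    return table


# ---------------------------------------------------------------------------
# Indices


@dataclass
class SynonymIndex:
    """One lookup tier: key → set of (entity_id, original surface).

    EXACT tiers are keyed by the verbatim surface (case-sensitive); RELAXED
    tiers by :func:`chemnorm.textnorm.relaxed_key`, whose outputs are fixed
    points of the relaxed normalizer. Colliding keys keep every entity —
    collisions are what the disambiguator exists for.
    """

    tier: str
    table: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, key: str, entity_id: str, surface: str) -> None:
        if key:
            self.table.setdefault(key, set()).add((entity_id, surface))

    def get(self, key: str) -> set[tuple[str, str]]:
        return self.table.get(key, set())


def build_synonym_indices(
    lexicon: Lexicon,
    table: ExternalSynonymTable | None = None,
    normalizer_config: NormalizationConfig = DEFAULT_CONFIG,
    report: LoadReport | None = None,
) -> list[SynonymIndex]:
    """Build the five lookup indices in tier order.

    EXACT_NAME and EXACT_SYNONYM hold verbatim lexicon names/synonyms;
    RELAXED_NAME_SYNONYM holds relaxed keys of both. EXACT_PUBCHEM /
    RELAXED_PUBCHEM hold external synonyms resolved to entities through the
    CID link table; CIDs with no link contribute nothing (counted when a
    report is supplied).
    """
    table = table or ExternalSynonymTable()
    exact_name = SynonymIndex("EXACT_NAME")
    exact_syn = SynonymIndex("EXACT_SYNONYM")
    relaxed = SynonymIndex("RELAXED_NAME_SYNONYM")
    exact_pc = SynonymIndex("EXACT_PUBCHEM")
    relaxed_pc = SynonymIndex("RELAXED_PUBCHEM")

    for ent in lexicon.entities.values():
        exact_name.add(ent.name, ent.entity_id, ent.name)
        relaxed.add(relaxed_key(ent.name, normalizer_config), ent.entity_id, ent.name)
        for surf, _stype in ent.synonyms:
            exact_syn.add(surf, ent.entity_id, surf)
            relaxed.add(relaxed_key(surf, normalizer_config), ent.entity_id, surf)

    for cid, syns in table.cid_synonyms.items():
        entity_ids = table.cid_to_entity.get(cid)
        if not entity_ids:
            if report is not None:
                report.unlinked_cids += 1
            continue
        linked = [eid for eid in entity_ids if eid in lexicon]
        for surf in syns:
            key = relaxed_key(surf, normalizer_config)
            for eid in linked:
                exact_pc.add(surf, eid, surf)
                relaxed_pc.add(key, eid, surf)

    return [exact_name, exact_syn, relaxed, exact_pc, relaxed_pc]
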