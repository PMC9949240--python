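"""The hierarchical dictionary matcher.

A mention is probed against the lookup tiers in a fixed order and the walk
stops at the first tier that yields any candidate:

1. ``EXACT_NAME`` — verbatim match to a lexicon recommended name;
2. ``EXACT_SYNONYM`` — verbatim match to a lexicon synonym;
3. ``RELAXED_NAME_SYNONYM`` — relaxed-key match to a name or synonym;
4. ``EXACT_PUBCHEM`` — verbatim match to an external (CID-linked) synonym;
5. ``RELAXED_PUBCHEM`` — relaxed-key match to an external synonym;
6. ``FUZZY`` — indel-ratio scan (ratio strictly > threshold, default 50)
   over lexicon names, then lexicon synonyms, then external synonyms,
   stopping at the first sub-source with any hit;
7. ``NO_MATCH`` otherwise. Surfaces of ≤2 characters (or "water") are
   ``UNMATCHABLE`` and skip the ladder entirely.

Only a *singleton* hit at one of the two verbatim lexicon tiers is accepted
without disambiguation; every other non-empty candidate set is passed on to
the disambiguator (a singleton relaxed match is trivially selected there).
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator

from .lexicon import ExternalSynonymTable, Lexicon, SynonymIndex
from .textnorm import (
    DEFAULT_CONFIG,
    NormalizationConfig,
    is_unmatchable,
    levenshtein_ratio,
    relaxed_key,
)

__all__ = [
    "Mention",
    "MatchTier",
    "Candidate",
    "CandidateSet",
    "MatcherConfig",
    "generate_candidates",
    "batch_candidates",
    "read_mentions_tsv",
    "read_mentions_bioc_xml",
    "write_candidates_jsonl",
]


class MatchTier(IntEnum):
    """Total order of the match hierarchy (lower value = probed earlier)."""

    EXACT_NAME = 0
    EXACT_SYNONYM = 1
    RELAXED_NAME_SYNONYM = 2
    EXACT_PUBCHEM = 3
    RELAXED_PUBCHEM = 4
    FUZZY = 5
    UNMATCHABLE = 6
    NO_MATCH = 7


@dataclass(frozen=True)
class Mention:
    """A chemical surface string anchored to a document title by span."""

    doc_id: str
    title: str
    span: tuple[int, int]  # 0-based half-open character offsets into title
    mesh_id: str | None = None

    def __post_init__(self) -> None:
        start, end = self.span
        if not (0 <= start < end <= len(self.title)):
            raise ValueError(
                f"invalid span {self.span} for title of length {len(self.title)}"
            )

    @property
    def surface(self) -> str:
        return self.title[self.span[0] : self.span[1]]


@dataclass(frozen=True)
class Candidate:
    entity_id: str
    matched_surface: str
    lexical_score: float  # 100 for dictionary tiers, the indel ratio for FUZZY


@dataclass
class CandidateSet:
    mention: Mention
    tier: MatchTier
    candidates: list[Candidate] = field(default_factory=list)
    needs_disambiguation: bool = False


@dataclass(frozen=True)
class MatcherConfig:
    fuzzy_threshold: float = 50.0  # candidates kept when ratio is strictly greater
    pool_fuzzy_sources: bool = False  # pool hits across fuzzy sub-sources
    normalizer: NormalizationConfig = DEFAULT_CONFIG


def _sorted_candidates(cands: Iterable[Candidate]) -> list[Candidate]:
    # Deterministic: descending lexical score, then ascending entity id.
    return sorted(cands, key=lambda c: (-c.lexical_score, c.entity_id))


def _from_index(hits: set[tuple[str, str]]) -> list[Candidate]:
    best: dict[str, str] = {}
    for eid, surf in sorted(hits):
        best.setdefault(eid, surf)
    return _sorted_candidates(Candidate(eid, surf, 100.0) for eid, surf in best.items())


def _fuzzy_sources(
    lexicon: Lexicon, table: ExternalSynonymTable | None
) -> Iterator[list[tuple[str, str]]]:
    """Fuzzy sub-sources in hierarchy order: names, synonyms, external."""
    yield [(ent.name, ent.entity_id) for ent in lexicon.entities.values()]
    yield [
        (surf, ent.entity_id)
        for ent in lexicon.entities.values()
        for surf, _ in ent.synonyms
    ]
    if table is not None:
        yield [
            (surf, eid)
            for cid, syns in table.cid_synonyms.items()
            for eid in sorted(table.cid_to_entity.get(cid, ()))
            if eid in lexicon
            for surf in syns
        ]


def _fuzzy_scan(
    surface: str,
    lexicon: Lexicon,
    table: ExternalSynonymTable | None,
    config: MatcherConfig,
) -> list[Candidate]:
    pooled: dict[str, Candidate] = {}
    for source in _fuzzy_sources(lexicon, table):
        hits: dict[str, Candidate] = {}
        for surf, eid in source:
            ratio = levenshtein_ratio(surface, surf)
            if ratio > config.fuzzy_threshold:
                prev = hits.get(eid)
                if prev is None or ratio > prev.lexical_score:
                    hits[eid] = Candidate(eid, surf, ratio)
        if hits and not config.pool_fuzzy_sources:
            return _sorted_candidates(hits.values())
        for eid, cand in hits.items():
            prev = pooled.get(eid)
            if prev is None or cand.lexical_score > prev.lexical_score:
                pooled[eid] = cand
    return _sorted_candidates(pooled.values())


def generate_candidates(
    mention: Mention,
    indices: list[SynonymIndex],
    lexicon: Lexicon,
    table: ExternalSynonymTable | None = None,
    config: MatcherConfig | None = None,
) -> CandidateSet:
    """Walk the tier ladder for one mention and return its candidate set.

    ``indices`` must be the five indices from
    :func:`chemnorm.lexicon.build_synonym_indices` in tier order. Failure is
    never an exception: an unmatched mention comes back as ``NO_MATCH`` with
    an empty candidate list.
    """
    config = config or MatcherConfig()
    surface = mention.surface
    if is_unmatchable(surface):
        return CandidateSet(mention, MatchTier.UNMATCHABLE)

    by_tier = {idx.tier: idx for idx in indices}
    key = relaxed_key(surface, config.normalizer)
    probes = [
        (MatchTier.EXACT_NAME, surface),
        (MatchTier.EXACT_SYNONYM, surface),
        (MatchTier.RELAXED_NAME_SYNONYM, key),
        (MatchTier.EXACT_PUBCHEM, surface),
        (MatchTier.RELAXED_PUBCHEM, key),
    ]
    for tier, probe_key in probes:
        idx = by_tier.get(tier.name)
        if idx is None:
            continue
        hits = idx.get(probe_key)
        if hits:
            cands = _from_index(hits)
            exact_singleton = (
                len(cands) == 1
                and tier in (MatchTier.EXACT_NAME, MatchTier.EXACT_SYNONYM)
            )
            return CandidateSet(mention, tier, cands, not exact_singleton)

    fuzzy = _fuzzy_scan(surface, lexicon, table, config)
    if fuzzy:
        return CandidateSet(mention, MatchTier.FUZZY, fuzzy, True)
    return CandidateSet(mention, MatchTier.NO_MATCH)


def batch_candidates(
    mentions: Iterable[Mention | Exception],
    indices: list[SynonymIndex],
    lexicon: Lexicon,
    table: ExternalSynonymTable | None = None,
    config: MatcherConfig | None = None,
) -> tuple[list[CandidateSet], Counter]:
    """Match a mention stream, order-preserving, with a per-tier tally.

    Items that are exceptions (malformed records forwarded by a reader) are
    skipped and counted under ``"malformed"`` in the tally.
    """
    out: list[CandidateSet] = []
    tally: Counter = Counter({tier.name: 0 for tier in MatchTier})
    tally["malformed"] = 0
    for item in mentions:
        if isinstance(item, Exception):
            tally["malformed"] += 1
            continue
        cs = generate_candidates(item, indices, lexicon, table, config)
        tally[cs.tier.name] += 1
        out.append(cs)
    return out, tally


# ---------------------------------------------------------------------------
# I/O


def read_mentions_tsv(path: str | Path) -> Iterator[Mention | Exception]:
    """Read mentions from 5-column TSV: doc_id, title, start, end, mesh_id.

    An empty or ``-`` mesh_id means none. Malformed rows are yielded as
    exceptions so :func:`batch_candidates` can count them without aborting.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            try:
                if len(row) < 4:
                    raise ValueError(f"row {lineno}: expected ≥4 columns")
                doc_id, title, start, end = row[:4]
                mesh = row[4] if len(row) > 4 and row[4] not in ("", "-") else None
                yield Mention(doc_id, title, (int(start), int(end)), mesh)
            except (ValueError, IndexError) as exc:
                yield exc


def read_mentions_bioc_xml(path: str | Path) -> Iterator[Mention | Exception]:
    """Read title-passage mentions from PubTator-dialect BioC XML.

    Each document's first passage is taken as the title; annotation offsets
    are interpreted relative to that passage, and an ``identifier`` (or
    ``MESH``) infon supplies the MeSH id when present.
    """
    tree = ET.parse(path)
    for doc in tree.getroot().iter("document"):
        doc_id = doc.findtext("id", default="")
        passage = doc.find("passage")
        if passage is None:
            continue
        p_offset = int(passage.findtext("offset", default="0"))
        title = passage.findtext("text", default="")
        for ann in passage.iter("annotation"):
            loc = ann.find("location")
            if loc is None:
                continue
            start = int(loc.get("offset", "0")) - p_offset
            end = start + int(loc.get("length", "0"))
            mesh = None
            for infon in ann.iter("infon"):
                if infon.get("key") in ("identifier", "MESH") and infon.text:
                    mesh = infon.text.strip() or None
            try:
                yield Mention(doc_id, title, (start, end), mesh)
            except ValueError as exc:
                yield exc


def write_candidates_jsonl(candidate_sets: Iterable[CandidateSet], path: str | Path) -> None:
    """Write candidate sets as JSONL, one object per mention."""
    with open(path, "w", encoding="utf-8") as fh:
        for cs in candidate_sets:
            obj = {
                "doc_id": cs.mention.doc_id,
                "span": list(cs.mention.span),
                "surface": cs.mention.surface,
                "mesh_id": cs.mention.mesh_id,
                "tier": cs.tier.name,
                "needs_disambiguation": cs.needs_disambiguation,
                "candidates": [
                    {
                        "entity_id": c.entity_id,
                        "matched_surface": c.matched_surface,
                        "lexical_score": c.lexical_score,
                    }
                    for c in cs.candidates
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
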