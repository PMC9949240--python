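"""End-to-end normalization: mention stream → NormalizationResult stream.

Glue over the matcher and disambiguator. The per-mention decision logic:

* ``UNMATCHABLE`` / ``NO_MATCH`` → ``method="none"``, entity ``NONE``;
* singleton hit at a verbatim lexicon tier → ``method="exact"`` (never
  thresholded);
* everything else → ranked by the configured disambiguator (embedding
  cosine, or the fuzzy-ratio baseline), then optionally thresholded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .disambiguator import (
    NONE,
    EmbeddingBackend,
    NormalizationResult,
    apply_threshold,
    fuzzy_disambiguate,
    rank_candidates,
)
from .lexicon import ExternalSynonymTable, Lexicon, SynonymIndex
from .matcher import CandidateSet, MatchTier, MatcherConfig, Mention, batch_candidates

__all__ = ["PipelineConfig", "resolve_candidate_set", "normalize_mentions",
           "write_results_jsonl", "results_to_frame"]


@dataclass
class PipelineConfig:
    method: Literal["embedding", "fuzzy_baseline"] = "embedding"
    tau: float = -1.0  # cosine threshold; -1 disables
    matcher: MatcherConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matcher is None:
            self.matcher = MatcherConfig()


def resolve_candidate_set(
    cs: CandidateSet,
    backend: EmbeddingBackend | None,
    lexicon: Lexicon,
    config: PipelineConfig,
) -> NormalizationResult:
    """Turn one candidate set into a final normalization decision."""
    if not cs.candidates:
        return NormalizationResult(cs.mention, NONE, 0.0, "none", cs.tier)
    if not cs.needs_disambiguation:
        cand = cs.candidates[0]
        return NormalizationResult(
            cs.mention, cand.entity_id, cand.lexical_score, "exact", cs.tier,
            all_scores=[(cand.entity_id, cand.lexical_score)],
        )
    if config.method == "fuzzy_baseline":
        return fuzzy_disambiguate(cs)
    if backend is None:
        raise ValueError("embedding method requires a backend")
    result = rank_candidates(cs, backend, lexicon)
    return apply_threshold(result, config.tau)


def normalize_mentions(
    mentions: Iterable[Mention | Exception],
    lexicon: Lexicon,
    indices: list[SynonymIndex],
    backend: EmbeddingBackend | None = None,
    table: ExternalSynonymTable | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[NormalizationResult], dict]:
    """Normalize a mention stream; returns results plus a tier tally."""
    config = config or PipelineConfig()
    candidate_sets, tally = batch_candidates(mentions, indices, lexicon, table, config.matcher)
    results = [resolve_candidate_set(cs, backend, lexicon, config) for cs in candidate_sets]
    return results, dict(tally)


def write_results_jsonl(results: Iterable[NormalizationResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            fh.write(json.dumps(_result_obj(r), ensure_ascii=False) + "\n")


def _result_obj(r: NormalizationResult) -> dict:
    return {
        "doc_id": r.mention.doc_id,
        "span": list(r.mention.span),
        "surface": r.mention.surface,
        "mesh_id": r.mention.mesh_id,
        "entity_id": r.entity_id,
        "score": r.score,
        "method": r.method,
        "tier": r.tier.name,
        "needs_disambiguation": r.needs_disambiguation,
        "flagged_below_threshold": r.flagged_below_threshold,
        "all_scores": [[eid, s] for eid, s in r.all_scores],
    }


def results_to_frame(results: Iterable[NormalizationResult]) -> pd.DataFrame:
    """TSV-friendly summary table of normalization decisions."""
    rows = [_result_obj(r) for r in results]
    for row in rows:
        row["start"], row["end"] = row.pop("span")
        row["all_scores"] = ";".join(f"{eid}:{s:.4f}" for eid, s in row["all_scores"])
    return pd.DataFrame(
        rows,
        columns=["doc_id", "start", "end", "surface", "mesh_id", "entity_id",
                 "score", "method", "tier", "needs_disambiguation",
                 "flagged_below_threshold", "all_scores"],
    )
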