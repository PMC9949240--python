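"""Candidate disambiguation by sentence-pair cosine similarity.

For an ambiguous mention, each candidate entity produces a *candidate
title*: the document title with the mention span replaced by the
candidate's recommended name. The original title and every candidate title
are embedded, the candidate whose title is most cosine-similar to the
original wins, and a similarity threshold can later flag low-confidence
winners as probable lexicon gaps.

Two embedding backends ship with the package:

* :class:`HashedNgramBackend` — a deterministic hashed character-3-gram
  bag-of-features embedder. No model weights, no network, bit-reproducible;
  the default for tests and offline pipelines.
* :class:`SentenceTransformerBackend` — an adapter for an external
  sentence-embedding model (mean pooling, 512-token cap). Requires the
  optional ``sentence-transformers`` dependency and trained weights; the
  training recipe lives in the docs.

A :class:`PairOracleBackend` is also provided for validation: constructed
from known (title, correct candidate title) pairs, it embeds both members
of a pair identically so the correct candidate is always nearest — an
upper-bound backend used to separate matcher errors from embedding errors.

The fuzzy baseline (:func:`fuzzy_disambiguate`) instead keeps the candidate
whose matched surface has the largest indel ratio against the mention.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol

import numpy as np

from .lexicon import Lexicon
from .matcher import CandidateSet, MatchTier, Mention
from .textnorm import levenshtein_ratio

__all__ = [
    "EmbeddingBackend",
    "HashedNgramBackend",
    "PairOracleBackend",
    "SentenceTransformerBackend",
    "NormalizationResult",
    "NONE",
    "build_candidate_title",
    "cosine",
    "rank_candidates",
    "fuzzy_disambiguate",
    "apply_threshold",
]

#: Sentinel accession for "no entity chosen".
NONE = "NONE"


class EmbeddingBackend(Protocol):
    """Contract: ``embed(text) -> 1-D numeric vector`` of constant length."""

    identifier: str
    deterministic: bool

    def embed(self, text: str) -> np.ndarray: ...


class HashedNgramBackend:
    """Deterministic hashed character-3-gram embedder.

    Lower-cased text is decomposed into padded character 3-grams, each
    hashed (BLAKE2, salted with ``seed``) into one of ``dim`` buckets with a
    ±1 sign, and the bucket counts are L2-normalized. Same text → same
    vector, across processes and platforms.
    """

    def __init__(self, dim: int = 256, seed: int = 0, n: int = 3):
        self.dim = dim
        self.seed = seed
        self.n = n
        self.identifier = f"hashed-{n}gram-d{dim}-s{seed}"
        self.deterministic = True

    def _bucket(self, gram: str) -> tuple[int, float]:
        h = hashlib.blake2b(
            gram.encode("utf-8"), digest_size=8, salt=str(self.seed).encode()[:16]
        ).digest()
        val = int.from_bytes(h, "big")
        return val % self.dim, 1.0 if (val >> 62) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        padded = f"^{text.lower()}$"
        for i in range(max(len(padded) - self.n + 1, 1)):
            idx, sign = self._bucket(padded[i : i + self.n])
            v[idx] += sign
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v


class PairOracleBackend:
    """Embeds both members of each known text pair to the same unit vector.

    Any text outside the pair list gets its own (hash-derived) dimension, so
    distinct unknown texts are mutually orthogonal and orthogonal to every
    pair. Used to validate the ranking machinery independently of any real
    embedding model.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], overflow_dim: int = 4096):
        self._index: dict[str, int] = {}
        for a, b in pairs:
            if a not in self._index:
                self._index[a] = len(set(self._index.values()))
            self._index[b] = self._index[a]
        self._n_pairs = max(self._index.values(), default=-1) + 1
        self._overflow = overflow_dim
        self.dim = self._n_pairs + overflow_dim
        self.identifier = f"pair-oracle-{self._n_pairs}"
        self.deterministic = True

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        if text in self._index:
            v[self._index[text]] = 1.0
        else:
            h = hashlib.blake2b(text.encode("utf-8"), digest_size=8).digest()
            v[self._n_pairs + int.from_bytes(h, "big") % self._overflow] = 1.0
        return v


class SentenceTransformerBackend:
    """Adapter for an external sentence-embedding model.

    Honors the conventions of the sentence-level models this pipeline was
    designed around: 512-token cap and mean pooling over token embeddings.
    Requires the optional ``sentence-transformers`` package and downloaded
    weights, so it is never exercised in offline test runs.
    """

    def __init__(self, model_id: str, max_tokens: int = 512):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "SentenceTransformerBackend requires the 'sentence-transformers' "
                "package; install it or use HashedNgramBackend"
            ) from exc
        self._model = SentenceTransformer(model_id)
        self._model.max_seq_length = max_tokens
        self.identifier = f"sentence-transformer:{model_id}"
        self.deterministic = False

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional
        return np.asarray(self._model.encode([text])[0], dtype=float)


@dataclass
class NormalizationResult:
    """Final linking decision for one mention."""

    mention: Mention
    entity_id: str  # accession or NONE
    score: float  # cosine in [-1,1] for embedding, ratio in [0,100] for fuzzy
    method: str  # one of: exact, embedding, fuzzy_baseline, none
    tier: MatchTier
    all_scores: list[tuple[str, float]] = field(default_factory=list)
    needs_disambiguation: bool = False
    flagged_below_threshold: bool = False
    error: str | None = None


def build_candidate_title(title: str, span: tuple[int, int], candidate_name: str) -> str:
    """Title with exactly the mention span replaced by the candidate name.

    Span-based (not string search), so repeated substrings elsewhere in the
    title are untouched.
    """
    start, end = span
    if not (0 <= start < end <= len(title)):
        raise ValueError(f"span {span} invalid for title of length {len(title)}")
    return title[:start] + candidate_name + title[end:]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; a zero vector scores 0 against anything (warned)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("cosine of a zero vector is defined as 0", RuntimeWarning)
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _default_tie_rule(tied: list) -> "object":
    """Among max-cosine candidates: higher lexical score, then lowest id."""
    return min(tied, key=lambda c: (-c.lexical_score, c.entity_id))


def rank_candidates(
    candidate_set: CandidateSet,
    backend: EmbeddingBackend,
    lexicon: Lexicon,
    tie_rule: Callable | None = None,
) -> NormalizationResult:
    """Choose the candidate whose substituted title is nearest the original.

    The original title is embedded once; each candidate title once. Exact
    cosine ties are broken by ``tie_rule`` (default: higher lexical score,
    then ascending entity id), which is independent of candidate order. A
    backend failure produces a ``method="none"`` result with the error
    recorded rather than an exception.
    """
    mention = candidate_set.mention
    cands = candidate_set.candidates
    if not cands:
        raise ValueError("rank_candidates requires a non-empty candidate set")
    tie_rule = tie_rule or _default_tie_rule
    try:
        title_vec = backend.embed(mention.title)
        scores: list[tuple[str, float]] = []
        by_id = {}
        for cand in cands:
            name = lexicon.name_of(cand.entity_id) if cand.entity_id in lexicon else cand.matched_surface
            cand_title = build_candidate_title(mention.title, mention.span, name)
            scores.append((cand.entity_id, cosine(title_vec, backend.embed(cand_title))))
            by_id[cand.entity_id] = cand
    except ValueError:
        raise
    except Exception as exc:  # backend failure: degrade, don't abort the stream
        return NormalizationResult(
            mention, NONE, 0.0, "none", candidate_set.tier,
            needs_disambiguation=candidate_set.needs_disambiguation, error=str(exc),
        )
    best_score = max(s for _, s in scores)
    tied = [by_id[eid] for eid, s in scores if s == best_score]
    winner = tie_rule(tied)
    return NormalizationResult(
        mention,
        winner.entity_id,
        best_score,
        "embedding",
        candidate_set.tier,
        all_scores=sorted(scores, key=lambda t: (-t[1], t[0])),
        needs_disambiguation=candidate_set.needs_disambiguation,
    )


def fuzzy_disambiguate(candidate_set: CandidateSet) -> NormalizationResult:
    """Baseline: keep the candidate with the largest indel ratio against the
    mention surface; ties go to the lowest entity id."""
    cands = candidate_set.candidates
    if not cands:
        raise ValueError("fuzzy_disambiguate requires a non-empty candidate set")
    surface = candidate_set.mention.surface
    scored = [(c.entity_id, levenshtein_ratio(surface, c.matched_surface)) for c in cands]
    best = max(s for _, s in scored)
    winner = min(eid for eid, s in scored if s == best)
    return NormalizationResult(
        candidate_set.mention,
        winner,
        best,
        "fuzzy_baseline",
        candidate_set.tier,
        all_scores=sorted(scored, key=lambda t: (-t[1], t[0])),
        needs_disambiguation=candidate_set.needs_disambiguation,
    )


def apply_threshold(result: NormalizationResult, tau: float) -> NormalizationResult:
    """Flag an embedding result whose cosine falls below ``tau``.

    ``tau = -1`` disables thresholding. Results from other methods (exact
    matches in particular) pass through untouched.
    """
    if result.method != "embedding" or tau <= -1 or result.score >= tau:
        return result
    return NormalizationResult(
        result.mention,
        NONE,
        result.score,
        result.method,
        result.tier,
        all_scores=result.all_scores,
        needs_disambiguation=result.needs_disambiguation,
        flagged_below_threshold=True,
        error=result.error,
    )
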