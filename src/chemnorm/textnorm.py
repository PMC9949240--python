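"""String normalization primitives for chemical mention matching.

Three operations shared by the indexing and matching layers:

* :func:`normalize_relaxed` — the "relaxed" normal form used by the
  dictionary tier that tolerates case, plural, and punctuation variation
  in chemical names (dashes, parentheses and commas carry no meaning for
  lookup; stemming is deliberately avoided because suffixes like ``-ol``
  or ``-ate`` are chemically meaningful).
* :func:`is_unmatchable` — mentions too short to be a chemical name, plus
  the ubiquitous non-informative mention "water".
* :func:`levenshtein_ratio` — the indel similarity ratio on a 0–100 scale
  used by the fuzzy tier (candidates are kept when the ratio is strictly
  greater than 50).

Unicode is preserved throughout: Greek letters are meaningful in chemical
nomenclature and are never ASCII-folded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "NormalizationConfig",
    "normalize_relaxed",
    "relaxed_key",
    "is_unmatchable",
    "levenshtein_ratio",
    "load_abbreviation_map",
]

#: Dash variants (ASCII hyphen, unicode hyphen, en/em dash, minus sign)
#: plus parentheses and comma — the characters stripped by the relaxed form.
DEFAULT_STRIP_CHARS = frozenset("-‐–—−(),")

#: Irregular plural → singular forms occasionally seen in chemical/biomedical
#: mention text. Applied to the final token only. Restricted to entries whose
#: singular is no longer than the plural, so normalization never lengthens a
#: string (Latin -a/-i plurals like "media" are deliberately left alone).
IRREGULAR_PLURALS = {
    "analyses": "analysis",
    "matrices": "matrix",
    "indices": "index",
    "vertices": "vertex",
}


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs of the relaxed normalizer.

    ``strip_chars`` must never contain alphanumeric characters — stripping
    those would merge distinct chemical names.
    """

    lowercase: bool = True
    strip_chars: frozenset[str] = DEFAULT_STRIP_CHARS
    depluralize: bool = True
    abbreviation_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [c for c in self.strip_chars if c.isalnum()]
        if bad:
            raise ValueError(f"strip_chars may not contain alphanumerics: {bad!r}")


DEFAULT_CONFIG = NormalizationConfig()


def _depluralize_token(token: str) -> str:
    """Singularize one token with a small irregular table plus suffix rules.

    Conservative by design: ``-ss``/``-us``/``-is`` endings are left alone
    (glass, apparatus, analysis-after-table) and two-letter tokens are never
    touched.
    """
    if token in IRREGULAR_PLURALS:
        return IRREGULAR_PLURALS[token]
    if len(token) <= 2 or not token[-1].isalpha():
        return token
    if token.endswith("ies") and len(token) > 3:
        return token[:-3] + "y"
    for suffix in ("ches", "shes", "xes", "zes", "ses"):
        if token.endswith(suffix):
            return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def normalize_relaxed(text: str, config: NormalizationConfig = DEFAULT_CONFIG) -> str:
    """Relaxed normal form of a chemical surface string.

    Applies, in order: whole-string abbreviation expansion, lower-casing,
    removal of ``strip_chars``, whitespace collapse to single spaces, and
    depluralization of the final whitespace-delimited token. Idempotent:
    ``normalize_relaxed(normalize_relaxed(x)) == normalize_relaxed(x)``.

    >>> normalize_relaxed("α-keto esters")
    'αketo ester'
    >>> normalize_relaxed("Simvastatin")
    'simvastatin'
    """
    if config.abbreviation_map:
        text = config.abbreviation_map.get(text, text)
    if config.lowercase:
        text = text.lower()
    if config.strip_chars:
        text = "".join(c for c in text if c not in config.strip_chars)
    tokens = text.split()
    if tokens and config.depluralize:
        tokens[-1] = _depluralize_token(tokens[-1])
    return " ".join(tokens)


def relaxed_key(text: str, config: NormalizationConfig = DEFAULT_CONFIG) -> str:
    """Lookup key for the RELAXED index tiers: relaxed form, spaces removed.

    Removing internal whitespace lets spacing variants of the same name
    collide — e.g. the plural mention "α-keto esters" keys to "αketoester",
    the same key as the lexicon name "α-ketoester".
    """
    return normalize_relaxed(text, config).replace(" ", "")


def is_unmatchable(surface: str) -> bool:
    """True for surfaces that should never be linked to an entity.

    A surface is unmatchable when, after trimming whitespace, it has two or
    fewer characters, or when it is the word "water" (case-insensitive).
    """
    s = surface.strip()
    return len(s) <= 2 or s.lower() == "water"


def levenshtein_ratio(a: str, b: str) -> float:
    """Indel similarity ratio between two strings on a 0–100 scale.

    Defined as ``100 * (1 - D(a, b) / (len(a) + len(b)))`` where ``D`` is the
    edit distance with insertion/deletion cost 1 and substitution cost 2.
    With that cost model ``D = len(a) + len(b) - 2 * LCS(a, b)``, so the
    ratio equals ``100 * 2 * LCS / (len(a) + len(b))``. Two empty strings
    score 100.
    """
    la, lb = len(a), len(b)
    if la + lb == 0:
        return 100.0
    if la == 0 or lb == 0:
        return 0.0
    if a == b:
        return 100.0
    # LCS length via the classic two-row DP.
    if lb > la:
        a, b, la, lb = b, a, lb, la
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        curr = [0] * (lb + 1)
        ca = a[i - 1]
        for j in range(1, lb + 1):
            if ca == b[j - 1]:
                curr[j] = prev[j - 1] + 1
            else:
                curr[j] = curr[j - 1] if curr[j - 1] >= prev[j] else prev[j]
        prev = curr
    lcs = prev[lb]
    return 200.0 * lcs / (la + lb)


def load_abbreviation_map(path: str | Path) -> dict[str, str]:
    """Read an abbreviation map from 2-column TSV (abbreviation, expansion)."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"abbreviation map row needs 2 columns: {row!r}")
            out[row[0]] = row[1]
    return out
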