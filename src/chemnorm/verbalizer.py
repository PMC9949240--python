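"""Verbalization: turning ontology facts into natural-language sentences.

Each retained entity's relation triples, synonyms, and definition are
rendered as human-readable sentences suitable for continued pretraining of
a biomedical language model — e.g. the triples

    diacylglycerol 44:4 —is_a→ diglyceride
    diacylglycerol 44:4 —SYNONYM→ DAG 44:4

become the single sentence

    "diacylglycerol 44:4, otherwise known as DAG 44:4, is a diglyceride."

Relation labels map to connective phrases through a
:class:`RelationTemplateTable`; labels without a template fall back to the
raw label with underscores replaced by spaces. The training recipe that
consumes this corpus (continued masked-LM pretraining, then sentence-level
fine-tuning) is documented in ``docs/methods.md``; running it is outside
this package.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import Lexicon, LexiconEntity

__all__ = [
    "VerbalizedSentence",
    "RelationTemplateTable",
    "DEFAULT_TEMPLATES",
    "verbalize_entity",
    "build_corpus",
    "write_corpus",
]

#: Synonym-type tags rendered with the IUPAC phrase rather than merged.
IUPAC_SYNONYM_TYPES = frozenset({"IUPAC_NAME", "IUPAC NAME", "IUPAC"})


@dataclass(frozen=True)
class VerbalizedSentence:
    entity_id: str
    text: str
    source_kind: str  # one of: triple, synonym, definition, merged

    def __post_init__(self) -> None:
        if not self.text or self.text[-1] not in ".!?":
            raise ValueError(f"sentence must end with terminal punctuation: {self.text!r}")


@dataclass
class RelationTemplateTable:
    """Relation label → connective phrase. Missing labels fall back to the
    raw label with underscores replaced by spaces."""

    phrases: dict[str, str] = field(default_factory=dict)

    def phrase(self, label: str) -> str:
        return self.phrases.get(label, label.replace("_", " "))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationTemplateTable":
        phrases = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or len(row) < 2:
                    continue
                phrases[row[0]] = row[1]
        return cls(phrases)


DEFAULT_TEMPLATES = RelationTemplateTable(
    {
        "is_a": "is a",
        "has_part": "is partially made up of",
        "has_role": "has the role",
        "IUPAC_NAME": "has preferred name",
        "SYNONYM": "otherwise known as",
    }
)


def _target_name(target_id: str, lexicon: Lexicon | None) -> str:
    if lexicon is not None and target_id in lexicon:
        return lexicon.name_of(target_id)
    return target_id


@dataclass(frozen=True)
class MergeConfig:
    """Merge all mergeable synonyms into the entity's first relation sentence
    (the default) or emit strictly one sentence per fact."""

    merge_synonyms: bool = True


def verbalize_entity(
    entity: LexiconEntity,
    templates: RelationTemplateTable = DEFAULT_TEMPLATES,
    lexicon: Lexicon | None = None,
    merge: MergeConfig = MergeConfig(),
) -> list[VerbalizedSentence]:
    """Render one entity's facts as sentences.

    Under the default merging rule, the entity's generic synonyms are folded
    into the sentence carrying its *first* relation ("NAME, otherwise known
    as S1 and S2, is a TARGET."); remaining relations become plain sentences,
    IUPAC-tagged synonyms always stand alone ("NAME has preferred name S."),
    and the definition becomes "NAME is defined as: DEFINITION." An entity
    with no facts yields an empty list.
    """
    sentences: list[VerbalizedSentence] = []
    name = entity.name

    mergeable = [s for s, t in entity.synonyms if t not in IUPAC_SYNONYM_TYPES]
    standalone_syns = [(s, t) for s, t in entity.synonyms if t in IUPAC_SYNONYM_TYPES]

    def synonym_clause(syns: list[str]) -> str:
        phrase = templates.phrase("SYNONYM")
        if len(syns) == 1:
            return f"{phrase} {syns[0]}"
        return f"{phrase} {', '.join(syns[:-1])} and {syns[-1]}"

    relations = list(entity.relations)
    merged_first = merge.merge_synonyms and mergeable and relations
    for i, (label, target) in enumerate(relations):
        connective = templates.phrase(label)
        obj = _target_name(target, lexicon)
        if i == 0 and merged_first:
            text = f"{name}, {synonym_clause(mergeable)}, {connective} {obj}."
            sentences.append(VerbalizedSentence(entity.entity_id, text, "merged"))
        else:
            sentences.append(
                VerbalizedSentence(entity.entity_id, f"{name} {connective} {obj}.", "triple")
            )

    if mergeable and not merged_first:
        for syn in mergeable:
            text = f"{name} is {templates.phrase('SYNONYM')} {syn}."
            sentences.append(VerbalizedSentence(entity.entity_id, text, "synonym"))
    for syn, stype in standalone_syns:
        text = f"{name} {templates.phrase('IUPAC_NAME')} {syn}."
        sentences.append(VerbalizedSentence(entity.entity_id, text, "synonym"))

    if entity.definition:
        definition = entity.definition.rstrip()
        if definition[-1] not in ".!?":
            definition += "."
        sentences.append(
            VerbalizedSentence(entity.entity_id, f"{name} is defined as: {definition}", "definition")
        )
    return sentences


def build_corpus(
    lexicon: Lexicon,
    templates: RelationTemplateTable = DEFAULT_TEMPLATES,
    split_fraction: float = 0.9,
    seed: int = 0,
    merge: MergeConfig = MergeConfig(),
) -> tuple[list[VerbalizedSentence], list[VerbalizedSentence], dict]:
    """Verbalize every retained entity and split into train/validation.

    Returns ``(train, validation, manifest)``. The shuffle is a deterministic
    function of ``seed``; the manifest reconciles sentence counts per
    source kind with the lexicon's fact counts, and carries a warning when
    the lexicon has nothing verbalizable.
    """
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must be in (0, 1)")
    sentences: list[VerbalizedSentence] = []
    for eid in sorted(lexicon.entities):
        sentences.extend(verbalize_entity(lexicon[eid], templates, lexicon, merge))

    counts: dict[str, int] = {"triple": 0, "synonym": 0, "definition": 0, "merged": 0}
    for s in sentences:
        counts[s.source_kind] += 1

    rng = random.Random(seed)
    shuffled = sentences[:]
    rng.shuffle(shuffled)
    n_train = int(round(split_fraction * len(shuffled)))
    train, val = shuffled[:n_train], shuffled[n_train:]

    manifest = {
        "n_sentences": len(sentences),
        "n_train": len(train),
        "n_validation": len(val),
        "split_fraction": split_fraction,
        "seed": seed,
        "counts_by_source_kind": counts,
    }
    if not sentences:
        manifest["warning"] = "lexicon contains no verbalizable content"
    return train, val, manifest


def write_corpus(
    train: list[VerbalizedSentence],
    val: list[VerbalizedSentence],
    manifest: dict,
    out_dir: str | Path,
) -> None:
    """Write train/validation as plain text + JSONL, plus the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for split_name, split in (("train", train), ("validation", val)):
        (out / f"{split_name}.txt").write_text(
            "".join(s.text + "\n" for s in split), encoding="utf-8"
        )
        with open(out / f"{split_name}.jsonl", "w", encoding="utf-8") as fh:
            for s in split:
                fh.write(
                    json.dumps(
                        {"entity_id": s.entity_id, "text": s.text, "source_kind": s.source_kind},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
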