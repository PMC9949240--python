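"""Synthetic miniature lexicons, synonym tables, corpora and gold standards.

Real inputs to this pipeline (a curated chemical ontology, an external
compound-synonym dump, tagger output over article titles, a hand-labelled
gold standard, a reference MeSH mapping) are all large downloads. This
module generates structurally faithful miniatures with controlled
difficulty so every other module is testable offline:

* **entity families** — a parent compound with stereoisomer-like children
  ("(R)-…"/"(S)-…", ``is_a`` the parent) that share an external synonym at
  the configured collision rate, reproducing the classic ambiguous-synonym
  situation the disambiguator exists for;
* **mention variants** — exact names, exact synonyms, pluralized forms and
  hyphenation variants (resolved at the RELAXED tier), bounded-edit typos
  (FUZZY tier), shared external synonyms (PUBCHEM tiers), and gibberish
  mentions with no true entity;
* **a role tree** — parent roles (pharmaceutical / metabolite / nutrient)
  with ``is_a`` chains of configurable depth, entities attached by
  ``has_role`` at the leaves.

Everything is a pure function of the seed, and the generator certifies its
own output: every non-typo mention's gold entity is recoverable by
exhaustive lookup by construction (surface keys are kept globally unique
except for the collisions deliberately built in), and every typo keeps an
indel ratio above the fuzzy threshold. Titles are template-based English so
character-n-gram embeddings of candidate titles are non-degenerate.

What these fixtures do *not* emulate: real chemical nomenclature grammar,
corpus-scale synonym noise, or contextual cues that a trained sentence
embedder would exploit — a green end-to-end test certifies the pipeline
machinery, not embedding quality.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path

from .evaluation import GoldRecord
from .lexicon import (
    ExternalSynonymTable,
    Lexicon,
    LexiconEntity,
    LoadReport,
)
from .matcher import Mention
from .textnorm import levenshtein_ratio, relaxed_key

__all__ = ["FixtureConfig", "FixtureLexicon", "FixtureCorpus",
           "make_fixture_lexicon", "make_fixture_corpus", "write_fixture_files",
           "PARENT_ROLE_IDS"]

# Role tree roots (ids chosen in a range far from generated chemical ids).
PARENT_ROLE_IDS = {
    "pharmaceutical": "CHEBI:800001",
    "metabolite": "CHEBI:800002",
    "nutrient": "CHEBI:800003",
}

_STEMS = ["kav", "nor", "lev", "meth", "carb", "phen", "sulf", "chlor", "benz",
          "amin", "oxal", "tau", "gal", "dopa", "cort", "estr", "lact", "cit"]
_MIDS = ["an", "ox", "ethyl", "prop", "amido", "yl", "in", "ur", "al", "oz"]
_SUFFIXES = ["ol", "ine", "ate", "ide", "one", "an", "amide", "oxin"]
_TITLE_TEMPLATES = [
    "Effects of {m} on cognitive decline in a transgenic mouse model",
    "Dietary {m} as a potent inhibitor of amyloid precursor protein processing",
    "The therapeutic effect of {m} on vascular brain lesions",
    "Randomized trial of {m} for mild cognitive impairment",
    "Neuroprotective mechanisms of {m} in cellular models of neurodegeneration",
    "{m} attenuates oxidative stress in hippocampal neurons",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generated world. All rates are probabilities in [0, 1];
    mention-category rates are applied in priority order
    no_entity → plural → punct_variant → typo, remaining mass is exact."""

    seed: int = 13
    n_entities: int = 50
    synonym_collision_rate: float = 0.2
    plural_rate: float = 0.15
    punct_variant_rate: float = 0.1
    typo_rate: float = 0.1
    typo_edits: int = 1
    no_entity_rate: float = 0.05
    n_titles: int = 200
    role_depth: int = 2

    def __post_init__(self) -> None:
        for name in ("synonym_collision_rate", "plural_rate", "punct_variant_rate",
                     "typo_rate", "no_entity_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_entities < 2:
            raise ValueError("n_entities must be ≥ 2")


@dataclass
class FixtureLexicon:
    lexicon: Lexicon
    table: ExternalSynonymTable
    dropped_rows: list[list[str]]  # bad-status rows emitted to exercise filtering
    families: list[list[str]]  # sibling entity-id groups sharing an external synonym


@dataclass
class FixtureCorpus:
    mentions: list[Mention]
    gold: list[GoldRecord]
    reference_rows: list[tuple[str, str]]  # (mesh_id, entity_id)
    categories: list[str]  # generation category per mention, for assertions


class _NameFactory:
    """Unique chemical-ish names whose relaxed keys never collide by accident."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used_keys: set[str] = set()
        self.used_surfaces: set[str] = set()

    def claim(self, surface: str) -> bool:
        key = relaxed_key(surface)
        if not key or key in self.used_keys or surface in self.used_surfaces:
            return False
        self.used_keys.add(key)
        self.used_surfaces.add(surface)
        return True

    def fresh(self, maker) -> str:
        for _ in range(1000):
            surface = maker()
            if self.claim(surface):
                return surface
        raise RuntimeError("name space exhausted; lower n_entities")

    def word(self) -> str:
        return self.fresh(
            lambda: self.rng.choice(_STEMS) + self.rng.choice(_MIDS) + self.rng.choice(_SUFFIXES)
        )

    def systematic(self, base: str) -> str:
        locants = ",".join(str(self.rng.randint(1, 9)) for _ in range(2))
        group = self.rng.choice(["methoxy", "hydroxy", "chloro", "amino"])
        return self.fresh(lambda: f"({locants}-di{group})-{base}")


def _build_role_tree(config: FixtureConfig) -> tuple[list[LexiconEntity], list[str]]:
    """Chains of depth ``role_depth`` under each parent role; returns the
    role entities and the leaf role ids entities can attach to."""
    entities: list[LexiconEntity] = []
    leaves: list[str] = []
    next_id = 810000
    for role_name, parent_id in PARENT_ROLE_IDS.items():
        entities.append(LexiconEntity(parent_id, role_name))
        prev = parent_id
        for depth in range(1, config.role_depth + 1):
            rid = f"CHEBI:{next_id}"
            next_id += 1
            entities.append(
                LexiconEntity(rid, f"{role_name} subtype {depth}",
                              relations=[("is_a", prev)])
            )
            prev = rid
        leaves.append(prev)
    return entities, leaves


def make_fixture_lexicon(config: FixtureConfig) -> FixtureLexicon:
    """Generate the lexicon, external synonym table and role tree.

    Entities come in two kinds: sibling families (parent + (R)-/(S)-children
    linked by ``is_a``) and standalone compounds, some with systematic
    recommended names and trivial-name synonyms. At the collision rate, a
    family shares one external synonym across all its members' CIDs. Two
    bad-status rows are included in the file output (and dropped on load) to
    keep ingestion filtering honest.
    """
    rng = random.Random(config.seed)
    names = _NameFactory(rng)
    role_entities, role_leaves = _build_role_tree(config)
    entities: list[LexiconEntity] = list(role_entities)
    table = ExternalSynonymTable()
    families: list[list[str]] = []

    next_id = 100001
    next_cid = 5001

    def new_entity(name: str, relations=None, synonyms=None, definition=None) -> LexiconEntity:
        nonlocal next_id, next_cid
        ent = LexiconEntity(
            f"CHEBI:{next_id}", name,
            synonyms=list(synonyms or []),
            relations=list(relations or []),
            definition=definition,
        )
        next_id += 1
        if rng.random() < 0.8:
            leaf = rng.choice(role_leaves)
            ent.relations.append(("has_role", leaf))
            ent.roles.append(leaf)
        cid = f"CID{next_cid}"
        next_cid += 1
        table.cid_synonyms[cid] = []
        table.cid_to_entity[cid] = {ent.entity_id}
        ent._cid = cid  # fixture-internal bookkeeping
        entities.append(ent)
        return ent

    n_chem = config.n_entities
    made = 0
    while made < n_chem:
        if n_chem - made >= 3 and rng.random() < 0.4:
            base = names.word()
            parent = new_entity(base, definition=f"A parent compound of the {base} family.")
            family_ids = [parent.entity_id]
            for prefix in ("(R)-", "(S)-"):
                sib_name = f"{prefix}{base}"
                if not names.claim(sib_name):
                    continue
                sib = new_entity(sib_name, relations=[("is_a", parent.entity_id)])
                family_ids.append(sib.entity_id)
            made += len(family_ids)
            if len(family_ids) >= 2 and rng.random() < config.synonym_collision_rate:
                shared = names.word()
                for eid in family_ids:
                    ent = next(e for e in entities if e.entity_id == eid)
                    table.cid_synonyms[ent._cid].append(shared)
                families.append(family_ids)
        else:
            trivial = names.word()
            if rng.random() < 0.3:
                systematic = names.systematic(names.word())
                ent = new_entity(
                    systematic,
                    synonyms=[(trivial, "EXACT")],
                    definition=f"A synthetic compound also known as {trivial}.",
                )
            else:
                syns = [(names.word(), "EXACT")]
                if rng.random() < 0.3:
                    syns.append((names.systematic(trivial), "IUPAC_NAME"))
                ent = new_entity(trivial, synonyms=syns,
                                 definition=f"A small molecule named {trivial}.")
            table.cid_synonyms[ent._cid].append(names.word())
            made += 1

    # CIDs that never received a synonym would vanish in TSV round-trips.
    table.cid_synonyms = {cid: syns for cid, syns in table.cid_synonyms.items() if syns}

    # Rows that must be dropped on load: one obsolete, one unknown status.
    dropped_rows = [
        ["CHEBI:999001", "obsoletium", "", "S", "3", ""],
        ["CHEBI:999002", "mysterium", "", "Z", "3", ""],
    ]

    report = LoadReport(retained=len(entities))
    return FixtureLexicon(Lexicon(entities, report), table, dropped_rows, families)


def _pluralize(name: str) -> str:
    if name.endswith(("s", "x", "z", "ch", "sh")):
        return name + "es"
    return name + "s"


def _punct_variant(name: str, rng: random.Random) -> str | None:
    """Insert a hyphen at an internal alphabetic boundary (relaxed-key safe)."""
    positions = [i for i in range(2, len(name) - 1)
                 if name[i - 1].isalpha() and name[i].isalpha()]
    if not positions:
        return None
    i = rng.choice(positions)
    return name[:i] + "-" + name[i:]


def _typo(name: str, rng: random.Random, n_edits: int) -> str:
    """Up to ``n_edits`` substitutions, never touching the first character."""
    chars = list(name)
    for _ in range(n_edits):
        positions = [i for i in range(1, len(chars)) if chars[i].isalpha()]
        if not positions:
            break
        i = rng.choice(positions)
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        chars[i] = rng.choice([c for c in alphabet if c != chars[i].lower()])
    return "".join(chars)


def _all_surfaces(fx: FixtureLexicon) -> set[str]:
    surfaces = set()
    for ent in fx.lexicon.entities.values():
        surfaces.add(ent.name)
        surfaces.update(s for s, _ in ent.synonyms)
    for syns in fx.table.cid_synonyms.values():
        surfaces.update(syns)
    return surfaces


def make_fixture_corpus(fx: FixtureLexicon, config: FixtureConfig) -> FixtureCorpus:
    """Generate titles, gold records and a reference MeSH mapping.

    Each title embeds exactly one mention; the gold record carries the
    generating entity (or ``NONE`` for gibberish mentions, whose surfaces
    are certified to stay at or below the fuzzy threshold against every
    lexicon surface). Each entity is assigned a MeSH-like id carried by its
    mentions; the reference mapping covers roughly 60% of those ids, with
    occasional parent-entity pairs standing in for the sibling-specific
    truth (the ancestor-conflict case).
    """
    rng = random.Random(config.seed + 1)
    chem_ids = sorted(
        eid for eid in fx.lexicon.entities
        if eid not in set(fx.lexicon.role_hierarchy) and not _is_role_id(eid)
    )
    mesh_of = {eid: f"MESH:D{100000 + i}" for i, eid in enumerate(chem_ids)}
    surfaces = _all_surfaces(fx)
    surface_keys = {relaxed_key(s) for s in surfaces}

    # entity → external shared synonyms usable as ambiguous mentions
    shared_syn: dict[str, list[str]] = {}
    for cid, syns in fx.table.cid_synonyms.items():
        for eid in fx.table.cid_to_entity.get(cid, ()):
            shared_syn.setdefault(eid, []).extend(syns)

    mentions: list[Mention] = []
    gold: list[GoldRecord] = []
    categories: list[str] = []

    def gibberish() -> str:
        for _ in range(200):
            s = "".join(rng.choice("qwjxzvk") for _ in range(12))
            if s in surfaces or relaxed_key(s) in surface_keys:
                continue
            worst = max(
                (levenshtein_ratio(s, surf) for surf in surfaces), default=0.0
            )
            if worst <= 50.0:
                return s
        raise RuntimeError("could not generate an unmatchable gibberish surface")

    for i in range(config.n_titles):
        r = rng.random()
        eid = rng.choice(chem_ids)
        ent = fx.lexicon[eid]
        category = "exact_name"
        if r < config.no_entity_rate:
            category, surface, gold_id, mesh = "no_entity", gibberish(), "NONE", f"MESH:C{900000 + i}"
        else:
            r -= config.no_entity_rate
            if r < config.plural_rate:
                category, surface = "plural", _pluralize(ent.name)
            else:
                r -= config.plural_rate
                if r < config.punct_variant_rate:
                    variant = _punct_variant(ent.name, rng)
                    if variant is None:
                        category, surface = "exact_name", ent.name
                    else:
                        category, surface = "punct", variant
                else:
                    r -= config.punct_variant_rate
                    if r < config.typo_rate:
                        for _ in range(100):
                            t = _typo(ent.name, rng, config.typo_edits)
                            if (
                                t not in surfaces
                                and relaxed_key(t) not in surface_keys
                                and levenshtein_ratio(t, ent.name) > 50.0
                            ):
                                break
                        category, surface = "typo", t
                    else:
                        options = [("exact_name", ent.name)]
                        options += [("exact_synonym", s) for s, _ in ent.synonyms]
                        options += [("external", s) for s in shared_syn.get(eid, [])]
                        category, surface = rng.choice(options)
            gold_id, mesh = eid, mesh_of[eid]
            if category in ("plural", "punct"):
                # variant surfaces must stay out of the verbatim lexicon
                if surface in surfaces:
                    category, surface = "exact_name", ent.name

        template = rng.choice(_TITLE_TEMPLATES)
        prefix = template.split("{m}")[0]
        # Unique trailing clause: identical surfaces in identical contexts
        # with different gold entities would make the gold unrecoverable by
        # any method, so every title carries a distinguishing cohort tag.
        title = template.format(m=surface) + f" (cohort {i + 1:03d})"
        start = len(prefix)
        span = (start, start + len(surface))
        doc_id = f"PMID:{i + 1:05d}"
        mentions.append(Mention(doc_id, title, span, mesh))
        gold.append(GoldRecord(doc_id, span, surface, gold_id))
        categories.append(category)

    reference_rows: list[tuple[str, str]] = []
    for eid, mesh in sorted(mesh_of.items()):
        roll = rng.random()
        if roll < 0.5:
            reference_rows.append((mesh, eid))
        elif roll < 0.65:
            parents = fx.lexicon[eid].is_a_parents()
            chem_parents = [p for p in parents if p in mesh_of]
            if chem_parents:
                reference_rows.append((mesh, chem_parents[0]))  # ancestor conflict
            else:
                reference_rows.append((mesh, eid))
        # else: uncovered mesh id → derived_only territory

    return FixtureCorpus(mentions, gold, reference_rows, categories)


def _is_role_id(eid: str) -> bool:
    try:
        num = int(eid.split(":")[1])
    except (IndexError, ValueError):
        return False
    return 800000 <= num < 900000


def write_fixture_files(fx: FixtureLexicon, corpus: FixtureCorpus, out_dir: str | Path) -> dict:
    """Emit every artifact in the dialects the other modules read.

    Returns a name → path map: ``lexicon.tsv`` (6/7-column fallback dialect,
    including the deliberately dropped bad-status rows), ``synonyms.tsv`` and
    ``links.tsv`` (external synonyms), ``mentions.tsv``, ``gold.tsv`` and
    ``reference.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv"
             for name in ("lexicon", "synonyms", "links", "mentions", "gold", "reference")}

    def tsv(path: Path, rows) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh, delimiter="\t").writerows(rows)

    lex_rows = []
    for eid in sorted(fx.lexicon.entities):
        ent = fx.lexicon[eid]
        syn_field = "|".join(
            s if t == "EXACT" else f"{s}~{t}" for s, t in ent.synonyms
        )
        rel_field = "|".join(f"{label} {target}" for label, target in ent.relations)
        lex_rows.append([eid, ent.name, syn_field, ent.status, str(ent.stars),
                         rel_field, ent.definition or ""])
    lex_rows.extend(fx.dropped_rows)
    tsv(paths["lexicon"], lex_rows)

    tsv(paths["synonyms"],
        [[cid, s] for cid in sorted(fx.table.cid_synonyms)
         for s in fx.table.cid_synonyms[cid]])
    tsv(paths["links"],
        [[cid, eid] for cid in sorted(fx.table.cid_to_entity)
         for eid in sorted(fx.table.cid_to_entity[cid])])
    tsv(paths["mentions"],
        [[m.doc_id, m.title, str(m.span[0]), str(m.span[1]), m.mesh_id or "-"]
         for m in corpus.mentions])
    tsv(paths["gold"],
        [[g.doc_id, str(g.span[0]), str(g.span[1]), g.surface, g.gold_entity_id]
         for g in corpus.gold])
    tsv(paths["reference"], [list(row) for row in corpus.reference_rows])
    return {k: str(v) for k, v in paths.items()}
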