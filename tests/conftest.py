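"""Shared fixtures: a hand-built micro-lexicon plus the seeded synthetic world."""

import pytest
from hypothesis import settings

import chemnorm as cn
from chemnorm.synthetic_fixtures import (
    FixtureConfig,
    make_fixture_corpus,
    make_fixture_lexicon,
)

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def build_micro_lexicon():
    """Hand-built lexicon exercising every tier: exact names, synonyms,
    a relaxed-only entity, external collisions, and a role chain."""
    entities = [
        cn.LexiconEntity(
            "CHEBI:63584", "Cabazitaxel",
            definition="A taxane ester.",
            relations=[("has_role", "CHEBI:52217")],
            roles=["CHEBI:52217"],
        ),
        cn.LexiconEntity(
            "CHEBI:92875", "5-(2-chloroethyl)-4-methylthiazole",
            synonyms=[("chlormethiazole", "EXACT")],
        ),
        cn.LexiconEntity("CHEBI:51848", "α-ketoester"),
        cn.LexiconEntity("CHEBI:6117", "kawain"),
        cn.LexiconEntity("CHEBI:91863", "4-methoxy-2-(2-phenylethenyl)-2,3-dihydropyran-6-one"),
        cn.LexiconEntity(
            "CHEBI:92164", "(2R)-4-methoxy-2-(2-phenylethenyl)-2,3-dihydropyran-6-one",
        ),
        cn.LexiconEntity(
            "CHEBI:9150", "Simvastatin",
            relations=[("is_a", "CHEBI:40303"), ("has_role", "CHEBI:50266")],
            roles=["CHEBI:50266"],
        ),
        cn.LexiconEntity("CHEBI:40303", "lovastatin"),
        cn.LexiconEntity(
            "CHEBI:50266", "prodrug", relations=[("is_a", "CHEBI:52217")]
        ),
        cn.LexiconEntity("CHEBI:52217", "pharmaceutical"),
    ]
    lexicon = cn.Lexicon(entities)
    table = cn.ExternalSynonymTable(
        cid_synonyms={
            "CID100": ["kavain"],
            "CID101": ["kavain"],
            "CID102": ["kavain"],
        },
        cid_to_entity={
            "CID100": {"CHEBI:6117"},
            "CID101": {"CHEBI:91863"},
            "CID102": {"CHEBI:92164"},
        },
    )
    return lexicon, table


@pytest.fixture(scope="session")
def micro_lexicon():
    return build_micro_lexicon()


@pytest.fixture(scope="session")
def micro_indices(micro_lexicon):
    lexicon, table = micro_lexicon
    return cn.build_synonym_indices(lexicon, table)


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(seed=13)


@pytest.fixture(scope="session")
def fixture_world(fixture_config):
    fx = make_fixture_lexicon(fixture_config)
    corpus = make_fixture_corpus(fx, fixture_config)
    return fx, corpus


@pytest.fixture(scope="session")
def fixture_indices(fixture_world):
    fx, _ = fixture_world
    return cn.build_synonym_indices(fx.lexicon, fx.table)


@pytest.fixture(scope="session")
def oracle_backend(fixture_world):
    """Backend constructed so each mention's gold candidate title is nearest."""
    fx, corpus = fixture_world
    pairs = [
        (m.title, cn.build_candidate_title(m.title, m.span, fx.lexicon.name_of(g.gold_entity_id)))
        for m, g in zip(corpus.mentions, corpus.gold)
        if g.gold_entity_id != cn.NONE
    ]
    return cn.PairOracleBackend(pairs)
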