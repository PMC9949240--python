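# chemnorm

Normalization of chemical mentions in article titles to a ChEBI-style
ontology, for literature-mining pipelines (e.g. mapping the chemical
interventions reported in the Alzheimer's/dementia literature onto ontology
entities so they can be filtered by role — pharmaceutical, metabolite,
nutrient — and cross-referenced with MeSH).

Upstream taggers normalize chemical mentions to MeSH, a terminology with
little ontological structure. ChEBI offers `is_a` hierarchy, `has_role`
relations and curated synonymy, but there is no complete MeSH→ChEBI map, and
chemical names are wildly variable (brand names, systematic names, plurals,
hyphenation, typos). `chemnorm` implements a hybrid normalizer:

1. **Hierarchical dictionary candidate generation.** A mention is probed
   against lookup tiers in a fixed order, stopping at the first hit:
   exact ontology name → exact ontology synonym → *relaxed* match
   (lower-case, depluralized, dashes/parentheses/commas removed) → exact
   external (PubChem-style CID-linked) synonym → relaxed external synonym →
   fuzzy match by indel ratio, keeping candidates with
   `ratio = 100·(1 − D(a,b)/(|a|+|b|)) > 50`, where `D` is the edit
   distance with substitution cost 2. Mentions of ≤2 characters (or
   "water") are unmatchable by fiat.
2. **Sentence-pair disambiguation.** When several candidates survive, each
   candidate's recommended name is substituted into the title at the
   mention span, every candidate title is embedded alongside the original
   title, and the candidate with maximal cosine similarity wins. A
   threshold τ on the winning cosine flags probable lexicon gaps. A
   fuzzy-ratio baseline (`argmax` indel ratio) is provided for comparison.
3. **Downstream consumers.** Ontology verbalization (triples, synonyms and
   definitions rendered as natural-language sentences for language-model
   pretraining), gold-standard evaluation with a threshold sweep,
   context-derived MeSH↔ChEBI mapping comparison, and `has_role`/`is_a`
   rollups to parent role terms.

The package ships a deterministic hashed character-3-gram embedding backend
(no model downloads, bit-reproducible) plus an adapter for external
sentence-embedding models; the recipe for training an ontology-aware
embedder is in `docs/methods.md`.

## Worked example

```python
import chemnorm as cn

lexicon = cn.Lexicon([
    cn.LexiconEntity("CHEBI:6117", "kawain"),
    cn.LexiconEntity("CHEBI:91863", "4-methoxy-2-(2-phenylethenyl)-2,3-dihydropyran-6-one"),
    cn.LexiconEntity("CHEBI:92164", "(2R)-4-methoxy-2-(2-phenylethenyl)-2,3-dihydropyran-6-one"),
])
table = cn.ExternalSynonymTable(
    cid_synonyms={"CID1": ["kavain"], "CID2": ["kavain"], "CID3": ["kavain"]},
    cid_to_entity={"CID1": {"CHEBI:6117"}, "CID2": {"CHEBI:91863"}, "CID3": {"CHEBI:92164"}},
)
indices = cn.build_synonym_indices(lexicon, table)

title = "The therapeutic effect of kavain on vascular brain lesions"
mention = cn.Mention("PMID:1", title, (26, 32))          # span of "kavain"
cs = cn.generate_candidates(mention, indices, lexicon, table)
print("tier:", cs.tier.name, "| needs_disambiguation:", cs.needs_disambiguation)
print("candidates:", [c.entity_id for c in cs.candidates])

result = cn.rank_candidates(cs, cn.HashedNgramBackend(dim=256, seed=0), lexicon)
print("chosen:", result.entity_id, "cosine: %.3f" % result.score)
```

prints

```
tier: EXACT_PUBCHEM | needs_disambiguation: True
candidates: ['CHEBI:6117', 'CHEBI:91863', 'CHEBI:92164']
chosen: CHEBI:6117 cosine: 0.952
```

The mention "kavain" misses every lexicon tier but is a shared external
synonym of three CID-linked entities, so the matcher stops at the
`EXACT_PUBCHEM` tier with all three as candidates. Substituting each
recommended name into the title and ranking by cosine similarity selects
`CHEBI:6117` ("kawain", cosine 0.952 against 0.634/0.630 for the two
systematic-name stereoisomer entries); the long systematic names make the
candidate titles much less similar to the original. The fuzzy baseline
(`cn.fuzzy_disambiguate(cs)`) agrees here with ratio 100.

## Command line

```bash
chemnorm make-fixtures --seed 13 --out fixtures/          # synthetic world
chemnorm normalize --mentions fixtures/mentions.tsv \
    --lexicon fixtures/lexicon.tsv --pubchem-syn fixtures/synonyms.tsv \
    --pubchem-links fixtures/links.tsv --out results.jsonl
chemnorm evaluate --results results.jsonl --gold fixtures/gold.tsv \
    --lexicon fixtures/lexicon.tsv --mentions fixtures/mentions.tsv \
    --taus -1,0.5,0.7,0.9 --out eval/
chemnorm verbalize --lexicon fixtures/lexicon.tsv --out corpus/
```

Lexicons load from OBO 1.4 or a 6/7-column TSV fallback; mentions from
5-column TSV or PubTator-dialect BioC XML.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the synthetic world from the seed, runs the full pipeline
(matching, embedding and fuzzy-baseline disambiguation, threshold sweep
evaluation, MeSH mapping comparison, role rollup) from scratch, and writes
the results file plus a `diagnostics.json` with tier tallies, accuracy
sweeps and rollup fractions next to it.
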