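# Methods

## The normalization model

`chemnorm` treats chemical entity normalization as candidate generation
followed by context disambiguation.

**Candidate generation** is a tier ladder over lookup indices. The ladder
order encodes a precision hierarchy: a verbatim match to an ontology
recommended name is more trustworthy than a verbatim synonym match, which
is more trustworthy than a match after relaxing surface variation, which is
more trustworthy than a match through an external compound-synonym table,
with fuzzy string matching as the last resort. The walk stops at the first
tier with any hit, so a lower-precision tier can never override a
higher-precision one. Only a *singleton* hit at one of the two verbatim
lexicon tiers is accepted outright; every other non-empty candidate set —
including singleton relaxed matches — passes through the disambiguator
(which selects a singleton trivially, but records a similarity score that
thresholding may later use to flag it; we chose to let the threshold apply
to relaxed singletons, while verbatim exact matches always bypass it).

**Relaxed normalization** applies, in order: whole-string abbreviation
expansion (user-supplied table, empty by default — the mechanism is
deliberately a plain dictionary because no principled expansion rule
survives chemical nomenclature), lower-casing, removal of dashes (all
unicode dash variants), parentheses and commas, whitespace collapse, and
depluralization of the final token. Depluralization is a small irregular
table plus suffix rules (`-ies→-y`, `-ches/-shes/-xes/-zes/-ses→` drop
`es`, trailing `-s` dropped unless `-ss/-us/-is`); stemming is avoided
because chemical suffixes (`-ol`, `-ate`, `-ide`) carry meaning. The
function is idempotent and never lengthens its input (the irregular table
is restricted to non-lengthening entries for that reason). Index *keys* at
the relaxed tiers additionally remove internal whitespace, so a spaced
plural variant ("α-keto esters") and a fused lexicon name ("α-ketoester")
collide on the key "αketoester"; keys are fixed points of both the
normalizer and the key function.

**The indel ratio** is `100·(1 − D(a,b)/(|a|+|b|))` with `D` the edit
distance under insertion/deletion cost 1 and substitution cost 2, computed
as `200·LCS/(|a|+|b|)` via the LCS dynamic program. The fuzzy tier keeps
candidates with ratio strictly greater than 50 (default), scanning
sub-sources in ladder order (lexicon names, lexicon synonyms, external
synonyms) and stopping at the first sub-source with any hit; a pooled mode
is available behind a flag. The 0–100 scale matches the conventional
fuzzy-matching threshold idiom.

**Disambiguation** builds, for each candidate, the title with the mention
span replaced by the candidate's recommended name (span-based substitution,
so repeated substrings are safe), embeds original and candidate titles,
and selects the argmax cosine. Exact cosine ties are broken by higher
lexical score then ascending entity id, which makes the decision
independent of candidate order. Cosine of a zero vector is defined as 0
(with a warning) so degenerate embeddings degrade instead of aborting; a
backend exception yields a `method="none"` result and the stream continues.
A threshold τ applied to embedding results converts sub-τ winners to
explicit no-matches while keeping the raw score for audit; τ=−1 disables
thresholding, and exact-tier results are never thresholded.

## Lexicon ingestion

Entities with curation status C (curated) or E (exists, uncurated) and a
2- or 3-star rating are retained; submitted/deleted/obsolete records and
unknown status codes are dropped and counted, never fatal. Status and star
filters are applied conjunctively (their order is immaterial). Dangling
relation targets stay listed on the entity but are excluded from the role
hierarchy so rollups never walk off the known graph. External synonyms are
dropped when empty, purely non-alphabetic, or bare registry numbers
(digit-hyphen groups); this "inconsistent structure" rule is a stand-in for
an underspecified upstream filter and can be disabled.

Accepted dialects: standard OBO 1.4 (`subset: N_STAR` carries stars; a
non-standard `status:` tag and `is_obsolete:` are honored; absent tags
default to C/3 so public exports load whole) and a 6/7-column TSV fallback
(`id, name, synonyms|pipe-joined[~TYPE], status, stars,
relations|pipe-joined "label TARGET"[, definition]`) so fixtures need no
OBO writer.

## Verbalization

Each retained entity's facts become sentences through a relation-phrase
table (`is_a`→"is a", `has_part`→"is partially made up of", IUPAC-tagged
synonym→"has preferred name", generic synonym→"otherwise known as";
untemplated labels fall back to the label with underscores as spaces). The
merging rule — fixed here because only a single worked example constrains
it — folds all generic synonyms into the entity's first relation sentence
("NAME, otherwise known as S1 and S2, is a TARGET."); remaining relations
become plain sentences, IUPAC synonyms always stand alone, definitions
become "NAME is defined as: …". One-sentence-per-fact mode is available.
The train/validation split is a seeded shuffle; the manifest reconciles
sentence counts per source kind exactly against lexicon contents.

**Training recipe (documented, not executed here).** The corpus is intended
for continuing masked-LM pretraining of a biomedical BERT (3 epochs, batch
size 8, learning rate 1e-4), followed by sentence-embedding fine-tuning on
a semantic textual similarity task (4 epochs, batch size 16, 512-token cap,
mean pooling over token embeddings). The resulting model plugs in through
`SentenceTransformerBackend`; no weights ship with the package.

## Evaluation and downstream analyses

Overall accuracy counts a mention correct when the chosen entity equals the
gold entity, with abstention on a truly absent entity counted correct.
Disambiguation accuracy restricts to mentions that went through the
disambiguator. The existence task (does any lexicon entity exist for this
mention?) is scored as binary precision/recall/F1 with positives =
non-abstentions after thresholding; exact-tier results are always predicted
positive. Metrics are order-invariant; a gold record with no aligned result
is a fatal error rather than a silent skip.

Mapping comparison categorizes each mention as matched / derived-only /
reference-only / conflict / neither (a partition); one-to-many reference
sets count as matched when the derived entity is any member, and conflicts
are annotated when one side is the other's `is_a` ancestor (ancestor
detection uses `is_a` edges only, never role edges). Role rollups follow
`has_role` then close upward over `is_a` within the role graph; an entity
counts once per parent role regardless of path multiplicity, and fractions
are reported over mentions with a non-abstention normalization.

## The synthetic world

The fixture generator emits a miniature of every input: entity families
(parent + stereoisomer-like children sharing an external synonym at the
collision rate), systematic-name entities, a role tree of configurable
depth under pharmaceutical/metabolite/nutrient roots, and a title corpus
whose mentions are drawn per category (priority order: no-entity →
plural → hyphenation variant → typo; remaining mass exact
name/synonym/external). Defaults (50 entities, 200 titles, collision 0.2,
plural 0.15, punct 0.10, typo 0.10, no-entity 0.05, single-edit typos)
keep every tier populated at a desk-scale corpus while leaving exact
matches the majority class, as in real title corpora.

Construction guarantees, enforced at generation time: surface keys are
globally unique except for deliberate collisions, so every non-typo
mention's gold entity is recoverable by exhaustive lookup; typos never
touch the first character and are certified to keep ratio > 50 against the
gold name; gibberish no-entity surfaces are certified to stay ≤ 50 against
every lexicon surface; every title carries a unique trailing cohort tag,
because identical surfaces in byte-identical contexts with different gold
entities would be unrecoverable by any method. Everything is a pure
function of the seed.

What a green end-to-end test establishes: the tier ladder, key functions,
ranking, thresholding and bookkeeping are correct (the pair-oracle backend
achieves 100% by construction, so any miss is a pipeline defect). What it
does not establish: embedding quality on real text — the hashed 3-gram
backend has no semantics, and real chemical nomenclature is far noisier
than the generator's syllable names.

## Numerical and design choices

- Exact-tier keys are case-sensitive verbatim strings; case folding happens
  only in the relaxed tier, preserving the precision hierarchy.
- Candidate lists are sorted by descending lexical score then ascending
  entity id; all tie-breaks in the package reduce to this pair.
- Two empty strings have indel ratio 100; one empty string scores 0.
- Exact name collisions between retained entities (possible in fixtures,
  not in a curated release) emit all entities as candidates and require
  disambiguation.
- Thresholding is monotone by construction: raising τ can only convert
  linked results to flagged abstentions.
- The hashed 3-gram backend salts BLAKE2 with its seed and L2-normalizes
  bucket counts; it is bit-reproducible across processes and platforms.

## Known limitations

- Abbreviation/acronym resolution is only as good as the user-supplied
  table; no acronym induction is attempted.
- Only title-level context is used for disambiguation; abstracts are out of
  scope.
- The fuzzy tier is a full scan (O(lexicon) per unmatched mention) — fine
  at fixture scale, and the natural upgrade path for corpus scale is an
  n-gram prefilter.
- BioC support covers the XML dialect with title passages; BioC JSON is not
  parsed.
- Named-entity recognition is upstream: mentions are consumed, never
  detected.
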