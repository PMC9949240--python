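"""Disambiguation: title substitution, cosine, ranking, ties, thresholds."""

import itertools

import numpy as np
import pytest

import chemnorm as cn
from chemnorm.matcher import Candidate, CandidateSet, MatchTier, Mention

from oracles import indel_ratio_oracle


EPI_TITLE = "Dietary (−)-epicatechin as a potent inhibitor of βγ-secretase amyloid precursor protein processing"
EPI_SPAN = (8, 23)  # "(−)-epicatechin"


class TestBuildCandidateTitle:
    def test_substitutes_exactly_the_span(self):
        assert EPI_TITLE[EPI_SPAN[0]:EPI_SPAN[1]] == "(−)-epicatechin"
        out = cn.build_candidate_title(EPI_TITLE, EPI_SPAN, "(+)-catechin")
        assert out == (
            "Dietary (+)-catechin as a potent inhibitor of βγ-secretase "
            "amyloid precursor protein processing"
        )

    def test_identity_substitution(self):
        assert cn.build_candidate_title(EPI_TITLE, EPI_SPAN, "(−)-epicatechin") == EPI_TITLE

    def test_prefix_replacement(self):
        assert cn.build_candidate_title("kavain trial", (0, 6), "kawain") == "kawain trial"

    def test_span_based_not_string_search(self):
        # the repeated substring outside the span is untouched
        title = "catechin and catechin derivatives"
        assert cn.build_candidate_title(title, (13, 21), "epicatechin") == (
            "catechin and epicatechin derivatives"
        )

    @pytest.mark.parametrize("span", [(-1, 3), (5, 2), (0, 999)])
    def test_invalid_span_is_error(self, span):
        with pytest.raises(ValueError):
            cn.build_candidate_title("short title", span, "x")


class TestCosine:
    def test_self_similarity(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cn.cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cn.cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_computed_value(self):
        # dot = 32, |u| = sqrt(14), |v| = sqrt(77)
        expected = 32 / (np.sqrt(14) * np.sqrt(77))
        assert cn.cosine(np.array([1, 2, 3]), np.array([4, 5, 6])) == pytest.approx(expected)

    def test_zero_vector_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert cn.cosine(np.zeros(3), np.ones(3)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cn.cosine(np.ones(3), np.ones(4))


class DictBackend:
    """Test backend with explicitly constructed vectors per text."""

    identifier = "dict"
    deterministic = True

    def __init__(self, vectors, default=None):
        self.vectors = vectors
        self.default = default if default is not None else np.array([1.0, 0.0, 0.0])

    def embed(self, text):
        return np.asarray(self.vectors.get(text, self.default), dtype=float)


class FailingBackend:
    identifier = "failing"
    deterministic = True

    def embed(self, text):
        raise RuntimeError("backend exploded")


def make_candidate_set(lexicon, surface, candidate_ids, tier=MatchTier.EXACT_PUBCHEM,
                       scores=None):
    prefix = "Trial of "
    title = f"{prefix}{surface} in dementia"
    mention = Mention("PMID:9", title, (len(prefix), len(prefix) + len(surface)))
    scores = scores or [100.0] * len(candidate_ids)
    cands = [Candidate(eid, surface, s) for eid, s in zip(candidate_ids, scores)]
    return CandidateSet(mention, tier, cands, needs_disambiguation=True)


@pytest.fixture()
def sibling_lexicon():
    return cn.Lexicon(
        [
            cn.LexiconEntity("CHEBI:90", "(−)-epicatechin"),
            cn.LexiconEntity("CHEBI:15600", "(+)-catechin"),
            cn.LexiconEntity("CHEBI:23053", "catechin"),
        ]
    )


class TestRankCandidates:
    def test_argmax_cosine_wins(self, sibling_lexicon):
        cs = make_candidate_set(
            sibling_lexicon, "epicatechin", ["CHEBI:15600", "CHEBI:23053", "CHEBI:90"]
        )
        title = cs.mention.title
        gold_title = cn.build_candidate_title(title, cs.mention.span, "(−)-epicatechin")
        backend = DictBackend(
            {title: [1, 0, 0], gold_title: [0.9, 0.1, 0]},  # gold nearest
            default=[0, 1, 0],
        )
        result = cn.rank_candidates(cs, backend, sibling_lexicon)
        assert result.entity_id == "CHEBI:90"
        assert result.method == "embedding"
        assert result.score == max(s for _, s in result.all_scores)
        assert len(result.all_scores) == 3

    def test_permuting_candidates_never_changes_winner(self, sibling_lexicon):
        ids = ["CHEBI:15600", "CHEBI:23053", "CHEBI:90"]
        base = make_candidate_set(sibling_lexicon, "epicatechin", ids)
        title = base.mention.title
        gold_title = cn.build_candidate_title(title, base.mention.span, "(−)-epicatechin")
        backend = DictBackend({title: [1, 0, 0], gold_title: [0.9, 0.1, 0]}, default=[0, 1, 0])
        winners = set()
        for perm in itertools.permutations(base.candidates):
            cs = CandidateSet(base.mention, base.tier, list(perm), True)
            winners.add(cn.rank_candidates(cs, backend, sibling_lexicon).entity_id)
        assert winners == {"CHEBI:90"}

    def test_singleton_candidate(self, sibling_lexicon):
        cs = make_candidate_set(sibling_lexicon, "epicatechin", ["CHEBI:90"])
        backend = DictBackend({}, default=[1, 1, 0])
        result = cn.rank_candidates(cs, backend, sibling_lexicon)
        assert result.entity_id == "CHEBI:90"
        assert result.method == "embedding"

    def test_exact_tie_resolved_by_lexical_score_then_id(self, sibling_lexicon):
        # identical vectors for every candidate title → forced tie
        backend = DictBackend({}, default=[1, 0, 0])
        cs = make_candidate_set(
            sibling_lexicon, "catechins", ["CHEBI:23053", "CHEBI:15600"], scores=[80.0, 90.0]
        )
        assert cn.rank_candidates(cs, backend, sibling_lexicon).entity_id == "CHEBI:15600"
        cs_equal = make_candidate_set(
            sibling_lexicon, "catechins", ["CHEBI:23053", "CHEBI:15600"], scores=[90.0, 90.0]
        )
        assert cn.rank_candidates(cs_equal, backend, sibling_lexicon).entity_id == "CHEBI:15600"

    def test_backend_failure_degrades_to_none(self, sibling_lexicon):
        cs = make_candidate_set(sibling_lexicon, "epicatechin", ["CHEBI:90"])
        result = cn.rank_candidates(cs, FailingBackend(), sibling_lexicon)
        assert result.method == "none"
        assert result.entity_id == cn.NONE
        assert "exploded" in result.error

    def test_empty_candidates_rejected(self, sibling_lexicon):
        mention = Mention("PMID:1", "title here", (0, 5))
        with pytest.raises(ValueError):
            cn.rank_candidates(CandidateSet(mention, MatchTier.NO_MATCH), DictBackend({}), sibling_lexicon)


class TestFuzzyDisambiguate:
    def test_largest_ratio_wins(self, sibling_lexicon):
        surface = "epicatechin"
        matched = ["(−)-epicatechin", "catechin", "(+)-catechin"]
        cs = make_candidate_set(sibling_lexicon, surface, ["CHEBI:90", "CHEBI:23053", "CHEBI:15600"])
        cs.candidates = [
            Candidate(eid, m, 60.0) for eid, m in zip(["CHEBI:90", "CHEBI:23053", "CHEBI:15600"], matched)
        ]
        result = cn.fuzzy_disambiguate(cs)
        oracle = {m: indel_ratio_oracle(surface, m) for m in matched}
        best_surface = max(oracle, key=oracle.get)
        expected_id = next(c.entity_id for c in cs.candidates if c.matched_surface == best_surface)
        assert result.entity_id == expected_id
        assert result.score == pytest.approx(max(oracle.values()))
        assert result.method == "fuzzy_baseline"

    def test_singleton(self, sibling_lexicon):
        cs = make_candidate_set(sibling_lexicon, "catechin", ["CHEBI:23053"])
        result = cn.fuzzy_disambiguate(cs)
        assert result.entity_id == "CHEBI:23053"
        assert result.score == 100.0

    def test_all_equal_ratios_pick_lowest_id(self, sibling_lexicon):
        cs = make_candidate_set(sibling_lexicon, "xyz", ["CHEBI:500", "CHEBI:200"])
        for c in cs.candidates:
            assert c.matched_surface == "xyz"
        assert cn.fuzzy_disambiguate(cs).entity_id == "CHEBI:200"


class TestApplyThreshold:
    def embedding_result(self, score):
        mention = Mention("PMID:1", "Trial of suloctidil today", (9, 18))
        return cn.NormalizationResult(
            mention, "CHEBI:91639", score, "embedding", MatchTier.FUZZY,
            all_scores=[("CHEBI:91639", score)], needs_disambiguation=True,
        )

    def test_above_threshold_unchanged(self):
        result = cn.apply_threshold(self.embedding_result(0.97), 0.9)
        assert result.entity_id == "CHEBI:91639"
        assert not result.flagged_below_threshold

    def test_below_threshold_flagged(self):
        # a systematic-name winner with low similarity is a lexicon-gap signal
        result = cn.apply_threshold(self.embedding_result(0.531), 0.9)
        assert result.entity_id == cn.NONE
        assert result.flagged_below_threshold
        assert result.score == 0.531  # audit trail keeps the raw similarity

    def test_no_threshold_mode(self):
        assert cn.apply_threshold(self.embedding_result(0.01), -1).entity_id == "CHEBI:91639"

    def test_exact_results_bypass(self):
        mention = Mention("PMID:1", "Trial of kavain today", (9, 15))
        exact = cn.NormalizationResult(mention, "CHEBI:6117", 100.0, "exact", MatchTier.EXACT_NAME)
        assert cn.apply_threshold(exact, 0.99).entity_id == "CHEBI:6117"

    def test_raising_tau_monotone_in_flagging(self):
        scores = [0.2, 0.5, 0.8, 0.95]
        kept_counts = []
        for tau in [-1, 0.3, 0.5, 0.7, 0.9]:
            kept = sum(
                cn.apply_threshold(self.embedding_result(s), tau).entity_id != cn.NONE
                for s in scores
            )
            kept_counts.append(kept)
        assert kept_counts == sorted(kept_counts, reverse=True)


class TestHashedNgramBackend:
    def test_deterministic_across_instances(self):
        a = cn.HashedNgramBackend(dim=128, seed=3)
        b = cn.HashedNgramBackend(dim=128, seed=3)
        text = "Dietary (−)-epicatechin as a potent inhibitor"
        assert np.array_equal(a.embed(text), b.embed(text))
        assert np.linalg.norm(a.embed(text)) == pytest.approx(1.0)

    def test_different_texts_differ(self):
        backend = cn.HashedNgramBackend()
        assert not np.array_equal(backend.embed("kavain"), backend.embed("memantine"))


class TestPairOracleBackend:
    def test_pair_members_identical_others_orthogonal(self):
        backend = cn.PairOracleBackend([("title A", "candidate A"), ("title B", "candidate B")])
        assert cn.cosine(backend.embed("title A"), backend.embed("candidate A")) == 1.0
        assert cn.cosine(backend.embed("title A"), backend.embed("candidate B")) == 0.0
        assert cn.cosine(backend.embed("title A"), backend.embed("something else")) == 0.0
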