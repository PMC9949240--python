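"""MeSH mapping derivation/comparison and role rollups."""

import pytest

import chemnorm as cn
from chemnorm.matcher import MatchTier, Mention
from chemnorm.mapping_roles import CATEGORIES


def result(doc_id, surface, entity_id, mesh_id=None, method="embedding", idx=0):
    prefix = "Use of "
    title = f"{prefix}{surface} in care ({idx})"
    mention = Mention(doc_id, title, (len(prefix), len(prefix) + len(surface)), mesh_id)
    return cn.NormalizationResult(
        mention, entity_id, 0.9 if entity_id != cn.NONE else 0.0,
        method if entity_id != cn.NONE else "none", MatchTier.EXACT_NAME,
    )


class TestDeriveMapping:
    def test_pairs_require_both_identifiers(self):
        results = [
            result("d1", "ladostigil", "CHEBI:177484", "MESH:C423264"),
            result("d2", "mystery", cn.NONE, "MESH:C000001"),
            result("d3", "anon", "CHEBI:1", None),
        ]
        mapping = cn.derive_mapping(results)
        assert mapping.get("MESH:C423264") == {"CHEBI:177484"}
        assert mapping.get("MESH:C000001") == set()
        assert ("MESH:C423264", "CHEBI:177484") in mapping.provenance

    def test_multiplicity_with_set_semantics(self):
        results = [
            result("d1", "ladostigil", "CHEBI:177484", "MESH:C423264", idx=i)
            for i in range(3)
        ]
        mapping = cn.derive_mapping(results)
        assert mapping.get("MESH:C423264") == {"CHEBI:177484"}
        assert mapping.multiplicity[("MESH:C423264", "CHEBI:177484")] == 3


@pytest.fixture()
def hydroxycholesterol_lexicon():
    # CHEBI:50515 is the is_a-ancestor of the stereo-specific CHEBI:34310
    return cn.Lexicon(
        [
            cn.LexiconEntity("CHEBI:50515", "24-hydroxycholesterol"),
            cn.LexiconEntity(
                "CHEBI:34310", "(24S)-24-hydroxycholesterol",
                relations=[("is_a", "CHEBI:50515")],
            ),
            cn.LexiconEntity("CHEBI:9330", "sulfamic acid"),
        ]
    )


class TestCompareMappings:
    def test_constructed_category_fractions(self, hydroxycholesterol_lexicon):
        reference = cn.MeshChebiMapping()
        for mesh, eid in [
            ("MESH:M1", "CHEBI:50515"), ("MESH:M2", "CHEBI:50515"),
            ("MESH:M3", "CHEBI:9330"), ("MESH:M4", "CHEBI:34310"),
            ("MESH:C1", "CHEBI:50515"), ("MESH:C2", "CHEBI:9330"),
            ("MESH:R1", "CHEBI:9330"),
        ]:
            reference.add(mesh, eid, "reference")
        results = [
            # 4 matched
            result("d1", "a", "CHEBI:50515", "MESH:M1", idx=1),
            result("d2", "b", "CHEBI:50515", "MESH:M2", idx=2),
            result("d3", "c", "CHEBI:9330", "MESH:M3", idx=3),
            result("d4", "d", "CHEBI:34310", "MESH:M4", idx=4),
            # 3 derived_only (mesh absent from reference)
            result("d5", "e", "CHEBI:9330", "MESH:X1", idx=5),
            result("d6", "f", "CHEBI:9330", "MESH:X2", idx=6),
            result("d7", "g", "CHEBI:34310", "MESH:X3", idx=7),
            # 2 conflict
            result("d8", "h", "CHEBI:34310", "MESH:C1", idx=8),
            result("d9", "i", "CHEBI:34310", "MESH:C2", idx=9),
            # 1 reference_only
            result("d10", "j", cn.NONE, "MESH:R1", idx=10),
        ]
        comparison = cn.compare_mappings(results, reference, hydroxycholesterol_lexicon)
        assert comparison.counts == {
            "matched": 4, "derived_only": 3, "conflict": 2,
            "reference_only": 1, "neither": 0,
        }
        assert comparison.fractions["matched"] == pytest.approx(0.4)
        assert comparison.fractions["derived_only"] == pytest.approx(0.3)
        assert comparison.fractions["conflict"] == pytest.approx(0.2)
        assert comparison.fractions["reference_only"] == pytest.approx(0.1)

    def test_ancestor_conflict_annotated_more_specific(self, hydroxycholesterol_lexicon):
        reference = cn.MeshChebiMapping()
        reference.add("MESH:C044563", "CHEBI:50515", "reference")
        results = [result("d1", "24S-hydroxycholesterol", "CHEBI:34310", "MESH:C044563")]
        comparison = cn.compare_mappings(results, reference, hydroxycholesterol_lexicon)
        assert comparison.categories == ["conflict"]
        assert comparison.conflicts[0]["annotation"] == "derived_more_specific"

    def test_one_to_many_reference_prioritizes_match(self, hydroxycholesterol_lexicon):
        reference = cn.MeshChebiMapping()
        reference.add("MESH:D008610", "CHEBI:50515", "reference")
        reference.add("MESH:D008610", "CHEBI:34310", "reference")
        results = [result("d1", "menthol", "CHEBI:34310", "MESH:D008610")]
        comparison = cn.compare_mappings(results, reference, hydroxycholesterol_lexicon)
        assert comparison.categories == ["matched"]

    def test_categories_partition_and_fractions_sum_to_one(self, hydroxycholesterol_lexicon):
        reference = cn.MeshChebiMapping()
        reference.add("MESH:M1", "CHEBI:50515", "reference")
        results = [
            result("d1", "a", "CHEBI:50515", "MESH:M1", idx=1),
            result("d2", "b", "CHEBI:9330", None, idx=2),
            result("d3", "c", cn.NONE, None, idx=3),
            result("d4", "d", cn.NONE, "MESH:M1", idx=4),
        ]
        comparison = cn.compare_mappings(results, reference, hydroxycholesterol_lexicon)
        assert len(comparison.categories) == len(results)
        assert set(comparison.categories) <= set(CATEGORIES)
        assert sum(comparison.counts.values()) == len(results)
        assert sum(comparison.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_swapping_derived_and_reference_swaps_only_counts(self, hydroxycholesterol_lexicon):
        reference = cn.MeshChebiMapping()
        reference.add("MESH:R1", "CHEBI:9330", "reference")
        reference.add("MESH:B1", "CHEBI:50515", "reference")
        results = [
            result("d1", "a", "CHEBI:34310", "MESH:D1", idx=1),  # derived_only
            result("d2", "b", cn.NONE, "MESH:R1", idx=2),        # reference_only
            result("d3", "c", "CHEBI:50515", "MESH:B1", idx=3),  # matched
        ]
        forward = cn.compare_mappings(results, reference, hydroxycholesterol_lexicon)
        # swap: derived pairs become the reference; reference pairs become results
        swapped_reference = cn.derive_mapping(results)
        swapped_results = [
            result("s1", "a", cn.NONE, "MESH:D1", idx=4),
            result("s2", "b", "CHEBI:9330", "MESH:R1", idx=5),
            result("s3", "c", "CHEBI:50515", "MESH:B1", idx=6),
        ]
        backward = cn.compare_mappings(swapped_results, swapped_reference, hydroxycholesterol_lexicon)
        assert forward.counts["derived_only"] == backward.counts["reference_only"]
        assert forward.counts["reference_only"] == backward.counts["derived_only"]
        assert forward.counts["matched"] == backward.counts["matched"]


@pytest.fixture()
def role_lexicon():
    # prodrug —is_a→ pharmaceutical; two role paths converge on pharmaceutical
    return cn.Lexicon(
        [
            cn.LexiconEntity("CHEBI:52217", "pharmaceutical"),
            cn.LexiconEntity("CHEBI:50266", "prodrug", relations=[("is_a", "CHEBI:52217")]),
            cn.LexiconEntity("CHEBI:35620", "drug", relations=[("is_a", "CHEBI:52217")]),
            cn.LexiconEntity("CHEBI:25212", "metabolite"),
            cn.LexiconEntity(
                "CHEBI:9150", "Simvastatin",
                relations=[("has_role", "CHEBI:50266"), ("has_role", "CHEBI:35620")],
                roles=["CHEBI:50266", "CHEBI:35620"],
            ),
            cn.LexiconEntity("CHEBI:17234", "glucose", roles=[], relations=[]),
        ]
    )


class TestRollupRoles:
    def test_role_reached_via_is_a(self, role_lexicon):
        results = [result("d1", "Simvastatin", "CHEBI:9150", idx=1)]
        summary = cn.rollup_roles(results, role_lexicon, ["CHEBI:52217", "CHEBI:25212"])
        assert summary.mention_counts["CHEBI:52217"] == 1
        assert summary.mention_counts["CHEBI:25212"] == 0

    def test_two_paths_counted_once(self, role_lexicon):
        # Simvastatin reaches pharmaceutical via prodrug AND via drug
        results = [result("d1", "Simvastatin", "CHEBI:9150", idx=1)]
        summary = cn.rollup_roles(results, role_lexicon, ["CHEBI:52217"])
        assert summary.mention_counts["CHEBI:52217"] == 1
        assert summary.distinct_entities("CHEBI:52217") == 1

    def test_entity_without_roles_unclassified(self, role_lexicon):
        results = [result("d1", "glucose", "CHEBI:17234", idx=1)]
        summary = cn.rollup_roles(results, role_lexicon, ["CHEBI:52217"])
        assert summary.unclassified_mentions == 1
        assert summary.n_mentions == 1

    def test_none_results_excluded_from_denominator(self, role_lexicon):
        results = [
            result("d1", "Simvastatin", "CHEBI:9150", idx=1),
            result("d2", "mystery", cn.NONE, idx=2),
        ]
        summary = cn.rollup_roles(results, role_lexicon, ["CHEBI:52217"])
        assert summary.n_mentions == 1
        assert summary.fraction("CHEBI:52217") == 1.0

    def test_unknown_parent_role_fatal(self, role_lexicon):
        with pytest.raises(ValueError, match="unknown parent role"):
            cn.rollup_roles([], role_lexicon, ["CHEBI:999999"])

    def test_invariant_to_relation_order(self):
        def build(reverse):
            relations = [("has_role", "CHEBI:50266"), ("has_role", "CHEBI:35620")]
            if reverse:
                relations = relations[::-1]
            return cn.Lexicon(
                [
                    cn.LexiconEntity("CHEBI:52217", "pharmaceutical"),
                    cn.LexiconEntity("CHEBI:50266", "prodrug", relations=[("is_a", "CHEBI:52217")]),
                    cn.LexiconEntity("CHEBI:35620", "drug", relations=[("is_a", "CHEBI:52217")]),
                    cn.LexiconEntity(
                        "CHEBI:9150", "Simvastatin", relations=relations,
                        roles=[t for _, t in relations],
                    ),
                ]
            )

        results = [result("d1", "Simvastatin", "CHEBI:9150", idx=1)]
        a = cn.rollup_roles(results, build(False), ["CHEBI:52217"])
        b = cn.rollup_roles(results, build(True), ["CHEBI:52217"])
        assert a.mention_counts == b.mention_counts
        assert a.entity_sets == b.entity_sets
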