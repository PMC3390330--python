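"""Dataset classification pipeline and the seeded fixture generator."""

import pytest

from pkclass.classify import (
    DatasetRecord,
    FixtureError,
    classify_dataset,
    dedupe,
    fixture_dotbracket,
    generate_fixture,
    total_genus_histogram,
)
from pkclass.structure_io import SecondaryStructure, parse_dotbracket


def record(rid, text, sequence=None):
    s = parse_dotbracket(text)
    if sequence is not None:
        s = SecondaryStructure(length=s.length, pairs=s.pairs, sequence=sequence)
    return DatasetRecord(id=rid, structure=s)


class TestDedupe:
    def test_same_sequence_keeps_first(self):
        a = record("a", "((..))", "GGAACC")
        b = record("b", "(....)", "GGAACC")
        assert dedupe([a, b]) == [a]

    def test_different_sequences_kept(self):
        a = record("a", "((..))", "GGAACC")
        b = record("b", "((..))", "GGUUCC")
        assert dedupe([a, b]) == [a, b]

    def test_empty_and_sequenceless(self):
        assert dedupe([]) == []
        a, b = record("a", "...."), record("b", "....")
        assert dedupe([a, b]) == [a, b]


class TestClassifyDataset:
    def test_single_h_pseudoknot_span_17(self):
        # two 2-bp stems crossing, leftmost to rightmost paired base = 17 nt
        s = SecondaryStructure(length=17, pairs={(1, 9), (2, 8), (5, 17), (6, 16)})
        subclasses, components, discarded = classify_dataset(
            [DatasetRecord(id="hk", structure=s)]
        )
        assert len(subclasses) == 1
        sub = subclasses[0]
        assert (sub.subclass_id, sub.token, sub.genus) == ("1A", "ABAB", 1)
        assert sub.n_sequences == 1
        assert sub.length_min == 17 and sub.length_mean == 17.0
        assert discarded == []

    def test_subclass_ordering_by_prevalence(self):
        recs = []
        for k in range(3):
            rec, _ = generate_fixture([("ABAB", (2, 2), 0.0)], seed=k, record_id=f"s{k}")
            recs.append(rec)
        rec, _ = generate_fixture(
            [("ABAB", (2, 2), 0.0), ("ABACBC", (1, 3), 0.0)], seed=9, record_id="s3"
        )
        recs.append(rec)
        subclasses, _, _ = classify_dataset(recs)
        assert [(s.subclass_id, s.token, s.n_sequences) for s in subclasses] == [
            ("1A", "ABAB", 4),
            ("1B", "ABACBC", 1),
        ]

    def test_tie_break_prefers_more_arcs(self):
        # equal prevalence, same genus: the 5-arc motif outranks the 4-arc one
        r1, _ = generate_fixture([("ABCDEDBCAE", (1, 1), 0.0)], seed=1, record_id="five")
        r2, _ = generate_fixture([("ABCACDBD", (1, 1), 0.0)], seed=2, record_id="four")
        subclasses, _, _ = classify_dataset([r1, r2])
        assert [(s.subclass_id, s.token) for s in subclasses] == [
            ("2A", "ABCDEDBCAE"),
            ("2B", "ABCACDBD"),
        ]

    def test_genus0_components_flagged_and_structures_discarded(self):
        subclasses, components, discarded = classify_dataset([record("h", "((..))")])
        assert subclasses == []
        assert [c.genus for c in components] == [0, 0]
        assert discarded == ["h"]

    def test_empty_dataset(self):
        assert classify_dataset([]) == ([], [], [])


class TestHistogram:
    def test_triple_h_pseudoknot(self):
        assert total_genus_histogram([record("x", "([)]([)]([)]")]) == {3: 1}

    def test_all_pseudoknot_free(self):
        recs = [record(f"r{i}", "((..))") for i in range(3)]
        assert total_genus_histogram(recs) == {0: 3}

    def test_totals_match_dataset_size(self):
        recs = [
            record("a", "([)]"),
            record("b", "...."),
            record("c", "([)]([)]"),
        ]
        hist = total_genus_histogram(recs)
        assert hist == {0: 1, 1: 1, 2: 1}
        assert sum(hist.values()) == len(recs)


class TestFixtureGenerator:
    def test_single_planted_motif_recovered(self):
        rec, truth = generate_fixture([("ABAB", (2, 2), 0.0)], seed=1)
        subclasses, _, _ = classify_dataset([rec])
        assert [(s.token, s.genus) for s in subclasses] == [("ABAB", 1)]
        assert truth[0]["genus"] == 1

    def test_deterministic_bytes(self):
        spec = [("ABCACDBD", (1, 3), 0.2), ("ABAB", (2, 5), 0.0)]
        a = fixture_dotbracket(generate_fixture(spec, seed=7)[0])
        b = fixture_dotbracket(generate_fixture(spec, seed=7)[0])
        assert a == b

    def test_total_genus_additivity(self):
        rec, truth = generate_fixture(
            [("ABCACDBD", (1, 3), 0.2), ("ABAB", (2, 5), 0.0)], seed=3
        )
        assert sum(t["genus"] for t in truth) == 2 + 1
        from pkclass.genus import total_genus

        assert total_genus(rec.structure) == 3

    def test_rejects_bad_spec(self):
        with pytest.raises(FixtureError, match="stem range"):
            generate_fixture([("ABAB", (3, 2), 0.0)], seed=1)
        with pytest.raises(FixtureError, match="not a primitive"):
            generate_fixture([("AABB", (1, 2), 0.0)], seed=1)
        with pytest.raises(FixtureError, match="not canonical"):
            generate_fixture([("BABA", (1, 2), 0.0)], seed=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_pipeline_recovers_planted_multiset(self, seed):
        spec = [
            ("ABAB", (1, 6), 0.1),
            ("ABACBC", (1, 4), 0.3),
            ("ABCACDBD", (1, 3), 0.2),
            ("ABAB", (2, 8), 0.0),
        ]
        rec, truth = generate_fixture(spec, seed=seed, extra_hairpins=2)
        _, components, _ = classify_dataset([rec])
        planted = sorted((t["token"], t["genus"]) for t in truth)
        found = sorted((c.token, c.genus) for c in components if c.genus >= 1)
        assert found == planted
        # spans are reported exactly
        assert sorted(t["span"] for t in truth) == sorted(
            (c.span_start, c.span_end) for c in components if c.genus >= 1
        )
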