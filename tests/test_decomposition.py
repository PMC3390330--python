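"""Irreducible/primitive decomposition, stem collapse and pattern tokens."""

import pytest
from hypothesis import given, strategies as st

from helpers import inflate, secondary_structures
from pkclass.decomposition import (
    Diagram,
    collapse_stems,
    crossing,
    extract_primitive,
    has_collapsible_pair,
    nonnested_closure,
    parse_token,
    pattern_token,
    split_irreducible,
)
from pkclass.genus import genus_of
from pkclass.structure_io import parse_dotbracket


class TestSplitIrreducible:
    def test_concatenated_hairpins(self):
        comps = split_irreducible(parse_dotbracket("((..))((..))"))
        assert [c.arcs for c in comps] == [((1, 6), (2, 5)), ((7, 12), (8, 11))]
        assert [c.ranked().arcs for c in comps] == [((1, 4), (2, 3))] * 2

    def test_h_pseudoknot_is_one_component(self):
        comps = split_irreducible(parse_dotbracket("([)]"))
        assert len(comps) == 1 and comps[0].n_arcs == 2

    def test_three_h_pseudoknots(self):
        comps = split_irreducible(parse_dotbracket("([)]([)]([)]"))
        assert len(comps) == 3

    def test_empty(self):
        assert split_irreducible(parse_dotbracket("....")) == []

    @given(secondary_structures())
    def test_arcs_conserved_and_ordered(self, s):
        comps = split_irreducible(s)
        arcs = [a for c in comps for a in c.arcs]
        assert set(arcs) == set(s.pairs)
        spans = [c.span for c in comps]
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestNonNestedClosure:
    def test_excludes_nested_arc(self):
        d = Diagram(((1, 5), (3, 8), (6, 7)))
        assert nonnested_closure(d) == {(1, 5), (3, 8)}

    def test_crossing_pair(self):
        d = Diagram(((1, 3), (2, 4)))
        assert nonnested_closure(d) == {(1, 3), (2, 4)}

    def test_pure_hairpin_keeps_seed_only(self):
        d = Diagram(((1, 6), (2, 5)))
        assert nonnested_closure(d) == {(1, 6)}


class TestExtractPrimitive:
    def test_pseudoknot_free_peels_per_level(self):
        comps = extract_primitive(parse_dotbracket("((((..))))"))
        assert [c.diagram.arcs for c in comps] == [
            ((1, 10),),
            ((2, 9),),
            ((3, 8),),
            ((4, 7),),
        ]
        assert all(genus_of(c.diagram).genus == 0 for c in comps)

    def test_h_pseudoknot_single_component(self):
        comps = extract_primitive(parse_dotbracket("([)]"))
        assert len(comps) == 1 and comps[0].diagram.n_arcs == 2

    def test_kissing_hairpin_with_nested_hairpin(self):
        # ABACBC-shaped kissing hairpin plus a hairpin inside its first loop
        d = Diagram(((1, 8), (4, 12), (9, 14), (2, 3)))
        comps = extract_primitive(d)
        assert len(comps) == 2
        assert pattern_token(comps[0].diagram) == "ABACBC"
        assert comps[1].diagram.arcs == ((2, 3),)

    @given(secondary_structures())
    def test_arc_conservation(self, s):
        comps = extract_primitive(s)
        arcs = [a for c in comps for a in c.diagram.arcs]
        assert len(arcs) == len(s.pairs)
        assert set(arcs) == set(s.pairs)

    @given(secondary_structures())
    def test_component_invariants(self, s):
        for comp in extract_primitive(s):
            arcs = comp.diagram.arcs
            if len(arcs) >= 2:
                # every arc crosses at least one other arc
                assert all(
                    any(crossing(a, b) for b in arcs if b != a) for a in arcs
                )
                # the closure from the leftmost arc reaches all arcs
                assert nonnested_closure(comp.diagram) == set(arcs)
            # irreducible: no internal cut point
            assert len(split_irreducible(comp.diagram)) == 1


class TestCollapseStems:
    def test_helix_collapses_to_one_arc(self):
        d = Diagram(((1, 8), (2, 7), (3, 6), (4, 5)))
        assert collapse_stems(d).n_arcs == 1

    def test_mutually_crossing_arcs_are_a_fixpoint(self):
        d = Diagram(((1, 4), (2, 5), (3, 6)))  # pseudotrefoil: all arcs cross
        assert collapse_stems(d) == d

    def test_stacked_pair_with_a_crossing_arc_still_collapses(self):
        # (2,6) and (3,5) sit on adjacent positions on both sides, so they
        # form a stem even though (1,4) threads through it; the merge keeps
        # the genus (1 before and after)
        d = Diagram(((1, 4), (2, 6), (3, 5)))
        shadow = collapse_stems(d)
        assert shadow.arcs == ((1, 4), (2, 6))
        assert genus_of(shadow).genus == genus_of(d).genus == 1

    def test_two_stem_pseudoknot_collapses_to_abab(self):
        d = Diagram(((1, 7), (2, 6), (4, 10), (5, 9)))
        shadow = collapse_stems(d)
        assert shadow.n_arcs == 2
        assert pattern_token(shadow) == "ABAB"

    def test_collapse_across_bulges(self):
        # unpaired gaps between stacked pairs do not block the merge
        assert collapse_stems(Diagram(((1, 20), (3, 18)))).n_arcs == 1

    @given(secondary_structures())
    def test_fixpoint_and_genus_preserved(self, s):
        from pkclass.decomposition import diagram_of

        d = diagram_of(s)
        shadow = collapse_stems(d)
        assert not has_collapsible_pair(shadow)
        assert genus_of(shadow).genus == genus_of(d).genus


class TestPatternToken:
    @pytest.mark.parametrize(
        "arcs, token",
        [
            (((1, 3), (2, 4)), "ABAB"),
            (((1, 3), (2, 5), (4, 6)), "ABACBC"),  # kissing hairpin
            (((1, 4), (2, 5), (3, 6)), "ABCABC"),  # pseudotrefoil
        ],
    )
    def test_examples(self, arcs, token):
        assert pattern_token(Diagram(arcs)) == token

    def test_token_parse_roundtrip(self):
        for token in ("ABAB", "ABACBC", "ABCACDBD", "ABCDEFEGCGHIAIJKBKFJHD"):
            assert pattern_token(parse_token(token)) == token

    def test_malformed_token(self):
        with pytest.raises(ValueError, match="occurs"):
            parse_token("ABA")

    @given(
        st.sampled_from(["ABAB", "ABACBC", "ABCABC", "ABCACDBD", "ABCDCADB"]),
        st.data(),
    )
    def test_invariant_under_stem_inflation(self, token, data):
        sizes = {
            ch: data.draw(st.integers(1, 5), label=f"stem {ch}")
            for ch in sorted(set(token))
        }
        inflated = inflate(token, sizes)
        assert pattern_token(collapse_stems(inflated)) == token
        assert genus_of(inflated).genus == genus_of(parse_token(token)).genus
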