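"""The N-gram extension automaton: collapse, escape, closure, notation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopattern import (
    ClosureFlank,
    FixedBase,
    MotifPlant,
    RepeatGroup,
    SegmentSpec,
    SyntheticSpec,
    TripletTable,
    count_triplets,
    extend,
    generate_genome,
    parse,
    render,
    seed_select,
)
from isopattern.ngram import TRIPLETS


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def revcomp_table(table: TripletTable) -> TripletTable:
    return TripletTable.from_counts({revcomp(t): table[t] for t in TRIPLETS})


def revcomp_tokens(tokens):
    out = []
    for t in reversed(tokens):
        if isinstance(t, FixedBase):
            out.append(FixedBase(revcomp(t.base)))
        elif isinstance(t, RepeatGroup):
            out.append(RepeatGroup(revcomp(t.unit)))
        else:
            out.append(ClosureFlank(tuple(revcomp_tokens(t.tokens))))
    return out


class TestExtend:
    def test_l1_derivation_replays_printed_pattern(self, at_rich_table):
        """Seed TTT on the AT-rich table yields [(A)(T)](A)(T)[(A)(T)]."""
        motif = extend(at_rich_table, "TTT")
        assert render(motif) == "[(A)(T)](A)(T)[(A)(T)]"

    def test_pure_self_loop_closes_on_itself(self):
        table = TripletTable.from_counts({"AAA": 500})
        motif = extend(table, "AAA")
        assert render(motif) == "[(A)]"

    def test_escape_requires_positive_count(self):
        # AAA dominant, AAT present: the (A) cycle escapes via T, then (T) self-closes
        table = TripletTable.from_counts({"AAA": 500, "AAT": 10, "ATT": 8, "TTT": 100})
        motif = extend(table, "AAA")
        events = [s.event for s in motif.trace if s.direction == "down"]
        assert "escape" in events

    def test_gc_planted_genome_extends_through_G_then_C_repeats(self):
        spec = SyntheticSpec(
            segments=[SegmentSpec(100_000, 0.7, "H3")],
            planted_motifs=[MotifPlant("GGGGGCCCCC", 600)],
            seed=3,
        )
        seq, _ = generate_genome(spec)
        motif = extend(count_triplets(seq), "GGG")
        units = [t.unit for t in motif.tokens if isinstance(t, RepeatGroup)]
        for flank in (t for t in motif.tokens if isinstance(t, ClosureFlank)):
            units.extend(u.unit for u in flank.tokens if isinstance(u, RepeatGroup))
        assert "G" in units and "C" in units

    def test_tandem_repeat_collapses_to_smallest_unit(self):
        table = TripletTable.from_counts({"CAC": 300, "ACA": 300})
        motif = extend(table, "CAC")
        assert render(motif) == "[(CA)]"

    def test_homopolymer_beats_longer_unit(self):
        # (XX) is never emitted: smallest-k rule collapses to (X)
        table = TripletTable.from_counts({"GGG": 300})
        motif = extend(table, "GGG")
        assert render(motif) == "[(G)]"

    def test_deterministic_replay(self, at_rich_table):
        m1 = extend(at_rich_table, "TTT")
        m2 = extend(at_rich_table, "TTT")
        assert m1.tokens == m2.tokens and m1.trace == m2.trace

    def test_trace_records_families_and_ranks(self, at_rich_table):
        motif = extend(at_rich_table, "TTT")
        chosen = [(s.family, s.chosen) for s in motif.trace if s.event in ("extend", "escape")]
        assert ("TTx", "A") in chosen  # the TTA escape out of the (T) cycle

    def test_invalid_seed_rejected(self, at_rich_table):
        with pytest.raises(ValueError, match="seed"):
            extend(at_rich_table, "AXT")

    def test_zero_table_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            extend(TripletTable(np.zeros(64)), "AAA")

    def test_max_steps_caps_each_direction(self, at_rich_table):
        motif = extend(at_rich_table, "TTT", max_steps=1)
        appended = [s for s in motif.trace if s.event in ("extend", "escape")]
        assert len(appended) <= 2  # one per direction

    @pytest.mark.parametrize("seed_triplet", ["ATT", "TAT", "CAC", "GGG"])
    def test_complement_duality_exact(self, at_rich_table, seed_triplet):
        """Extending the revcomp seed on the revcomp table mirrors the motif."""
        fwd = extend(at_rich_table, seed_triplet)
        rev = extend(revcomp_table(at_rich_table), revcomp(seed_triplet))
        assert list(rev.tokens) == revcomp_tokens(fwd.tokens)

    @pytest.mark.parametrize("seed_triplet", ["TTT", "AAA"])
    def test_complement_duality_up_to_periodic_phase(self, at_rich_table, seed_triplet):
        """Homopolymer seeds close into fully periodic patterns whose finite
        rendering is phase-anchored on the seed letter; duality holds on the
        bi-infinite pattern, i.e. up to a rotation of the block cycle."""

        def blocks(tokens):
            out = []
            for t in tokens:
                if isinstance(t, ClosureFlank):
                    out.extend(blocks(t.tokens))
                else:
                    out.append(t)
            return out

        fwd = extend(at_rich_table, seed_triplet)
        rev = extend(revcomp_table(at_rich_table), revcomp(seed_triplet))
        got = blocks(rev.tokens)
        want = blocks(revcomp_tokens(fwd.tokens))
        assert len(got) == len(want)
        assert any(
            got == want[k:] + want[:k] for k in range(len(want))
        ), (render(rev), render(fwd))

    def test_stochastic_mode_is_seeded(self, at_rich_table):
        m1 = extend(at_rich_table, "TTT", stochastic=True, rng=42)
        m2 = extend(at_rich_table, "TTT", stochastic=True, rng=42)
        assert m1.tokens == m2.tokens


class TestSeedSelect:
    def test_top_ranked_triplet(self, at_rich_table):
        assert seed_select(at_rich_table) == "TTT"

    def test_most_frequent_CG_containing_is_ACG(self, at_rich_table):
        assert seed_select(at_rich_table, must_contain="CG") == "ACG"

    def test_all_zero_CG_family_falls_back_lexicographic(self):
        table = TripletTable.from_counts({"TTT": 9})
        assert seed_select(table, must_contain="CG") == "ACG"

    def test_invalid_constraint_rejected(self, at_rich_table):
        with pytest.raises(ValueError):
            seed_select(at_rich_table, must_contain="CGA")


token_st = st.recursive(
    st.one_of(
        st.sampled_from("ACGT").map(FixedBase),
        st.sampled_from(["A", "T", "CA", "TG", "ACG"]).map(RepeatGroup),
    ),
    lambda inner: st.lists(inner, min_size=1, max_size=3).map(
        lambda ts: ClosureFlank(tuple(t for t in ts if not isinstance(t, ClosureFlank)) or (RepeatGroup("A"),))
    ),
    max_leaves=6,
)


class TestNotation:
    @pytest.mark.parametrize(
        "tokens,expected",
        [
            ((RepeatGroup("A"), RepeatGroup("T")), "(A)(T)"),
            (parse("(CA)CAG(A)(T)CTG(TG)"), "(CA)CAG(A)(T)CTG(TG)"),
            (parse("(CA)CAG(A)(T)CCGG(A)(T)CTG(TG)"), "(CA)CAG(A)(T)CCGG(A)(T)CTG(TG)"),
        ],
    )
    def test_render_examples(self, tokens, expected):
        assert render(tokens) == expected

    @settings(max_examples=80, deadline=None)
    @given(st.lists(token_st, min_size=1, max_size=6))
    def test_parse_render_round_trip(self, tokens):
        assert parse(render(tokens)) == tuple(tokens)

    @pytest.mark.parametrize("bad", ["(A", "[(A)", "A)", "(AAAA)", "A-B"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(ValueError):
            parse(bad)
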