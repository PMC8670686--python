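"""Deletion extraction, splitting, ambiguity, edge matching, cascade order."""

from __future__ import annotations

import itertools
from collections import Counter

import pytest

from jumpdel.deletion_detect import (
    Deletion,
    DetectConfig,
    ReadContext,
    deletions_for_read,
    enforce_edge_matching,
    extract_deletions_from_cigar,
    is_ambiguous_deletion,
    join_split_alignments,
)
from jumpdel.io_formats import ReferenceSequence

from conftest import make_segment, read_for_deletion

NO_FILTER = DetectConfig(remove_ambiguous=False, enforce_edges=False)


class TestCigarExtraction:
    def test_simple_deletion(self, small_ref):
        seg = make_segment(cigar=[(8, "M"), (12, "D"), (8, "M")])
        (d,) = extract_deletions_from_cigar(seg, small_ref)
        assert (d.five_prime_site, d.three_prime_site) == (8, 21)
        assert d.deleted_length == 12
        assert d.insertion_length == 0

    def test_short_deletion_ignored(self, small_ref):
        seg = make_segment(cigar=[(8, "M"), (5, "D"), (15, "M")])
        assert extract_deletions_from_cigar(seg, small_ref) == []

    def test_adjacent_insertion_counted(self, small_ref):
        seg = make_segment(cigar=[(8, "M"), (3, "I"), (12, "D"), (8, "M")])
        (d,) = extract_deletions_from_cigar(seg, small_ref)
        assert (d.five_prime_site, d.three_prime_site, d.insertion_length) == (8, 21, 3)

    def test_multiple_deletions_per_read(self, small_ref):
        seg = make_segment(cigar=[(5, "M"), (10, "D"), (5, "M"), (11, "D"), (5, "M")])
        dels = extract_deletions_from_cigar(seg, small_ref)
        assert [(d.five_prime_site, d.three_prime_site) for d in dels] == \
            [(5, 16), (20, 32)]

    def test_walking_past_reference_end_errors(self, small_ref):
        seg = make_segment(ref_start=50, cigar=[(8, "M"), (12, "D"), (8, "M")])
        with pytest.raises(ValueError):
            extract_deletions_from_cigar(seg, small_ref)


class TestSplitJoin:
    def _ref200(self):
        return ReferenceSequence("r200", "ACGT" * 50)

    def test_clean_split(self):
        ref = self._ref200()
        a = make_segment(ref_name="r200", ref_start=1,
                         cigar=[(40, "M"), (40, "S")])
        b = make_segment(ref_name="r200", ref_start=141,
                         cigar=[(40, "S"), (40, "M")])
        (d,) = join_split_alignments([a, b], ref)
        assert (d.five_prime_site, d.three_prime_site) == (40, 141)
        assert (d.deleted_length, d.insertion_length) == (100, 0)

    def test_query_gap_becomes_insertion(self):
        ref = self._ref200()
        a = make_segment(ref_name="r200", ref_start=1,
                         cigar=[(40, "M"), (45, "S")])
        b = make_segment(ref_name="r200", ref_start=141,
                         cigar=[(45, "S"), (40, "M")])
        (d,) = join_split_alignments([a, b], ref)
        assert d.insertion_length == 5

    def test_small_reference_gap_discarded(self):
        ref = self._ref200()
        a = make_segment(ref_name="r200", ref_start=1,
                         cigar=[(40, "M"), (40, "S")])
        b = make_segment(ref_name="r200", ref_start=46,
                         cigar=[(40, "S"), (40, "M")])
        assert join_split_alignments([a, b], ref) == []

    def test_query_overlap_trimmed_to_slid_junction(self):
        # downstream alignment claims 3 query bases already aligned by the
        # upstream one; its start is advanced 3 ref positions instead of
        # dropping the candidate.
        ref = self._ref200()
        a = make_segment(ref_name="r200", ref_start=1,
                         cigar=[(43, "M"), (37, "S")])
        b = make_segment(ref_name="r200", ref_start=141,
                         cigar=[(40, "S"), (40, "M")])
        (d,) = join_split_alignments([a, b], ref)
        assert (d.five_prime_site, d.three_prime_site) == (43, 144)
        assert d.insertion_length == 0

    def test_strand_mismatch_tallied(self):
        ref = self._ref200()
        a = make_segment(ref_name="r200", ref_start=1,
                         cigar=[(40, "M"), (40, "S")])
        b = make_segment(ref_name="r200", ref_start=141,
                         cigar=[(40, "S"), (40, "M")], is_reverse=True)
        tally = Counter()
        assert join_split_alignments([a, b], ref, NO_FILTER, tally) == []
        assert tally["split_ref_or_strand_mismatch"] == 1


def brute_force_placements(ref: ReferenceSequence, five: int, three: int) -> int:
    """Number of placements of a same-length deleted block reproducing the
    identical read sequence — the enumeration oracle for ambiguity."""
    read = read_for_deletion(ref, five, three)
    length = three - five - 1
    n = 0
    # a block may also sit flush against either reference end (f = 0 or
    # t = len+1): not reportable junctions, but alternative read explanations
    for f in range(0, len(ref) - length + 1):
        t = f + length + 1
        if ref.sequence[:f] + ref.sequence[t - 1:] == read:
            n += 1
    return n


class TestAmbiguity:
    def test_spec_examples(self):
        ref1 = ReferenceSequence("a", "CTAAAG")
        assert not is_ambiguous_deletion(Deletion("a", 2, 6), ref1)
        ref2 = ReferenceSequence("b", "CAAAG")
        assert is_ambiguous_deletion(Deletion("b", 2, 5), ref2)

    def test_distinct_flanks_unambiguous(self):
        ref = ReferenceSequence("c", "ACGTACGTAC")
        assert not is_ambiguous_deletion(Deletion("c", 2, 6), ref)

    def test_out_of_bounds_rejected(self):
        ref = ReferenceSequence("d", "ACGTACGT")
        with pytest.raises(ValueError):
            is_ambiguous_deletion(Deletion("d", 0, 4), ref)

    def test_slide_test_equals_enumeration_exhaustively(self):
        """The O(1) two-sided slide test agrees with full placement
        enumeration on every sequence of length 6 over {A,C} (isomorphic to
        the full 4-letter case for a 2-letter comparison) and every block."""
        for tup in itertools.product("AC", repeat=6):
            ref = ReferenceSequence("x", "".join(tup))
            for five in range(1, 5):
                for three in range(five + 2, 7):
                    d = Deletion("x", five, three)
                    assert is_ambiguous_deletion(d, ref) == \
                        (brute_force_placements(ref, five, three) > 1), \
                        (ref.sequence, five, three)

    def test_slide_test_equals_enumeration_random(self, rng):
        import numpy as np
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(6, 16))
            ref = ReferenceSequence("x", "".join(bases[rng.integers(0, 4, n)]))
            five = int(rng.integers(1, n - 2))
            three = int(rng.integers(five + 2, n + 1))
            d = Deletion("x", five, three)
            assert is_ambiguous_deletion(d, ref) == \
                (brute_force_placements(ref, five, three) > 1)


def context_for(ref, five, three, insert="", mutations=()):
    """ReadContext for a read carrying a clean (five, three) deletion, with
    optional point mutations given as (ref_pos, base)."""
    left = list(ref.sequence[:five])
    right = list(ref.sequence[three - 1:])
    for pos, base in mutations:
        if pos <= five:
            left[pos - 1] = base
        else:
            right[pos - three] = base
    seq = "".join(left) + insert + "".join(right)
    a = make_segment(ref_name=ref.name, ref_start=1,
                     cigar=[(five + len(insert), "M"),
                            (three - five - 1, "D"),
                            (len(ref) - three + 1, "M")]
                     if not insert else
                     [(five, "M"), (len(insert), "I"),
                      (three - five - 1, "D"), (len(ref) - three + 1, "M")],
                     query_sequence=seq)
    return ReadContext([a])


class TestEdgeMatching:
    def test_exact_flanks_unchanged(self, small_ref):
        d = Deletion("ref60", 20, 35, read_id="r")
        ctx = context_for(small_ref, 20, 35)
        assert enforce_edge_matching(d, ctx, small_ref) is d

    def test_single_flank_mismatch_shifts_and_records_insertion(self, small_ref):
        # mutate the read base aligned at the 5' site
        wrong = "A" if small_ref.base(20) != "A" else "C"
        ctx = context_for(small_ref, 20, 35, mutations=[(20, wrong)])
        d = Deletion("ref60", 20, 35, read_id="r")
        out = enforce_edge_matching(d, ctx, small_ref)
        assert out.five_prime_site == 19
        assert out.insertion_length == 1
        assert out.three_prime_site == 35

    def test_excessive_shifts_drop(self, small_ref):
        # corrupt 11 consecutive read bases upstream of the junction
        muts = []
        for p in range(10, 21):
            wrong = "A" if small_ref.base(p) != "A" else "C"
            muts.append((p, wrong))
        ctx = context_for(small_ref, 20, 35, mutations=muts)
        d = Deletion("ref60", 20, 35, read_id="r")
        tally = Counter()
        assert enforce_edge_matching(d, ctx, small_ref, DetectConfig(),
                                     tally) is None
        assert tally["edge_shift_exceeded"] == 1

    def test_flank_past_reference_start_drops(self, small_ref):
        seg = make_segment(ref_start=1,
                           cigar=[(2, "M"), (12, "D"), (20, "M")],
                           query_sequence=small_ref.sequence[:2]
                           + small_ref.sequence[14:34])
        ctx = ReadContext([seg])
        d = Deletion("ref60", 2, 15, read_id="r")
        assert enforce_edge_matching(d, ctx, small_ref) is None

    def test_postcondition_flanks_exact(self, small_ref, rng):
        """Every emitted deletion has 3-nt flanks identical to the
        reference — the machine-checkable contract of edge matching."""
        import numpy as np
        bases = np.array(list("ACGT"))
        checked = 0
        for _ in range(200):
            five = int(rng.integers(6, 30))
            three = int(rng.integers(five + 11, min(five + 30, 55)))
            n_mut = int(rng.integers(0, 3))
            muts = []
            for _ in range(n_mut):
                p = int(rng.integers(max(1, five - 4), min(60, three + 5)))
                if five < p < three:
                    continue
                muts.append((p, str(bases[rng.integers(0, 4)])))
            ctx = context_for(small_ref, five, three, mutations=muts)
            d = Deletion("ref60", five, three, read_id="r")
            out = enforce_edge_matching(d, ctx, small_ref)
            if out is None:
                continue
            checked += 1
            for p in range(out.five_prime_site - 2, out.five_prime_site + 1):
                assert ctx.base_at(p) == small_ref.base(p)
            for p in range(out.three_prime_site, out.three_prime_site + 3):
                assert ctx.base_at(p) == small_ref.base(p)
            # shifting can only grow the deletion
            assert out.deleted_length >= d.deleted_length
            assert (out.deleted_length + out.insertion_length
                    - d.deleted_length - d.insertion_length) <= 10 * 2
        assert checked > 50


class TestCascade:
    def test_insertion_filter_applied(self, small_ref):
        seg = make_segment(cigar=[(8, "M"), (12, "I"), (12, "D"), (8, "M")],
                           query_sequence="A" * 28)
        tally = Counter()
        out = deletions_for_read([seg], small_ref,
                                 DetectConfig(remove_ambiguous=False,
                                              enforce_edges=False),
                                 tally)
        assert out == []
        assert tally["insertion_too_long"] == 1

    def test_ambiguity_toggle(self):
        ref = ReferenceSequence("amb", "CG" + "A" * 12 + "GTCCGGTTAAGGCCAT")
        # deletion of A-run block: slides freely -> ambiguous
        seg = make_segment(ref_name="amb", ref_start=1,
                           cigar=[(3, "M"), (10, "D"), (17, "M")],
                           query_sequence=ref.sequence[:3] + ref.sequence[13:])
        on = deletions_for_read([seg], ref, DetectConfig(enforce_edges=False))
        off = deletions_for_read([seg], ref,
                                 DetectConfig(remove_ambiguous=False,
                                              enforce_edges=False))
        assert on == [] and len(off) == 1

    def test_reverse_strand_read_discarded(self, small_ref):
        seg = make_segment(cigar=[(8, "M"), (12, "D"), (8, "M")],
                           is_reverse=True)
        tally = Counter()
        assert deletions_for_read([seg], small_ref, NO_FILTER, tally) == []
        assert tally["reverse_strand_segments"] == 1

    def test_cascade_order_edge_before_ambiguity(self):
        """Regression pin: edge matching runs before ambiguity removal.

        This junction is unambiguous as aligned, but one flank mismatch
        shifts it onto an ambiguous placement, which the fixed order then
        removes; ambiguity-first would keep (a shifted version of) it.
        """
        ref = ReferenceSequence("o", "ATGCCGTAAGCTTGACCTGAGATCGTACGGATCCAAGTTC")
        # pick a junction that is unambiguous as encoded but whose 5'-shifted
        # placement is ambiguous (depends on reference only)
        found = next(
            (f, f + 13) for f in range(4, 25)
            if not is_ambiguous_deletion(Deletion("o", f, f + 13), ref)
            and is_ambiguous_deletion(Deletion("o", f - 1, f + 13), ref)
        )
        five, three = found
        wrong = next(b for b in "ACGT" if b != ref.base(five))
        left = list(ref.sequence[:five])
        left[five - 1] = wrong
        read = "".join(left) + ref.sequence[three - 1:]
        seg = make_segment(ref_name="o", ref_start=1,
                           cigar=[(five, "M"), (three - five - 1, "D"),
                                  (len(ref) - three + 1, "M")],
                           query_sequence=read)
        cfg_full = DetectConfig()
        out = deletions_for_read([seg], ref, cfg_full)
        # edge-first: shifted placement flagged ambiguous and removed
        assert out == []
        # with ambiguity removal disabled the shifted record survives
        out2 = deletions_for_read([seg], ref, DetectConfig(remove_ambiguous=False))
        assert len(out2) == 1 and out2[0].five_prime_site == five - 1
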